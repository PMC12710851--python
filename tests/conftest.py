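import pytest

from thermocard.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    """A small but complete synthetic study shared across read-only tests."""
    cfg = SimulationConfig(n_populations=6, rng_seed=5)
    return simulate_study(cfg)
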