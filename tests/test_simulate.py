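import numpy as np
import pandas as pd
import pytest

from thermocard.data_model import COLOURS, PopulationMeta
from thermocard.simulate import (
    SimulationConfig,
    TruePopulation,
    simulate_counts,
    simulate_populations,
    simulate_seed_records,
    simulate_study,
)


def _zero_effect_config(**kw):
    betas = {f: 0.0 for f in vars(SimulationConfig())
             if f.startswith("beta_")}
    return SimulationConfig(
        **betas, colour_effect_scale=0.0, tb_noise_sd=0.0, to_noise_sd=0.0,
        tc_noise_sd=0.0, rmax_noise_sd=0.0, noise_sd_rate=0.0, **kw,
    )


def test_zero_effects_zero_noise_gives_identical_parameters():
    pops = simulate_populations(_zero_effect_config(n_populations=20))
    cfg = SimulationConfig()
    for p in pops:
        assert p.Tb == pytest.approx(cfg.tb_intercept)
        assert p.To == pytest.approx(cfg.to_intercept)
        assert p.Tc == pytest.approx(cfg.tc_intercept)
        assert p.Rmax == pytest.approx(cfg.rmax_intercept)


def test_pure_latitude_effect_makes_tb_decrease_with_latitude():
    cfg = _zero_effect_config(n_populations=40, rng_seed=3)
    cfg.beta_lat_tb = -0.2
    pops = simulate_populations(cfg)
    order = np.argsort([p.meta.latitude for p in pops])
    tb = np.array([p.Tb for p in pops])[order]
    assert np.all(np.diff(tb) < 0)


def test_same_seed_reproduces_identical_truth_table():
    a = simulate_study(SimulationConfig(n_populations=8, rng_seed=9))
    b = simulate_study(SimulationConfig(n_populations=8, rng_seed=9))
    pd.testing.assert_frame_equal(a["truth"], b["truth"])
    for ea, eb in zip(a["experiments"], b["experiments"]):
        assert np.array_equal(ea.cumulative_counts, eb.cumulative_counts)
    c = simulate_study(SimulationConfig(n_populations=8, rng_seed=10))
    assert not a["truth"]["true_Tb"].equals(c["truth"]["true_Tb"])


def test_parameters_lie_in_field_ranges_and_are_ordered(tiny_study):
    cfg = SimulationConfig()
    for p in tiny_study["populations"]:
        assert cfg.tb_range[0] <= p.Tb <= cfg.tb_range[1]
        assert cfg.to_range[0] <= p.To <= cfg.to_range[1]
        assert cfg.tc_range[0] <= p.Tc <= cfg.tc_range[1]
        assert cfg.rmax_range[0] <= p.Rmax <= cfg.rmax_range[1]
        assert p.Tb < p.To < p.Tc


def test_black_is_most_frequent_colour():
    pops = simulate_populations(SimulationConfig(n_populations=400, rng_seed=1))
    freq = pd.Series([p.colour for p in pops]).value_counts()
    assert freq.idxmax() == "black"
    assert set(freq.index) <= set(COLOURS)


def _manual_population(Tb=9.0, To=24.0, Tc=34.0, Rmax=0.01):
    return TruePopulation(
        meta=PopulationMeta("X", 43.0, 15.0, 300.0, "Serbia"),
        colour="black",
        trait_means={},
        Tb=Tb, To=To, Tc=Tc, Rmax=Rmax,
    )


def test_counts_zero_at_base_temperature():
    cfg = SimulationConfig(temperatures=(9.0,), n_populations=1)
    exps = simulate_counts(_manual_population(), cfg)
    for e in exps:
        assert np.all(e.cumulative_counts == 0)


def test_deterministic_counts_match_weibull_cdf_exactly():
    cfg = SimulationConfig(
        temperatures=(24.0,), n_replicates=1, viability_mean=1.0,
        deterministic_counts=True, weibull_shape=3.0,
    )
    e = simulate_counts(_manual_population(Rmax=0.01), cfg)[0]
    lam = 100.0 / np.log(2.0) ** (1.0 / 3.0)
    expected = 50 * (1.0 - np.exp(-((e.times / lam) ** 3)))
    assert np.allclose(e.cumulative_counts, expected, atol=1e-12)


def test_large_shape_gives_step_at_t50():
    cfg = SimulationConfig(
        temperatures=(24.0,), n_replicates=1, viability_mean=1.0,
        deterministic_counts=True, weibull_shape=500.0,
    )
    e = simulate_counts(_manual_population(Rmax=0.01), cfg)[0]
    # T50 = 100 h: nothing before the 96-h observation, everything after
    assert np.all(e.cumulative_counts[e.times < 100] < 1e-3)
    assert np.all(e.cumulative_counts[e.times > 120] > 50 - 1e-3)


def test_monte_carlo_half_germination_at_t50():
    # At the optimum with Rmax=0.01 and kappa=3, T50 = 100 h; by construction
    # the expected germinated fraction at t = T50 is exactly one half.
    cfg = SimulationConfig(
        temperatures=(24.0,), n_replicates=1, n_seeds_per_dish=10_000,
        viability_mean=1.0, noise_sd_rate=0.0, rng_seed=12,
    )
    rng = np.random.default_rng(99)
    e = simulate_counts(_manual_population(Rmax=0.01), cfg, rng=rng)[0]
    lam = 100.0 / np.log(2.0) ** (1.0 / 3.0)
    cdf_96 = 1.0 - np.exp(-((96.0 / lam) ** 3))
    frac_96 = e.cumulative_counts[e.times == 96][0] / 10_000
    se = np.sqrt(cdf_96 * (1 - cdf_96) / 10_000)
    assert abs(frac_96 - cdf_96) < 4 * se


def test_generated_tables_pass_validation(tiny_study, tmp_path):
    # construction already validates; additionally the CSV chain re-validates
    from thermocard.data_model import read_counts, write_counts

    write_counts(tiny_study["experiments"], tmp_path / "c.csv")
    assert len(read_counts(tmp_path / "c.csv")) == len(tiny_study["experiments"])
    records = simulate_seed_records(
        tiny_study["populations"], SimulationConfig(n_populations=6, rng_seed=5)
    )
    assert all(0 <= r.awn_contact <= 1 for r in records)


def test_config_rejects_bad_inputs():
    with pytest.raises(ValueError, match="strictly increasing"):
        SimulationConfig(temperatures=(10.0, 10.0))
    with pytest.raises(ValueError, match="viability"):
        SimulationConfig(viability_mean=0.0)
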