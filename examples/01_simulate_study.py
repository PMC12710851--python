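"""Generate a synthetic germination study and look at what it contains.

Builds a 12-population collection (temperatures 5-35 degC, 3 dishes of 50
seeds each, counted every 24 h for 14 days) and prints the ground-truth
cardinal parameters the later stages will try to recover.
"""

from thermocard import SimulationConfig, simulate_study

cfg = SimulationConfig(n_populations=12, rng_seed=42)
study = simulate_study(cfg)

print(f"populations: {len(study['populations'])}")
print(f"count experiments (pop x temp x dish): {len(study['experiments'])}")
print(f"measured seeds: {len(study['seed_records'])}")
print("\nTrue cardinal parameters (degC; Rmax in 1/h):")
print(study["truth"].round(3).to_string(index=False))

# Tb/To/Tc are the base, optimum and ceiling temperatures of each
# population; Rmax is its germination rate at the optimum.  Colour, traits
# and geography shift these values with the directions built into the
# generator (e.g. darker seeds -> higher Tb).
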