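"""Estimate cardinal temperatures from GR50 vs temperature.

The segmented ("Dent-like", single-optimum) model rises linearly from zero
at the base temperature Tb to the maximum rate Rmax at the optimum To, and
falls linearly back to zero at the ceiling Tc.  TGR = Tc - Tb is the
thermal germination range.
"""

from thermocard import (
    SimulationConfig,
    estimate_rates,
    fit_cardinal_table,
    simulate_study,
    summarize_cardinal,
)

cfg = SimulationConfig(n_populations=20, rng_seed=3)
study = simulate_study(cfg)
rates = estimate_rates(study["experiments"])
fits = fit_cardinal_table(rates)

merged = fits.merge(study["truth"], on="population_id")
conv = merged[merged["converged"]]
print(conv[["population_id", "Tb", "true_Tb", "To", "true_To",
            "Tc", "true_Tc", "TGR", "r_squared"]].round(2)
      .head(8).to_string(index=False))

print("\nDistribution over populations (cf. per-parameter histograms):")
print(summarize_cardinal(fits).round(3).to_string(index=False))

# Fitted Tb/To/Tc typically land within ~1 degC of the generating truth at
# the default 5% rate noise; populations with fewer than 4 usable
# temperatures are flagged non-converged instead of being force-fitted.
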