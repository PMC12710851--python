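# thermocard

Thermal biology of seed germination, from raw count data to geography.

`thermocard` is a Python library for estimating **cardinal germination
temperatures** — the base (Tb), optimum (To) and ceiling (Tc) temperatures
that bound a population's germination response — from replicated
germination-count experiments, and for relating those thermal parameters to
seed morphology and geographic origin. It is aimed at seed ecologists and
weed scientists who run temperature-gradient germination assays (e.g. on
wild oat or similar grass populations) and want a reproducible, testable
pipeline instead of a chain of spreadsheet and GUI steps.

## The models

**Time-course.** For each population × temperature, the cumulative
germination fraction CGF_t = N_t / N_total is fitted with a Weibull rise

    g(t) = g_max · (1 − exp(−(t/λ)^κ))

The time to half the final CGF has the closed form
**T50 = λ (ln 2)^(1/κ)**, and **GR50 = 1/T50** is the germination rate.

**Cardinal temperatures.** GR50 as a function of temperature T follows a
segmented ("Dent-like", single-optimum) model

    GR50(T) = Rmax · (T − Tb)/(To − Tb)   for Tb < T ≤ To
            = Rmax · (Tc − T)/(Tc − To)   for To < T < Tc
            = 0                            otherwise

fitted by multi-start least squares with Rmax profiled analytically.
**TGR = Tc − Tb** is the thermal germination range.

**Downstream inference.** Thermal parameters are screened against seed
traits and geography via per-pair tests reported as **log-worth**
(−log10 P, significant above 2); predicted from morphology by
**mixed-activation feed-forward networks** (TanH / Linear / Gaussian nodes,
two hidden layers, 45/30/25 split, 10 SGD tours at learning rate 0.1); and
clustered (Ward linkage on z-scored Tb, Tc, GR50, TGR) with silhouette
validation and the TGR–longitude Pearson correlation.

A **synthetic-data generator** reproduces the statistical structure of a
122-population European field collection (trait and colour effects on the
thermal parameters, geographic clines, censored Weibull germination times),
so every stage is testable end to end without any external data.

## Worked example

```python
from thermocard import (SimulationConfig, simulate_study, estimate_rates,
                        fit_cardinal_table, summarize_cardinal)

study = simulate_study(SimulationConfig(n_populations=20, rng_seed=3))
rates = estimate_rates(study["experiments"])     # Weibull fits, T50, GR50
fits  = fit_cardinal_table(rates)                # segmented model per population
print(summarize_cardinal(fits).round(3).to_string(index=False))
```

prints

```
parameter   mean    sd    min    max  n
       Tb  8.394 2.355  2.548 11.426 16
       To 24.573 1.629 22.354 27.898 16
       Tc 33.317 1.517 30.543 35.172 16
     Rmax  0.016 0.005  0.009  0.025 16
      TGR 24.923 2.988 20.116 31.872 16
```

i.e. 16 of 20 simulated populations yielded identifiable cardinal fits
(the rest germinated at too few temperatures and are flagged, not
force-fitted); base temperatures centre near 8–9 °C, optima near 24–25 °C
and ceilings near 33 °C, with Rmax the per-hour germination rate at the
optimum. Each script in `examples/` walks through one capability
(simulation, time-course fitting, cardinal estimation, screening, the
neural network, clustering, the full pipeline) and prints what the numbers
mean.

There is also a thin CLI:

```bash
thermocard simulate --seed 4 --out sim/
thermocard fit-timecourse sim/counts.csv --out rates.csv
thermocard fit-cardinal rates.csv --out cardinal.csv
thermocard run --config run.yaml --out results/
```

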