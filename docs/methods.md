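# Methods

This note documents the models implemented in `thermocard`, the choices
made where the underlying methodology left the design open, and what the
synthetic-data generator does and does not emulate.

## Germination time-course model

Counts are cumulative germinated seeds per dish on a 24-h grid over 336 h
(14 days), with 3 replicate dishes of 50 seeds per temperature. Replicates
are pooled before fitting (counts and seeds summed, then divided), which
matches producing a single GR50 per population × temperature; per-dish
fitting is available behind a flag for uncertainty work.

The CGF curve is fitted with a three-parameter Weibull,
g(t) = g_max (1 − exp(−(t/λ)^κ)):

* **g_max** ∈ (0, 1] — final germination fraction (asymptote). Fitting it
  rather than fixing it at the observed final value absorbs viability
  differences between dishes.
* **λ** (hours) — scale; **κ** (dimensionless) — shape (steepness).
* Least squares with multi-start over κ ∈ {0.5, 1, 2, 4, 8}, λ started at
  the first time the curve reaches half its final value, bounded
  trust-region refinement (tolerances 1e-12). Non-convergence is flagged,
  never raised.

**T50 is relative to the fitted asymptote** (time to 0.5 · g_max), not to
0.5 absolute — the closed form λ (ln 2)^(1/κ) — and GR50 = 1/T50 in h⁻¹.
Curves whose final pooled CGF is below **0.1** (configurable) are marked
unusable: the half-time of a near-flat curve is not identifiable. Unusable
temperatures contribute nothing to the cardinal fit by default; an option
exists to enter them as explicit zeros when they lie outside the observed
germinating span, but this risks biasing Tc/Tb when a temperature
germinates slowly rather than not at all, so it is off by default.

## Segmented cardinal-temperature model

GR50(T) = Rmax · f(T) with f triangular between (Tb, 0), (To, 1), (Tc, 0).
Notes on this parameterization:

* The relative (0–1) response needs the **scale Rmax** to touch observed
  rates; Rmax is therefore a fitted parameter (the rate at the optimum)
  and doubles as the population-level GR50 used downstream.
* The supra-optimal branch is implemented as (Tc − T)/(Tc − To), i.e.
  decreasing from 1 at To to 0 at Tc. The algebraically inverted variant
  (zero at the optimum, maximal at the ceiling) is available as
  `supra="inverted"` for comparison only — it contradicts To being an
  optimum and is never used in fitting.
* A single-breakpoint (triangular) shape is used rather than a plateaued
  variant, matching the estimation of a single To.

Fitting minimizes squared error over (Tb, To, Tc) with Rmax profiled in
closed form at every candidate: a 1 °C grid (Tb below the coolest
germinating temperature, Tc above the warmest, To across the germinating
span) locates the basin — ties broken by lowest RSS then lowest Tc — and
Nelder-Mead polishes (xatol 1e-8; derivative-free because the objective is
piecewise-smooth). Requirements and degeneracies:

* ≥ 4 usable (T, GR50) points with at least one positive rate; otherwise
  the population is reported unfitted with a reason.
* Flat positive rates (no interior maximum) are flagged non-identifiable.
* With exactly 4 usable points the 4-parameter fit is exactly determined,
  so R² = 1 by construction; reported R² values are therefore meaningful
  mainly for populations with ≥ 5 usable temperatures.

TGR = Tc − Tb is computed exactly from the fitted values.

## Response screening

Each response (GR50, Tb, To, Tc) × predictor pair is tested marginally:
simple-regression slope t-test for continuous predictors, one-way ANOVA
for colour. Evidence is the log-worth −log10 P (capped at 300); pairs
above 2 (P < 0.01, strictly) are significant. This is the minimal
realization of marginal response screening with the stated factor types;
no robust variants or transformations are applied, and no multiplicity
correction enters the ranking (a Benjamini–Hochberg column is emitted for
reference). Screening runs at population level: per-seed morphology is
aggregated by population means (modal colour, lexicographic tie-break,
flagged) because thermal parameters exist only per population.

## Neural networks

Two hidden layers; each node applies tanh(z), z, or exp(−z²) (the Gaussian
is the radial-bump convention) to its affine input. The GR50 architecture
is 6/2/11 (TanH/Linear/Gaussian) then 8/2/18; architectures for Tb, To, Tc
are configuration inputs with this as the default, since only the GR50
composition is anchored. Protocol details chosen here:

* Inputs and response z-scored **on the training split only**; colour as
  one-hot over the full category set; features with pairwise
  |Spearman ρ| > 0.7 dropped first (the member with the larger mean
  absolute correlation goes).
* 45/30/25 split by seeded shuffle; floor sizes with the remainder to
  training (n = 10 → 5/3/2).
* Per-sample SGD on squared error at fixed learning rate 0.1, epoch budget
  default 300–500 with the best-validation-epoch weights retained (an
  early-stopping flavour; no stopping rule was prescribed). Weights start
  uniform in ±0.3. 10 tours from independent initializations; minimal
  validation SSE wins, ties to the lowest tour index; diverging tours are
  abandoned with a warning.
* Topology is input → first hidden layer → second hidden layer → linear
  output (the layer order is an assumption; only "first/second" counts
  were stated).

Metrics: R² (1 − SSE/TSS), RASE = √(SSE/n), MAD, SSE, and Gaussian
negative log-likelihood with variance SSE/n computed per evaluated split.

## Clustering and geography

Agglomerative clustering with Ward linkage on Euclidean distance over
z-scored (Tb, Tc, GR50, TGR), cut at k = 4 (k exposed; a silhouette-vs-k
scan over 2–8 is emitted as a diagnostic). The linkage/distance choice is
this package's — the underlying methodology named only hierarchical
clustering — picked for determinism and reproducibility. Silhouette uses
the same standardized features. The TGR–longitude association is the
Pearson correlation with a two-sided t-test.

## Synthetic-data generator

The generator emulates a European field collection: 122 populations,
longitude ~ U(6°, 24°), latitude ~ U(37°, 49°), altitude ~ U(100, 800) m;
7 seed-colour categories with black most frequent (p = 0.34); 30 measured
seeds per population scattered around population trait means; germination
tested at 5–35 °C in 5 °C steps (7 levels support the 4-parameter fit),
3 × 50 seeds, counted every 24 h to 336 h.

True parameters are linear in traits and geography with the reported
directions, plus Gaussian noise, clipped into the observed field ranges
(Tb 6–15, To 18–27.76, Tc 29–38 °C, Rmax 0.006–0.028 h⁻¹; the Rmax range
is used rather than a summary mean/SD, which were mutually inconsistent in
the source report):

* **Tb** = 9.4 + colour effect (black +1.2 … light brown −1.4 °C)
  − 0.12 · (lat − 43) + 0.02 · (hairiness% − 35) + N(0, 0.9).
* **Tc** = 33.46 + colour effect (black −1.0, brown +1.0 °C)
  + 0.30 · (lon − 15) + 2.0 · (contact − 0.5) − 0.08 · (mass − 22)
  + 0.05 · (fruit length − 18) + N(0, 0.8).
* **To** = 24 + small colour/contact/hair-length/mass terms + N(0, 0.8),
  resampled until Tb + 0.5 < To < Tc − 0.5 (error after 200 attempts).
* **Rmax** = 0.015 + colour effect − 0.0007 · (mass − 22)
  − 0.0003 · (awn length − 30) + 0.0002 · (awn angle − 35)
  − 0.00002 · (hairiness − 35) ± 0.006 · (contact − 0.5), all times a
  multiplicative N(1, 0.05) term. The sign of the awn-contact effect is
  configurable (`gr50_contact_sign`) because the reported direction is
  ambiguous; the default is positive (higher attachment → faster).

Effect sizes were set once, a priori, from the reported qualitative
directions and printed dispersions: the colour span on Tb (~2.6 °C against
~1 °C residual noise) makes colour the dominant Tb predictor at n = 122;
β_lon = 0.3 °C/° with these variances gives a TGR–longitude correlation
near 0.6 at n = 122. They are configuration fields, not tuned constants.

Counts are generated by the same forward model the analysis assumes: dish
rate r = Rmax · f(T) times a shared multiplicative noise term per
population × temperature (SD `noise_sd_rate`, default 5%); viable seeds
(probability 0.85 — non-viable seeds never germinate, modelling empty or
infested seeds as reduced viability rather than removal) draw
Weibull(κ = 3, λ = T50/(ln 2)^(1/κ)) times, censored at 336 h and binned on
the grid. A **deterministic mode** replaces sampling with exact expected
fractional counts, used for noiseless recovery studies where sampling
error would mask fitting error.

What the generator does **not** emulate: spatial autocorrelation (geography
enters only through linear effects), country labels consistent with the
sampled coordinates (countries are a weighted categorical), dormancy,
temperature-dependent κ or viability, or between-dish viability spread.
Consequently, passing recovery tests demonstrate correctness of the
estimation chain under a well-specified model, not robustness to the
misspecifications real seed lots exhibit.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use the design scale for
single-run analyses (122 populations) and 40 populations for the repeated
recovery studies, 100 replicates for planted-effect detection, and 1,000
pairs for null calibration — sizes at which the binomial/Monte-Carlo error
of each check is comfortably below its acceptance margin.

## Known limitations

* Populations germinating at < 4 temperatures are reported unfitted;
  downstream summaries cover converged fits only (typically ~90% at the
  default conditions, fewer for narrow thermal ranges).
* With 5 °C temperature spacing, To is the least constrained cardinal
  parameter (it is a kink location); Tb and Tc are extrapolations of the
  two branches and inherit their slope uncertainty.
* No standard errors or bootstrap intervals for T50 or the cardinal
  temperatures are produced.
* The network stage offers no regularization or architecture search; it
  implements the stated protocol only.
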