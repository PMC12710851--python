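"""Synthetic germination study generator.

Emulates a European wild-oat style collection: 122 populations spread over
longitudes 6-24 degE, latitudes 37-49 degN and altitudes 100-800 m, each with
per-seed morphology (30 seeds measured per population), a seed-colour
category (black most frequent), and true cardinal germination parameters
(Tb, To, Tc, Rmax) lying in the observed field ranges (Tb 6-15 degC,
To 18-27.76 degC, Tc 29-37.65 degC, Rmax 0.006-0.028 h^-1).

Trait and geography effects enter the cardinal parameters linearly with the
reported directions: darker colours and hairier seeds raise Tb, higher
latitude lowers Tb, higher longitude raises Tc, black seeds have the lowest
Tc, awns attached nearer the lemma tip lower To and raise Tc, heavier seeds
lower To/Tc and slow germination, wider awn angles speed it.  The sign of
the awn-contact effect on the germination rate is configurable because the
source reports are contradictory; the default is positive (higher
attachment, faster germination).

Germination counts are generated by the same forward model the analysis
assumes: rate r = Rmax * f(T; Tb, To, Tc) from the segmented model (with
optional multiplicative dish-level noise), T50 = 1/r, Weibull(kappa,
lambda = T50/(ln 2)^(1/kappa)) germination times per viable seed, censored
at the end of the observation window and binned on the 24-h counting grid.
A deterministic mode replaces sampling with expected (fractional) counts for
exact parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .cardinal import dent_rate
from .data_model import (
    COLOURS,
    CONTINUOUS_TRAITS,
    GerminationExperiment,
    PopulationMeta,
    SeedTraitRecord,
)

#: Sampling probabilities by colour; black is the most frequent category.
COLOUR_PROBS: dict[str, float] = {
    "black": 0.34,
    "brown": 0.14,
    "light_brown": 0.12,
    "cream": 0.11,
    "golden": 0.10,
    "yellow": 0.10,
    "white": 0.09,
}

#: Colour offsets (degC) on Tb: dark and dense-coated categories germinate
#: from a higher base temperature; brown/light-brown the lowest.
COLOUR_EFFECT_TB = {
    "black": 1.2, "cream": 1.0, "golden": 0.8, "yellow": -0.2,
    "white": -0.4, "brown": -1.2, "light_brown": -1.4,
}
#: Colour offsets (degC) on To: yellow/white slightly higher optimum.
COLOUR_EFFECT_TO = {
    "black": 0.0, "cream": 0.0, "golden": 0.0, "yellow": 0.8,
    "white": 0.8, "brown": 0.0, "light_brown": 0.0,
}
#: Colour offsets (degC) on Tc: black lowest ceiling, brown/light-brown highest.
COLOUR_EFFECT_TC = {
    "black": -1.0, "cream": 0.3, "golden": 0.0, "yellow": 0.0,
    "white": 0.0, "brown": 1.0, "light_brown": 0.9,
}
#: Colour offsets (h^-1) on Rmax (colour is the dominant rate predictor).
COLOUR_EFFECT_RMAX = {
    "black": 0.0025, "cream": 0.001, "golden": 0.0, "yellow": -0.001,
    "white": -0.002, "brown": -0.0015, "light_brown": -0.0015,
}

#: Country labels with rough collection-frequency weights (Serbia dominant).
COUNTRY_WEIGHTS = {
    "Serbia": 63, "Poland": 8, "Slovenia": 6, "Bosnia and Herzegovina": 5,
    "Czech Republic": 4, "Bulgaria": 3, "Romania": 3, "North Macedonia": 3,
    "Montenegro": 3, "Hungary": 3, "Greece": 3, "Croatia": 3, "Italy": 3,
    "France": 3, "Switzerland": 3, "Germany": 6,
}


@dataclass
class SimulationConfig:
    """Study-design and effect-size settings for the generator.

    Defaults reproduce the field study's design: 122 populations, 3
    replicates of 50 seeds per dish at 7 temperatures (5-35 degC in 5-deg
    steps), counted every 24 h up to 336 h.
    """

    n_populations: int = 122
    temperatures: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
    n_replicates: int = 3
    n_seeds_per_dish: int = 50
    n_seeds_measured: int = 30
    observation_end_h: float = 336.0
    observation_step_h: float = 24.0
    weibull_shape: float = 3.0
    viability_mean: float = 0.85
    noise_sd_rate: float = 0.05       # multiplicative SD on the dish rate
    rmax_noise_sd: float = 0.05       # multiplicative SD on true Rmax
    tb_noise_sd: float = 0.9
    to_noise_sd: float = 0.8
    tc_noise_sd: float = 0.8
    # linear effect sizes (units: response unit per predictor unit)
    beta_lat_tb: float = -0.12        # degC per deg latitude (northern = lower Tb)
    beta_hair_tb: float = 0.02        # degC per % hairiness
    beta_lon_tc: float = 0.30         # degC per deg longitude (eastern = higher Tc)
    beta_contact_tc: float = 2.0      # degC per unit awn-contact position
    beta_mass_tc: float = -0.08       # degC per mg
    beta_fruitlen_tc: float = 0.05    # degC per mm
    beta_contact_to: float = -2.0
    beta_hairlen_to: float = 1.0
    beta_mass_to: float = -0.10
    beta_mass_rmax: float = -0.0007   # h^-1 per mg (heavier seeds slower)
    beta_awnlen_rmax: float = -0.0003
    beta_awnangle_rmax: float = 0.0002
    beta_hair_rmax: float = -0.00002
    beta_contact_rmax: float = 0.006
    gr50_contact_sign: float = 1.0    # +1: higher attachment -> faster (default)
    colour_effect_scale: float = 1.0  # 0 switches all colour effects off
    # intercepts and clipping ranges (field-observed ranges)
    tb_intercept: float = 9.4
    to_intercept: float = 24.0
    tc_intercept: float = 33.46
    rmax_intercept: float = 0.015
    tb_range: tuple[float, float] = (6.0, 15.0)
    to_range: tuple[float, float] = (18.0, 27.76)
    tc_range: tuple[float, float] = (29.0, 38.0)
    rmax_range: tuple[float, float] = (0.006, 0.028)
    deterministic_counts: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = temps
        if not 0.0 < self.viability_mean <= 1.0:
            raise ValueError("viability_mean must lie in (0, 1]")
        for name in ("n_populations", "n_replicates", "n_seeds_per_dish",
                     "n_seeds_measured"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def observation_grid(self) -> np.ndarray:
        return np.arange(self.observation_step_h,
                         self.observation_end_h + 1e-9,
                         self.observation_step_h)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperatures"] = list(self.temperatures)
        d["tb_range"] = list(self.tb_range)
        d["to_range"] = list(self.to_range)
        d["tc_range"] = list(self.tc_range)
        d["rmax_range"] = list(self.rmax_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("temperatures", "tb_range", "to_range", "tc_range",
                    "rmax_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class TruePopulation:
    """Ground truth for one simulated population."""

    meta: PopulationMeta
    colour: str
    trait_means: dict[str, float]
    Tb: float
    To: float
    Tc: float
    Rmax: float


def _population_traits(rng: np.random.Generator) -> dict[str, float]:
    """Population-mean morphology, on scales typical of wild-oat florets."""
    return {
        "seed_mass": max(rng.normal(22.0, 3.0), 5.0),        # mg
        "seed_length": max(rng.normal(8.0, 0.8), 3.0),       # mm (caryopsis)
        "fruit_width": max(rng.normal(2.8, 0.3), 0.5),       # mm
        "fruit_length": max(rng.normal(18.0, 2.0), 6.0),     # mm (with lemma)
        "awn_length": max(rng.normal(30.0, 4.0), 5.0),       # mm
        "awn_angle": float(np.clip(rng.normal(35.0, 8.0), 5.0, 85.0)),  # deg
        "awn_contact": float(rng.uniform(0.3, 0.7)),         # 0=base, 1=tip
        "pct_hairiness": float(rng.uniform(10.0, 60.0)),     # %
        "hair_length": max(rng.normal(1.2, 0.3), 0.1),       # mm
    }


def simulate_populations(config: SimulationConfig) -> list[TruePopulation]:
    """Draw populations with geography, colour, trait means and true
    cardinal parameters; the ordering Tb < To < Tc is enforced by
    resampling the To noise (error after 200 attempts)."""
    rng = np.random.default_rng(config.rng_seed)
    colours = list(COLOUR_PROBS)
    colour_p = np.array([COLOUR_PROBS[c] for c in colours])
    colour_p = colour_p / colour_p.sum()
    countries = list(COUNTRY_WEIGHTS)
    country_p = np.array([COUNTRY_WEIGHTS[c] for c in countries], dtype=float)
    country_p = country_p / country_p.sum()

    pops: list[TruePopulation] = []
    for i in range(config.n_populations):
        pid = f"P{i + 1:03d}"
        lat = rng.uniform(37.0, 49.0)
        lon = rng.uniform(6.0, 24.0)
        alt = rng.uniform(100.0, 800.0)
        country = countries[rng.choice(len(countries), p=country_p)]
        colour = colours[rng.choice(len(colours), p=colour_p)]
        tr = _population_traits(rng)

        tb = (
            config.tb_intercept
            + config.colour_effect_scale * COLOUR_EFFECT_TB[colour]
            + config.beta_lat_tb * (lat - 43.0)
            + config.beta_hair_tb * (tr["pct_hairiness"] - 35.0)
            + rng.normal(0.0, config.tb_noise_sd)
        )
        tb = float(np.clip(tb, *config.tb_range))
        tc = (
            config.tc_intercept
            + config.colour_effect_scale * COLOUR_EFFECT_TC[colour]
            + config.beta_lon_tc * (lon - 15.0)
            + config.beta_contact_tc * (tr["awn_contact"] - 0.5)
            + config.beta_mass_tc * (tr["seed_mass"] - 22.0)
            + config.beta_fruitlen_tc * (tr["fruit_length"] - 18.0)
            + rng.normal(0.0, config.tc_noise_sd)
        )
        tc = float(np.clip(tc, *config.tc_range))
        to_base = (
            config.to_intercept
            + config.colour_effect_scale * COLOUR_EFFECT_TO[colour]
            + config.beta_contact_to * (tr["awn_contact"] - 0.5)
            + config.beta_hairlen_to * (tr["hair_length"] - 1.2)
            + config.beta_mass_to * (tr["seed_mass"] - 22.0)
        )
        to = None
        for _ in range(200):
            cand = float(np.clip(to_base + rng.normal(0.0, config.to_noise_sd),
                                 *config.to_range))
            if tb + 0.5 < cand < tc - 0.5:
                to = cand
                break
        if to is None:
            raise RuntimeError(
                f"could not order Tb < To < Tc for population {pid} "
                f"(Tb={tb:.2f}, Tc={tc:.2f}); check config effect sizes"
            )
        rmax = (
            config.rmax_intercept
            + config.colour_effect_scale * COLOUR_EFFECT_RMAX[colour]
            + config.beta_mass_rmax * (tr["seed_mass"] - 22.0)
            + config.beta_awnlen_rmax * (tr["awn_length"] - 30.0)
            + config.beta_awnangle_rmax * (tr["awn_angle"] - 35.0)
            + config.beta_hair_rmax * (tr["pct_hairiness"] - 35.0)
            + config.gr50_contact_sign
            * config.beta_contact_rmax
            * (tr["awn_contact"] - 0.5)
        )
        rmax *= 1.0 + rng.normal(0.0, config.rmax_noise_sd)
        rmax = float(np.clip(rmax, *config.rmax_range))

        pops.append(
            TruePopulation(
                meta=PopulationMeta(pid, lat, lon, alt, country),
                colour=colour,
                trait_means=tr,
                Tb=tb,
                To=to,
                Tc=tc,
                Rmax=rmax,
            )
        )
    return pops


def simulate_seed_records(
    pops: Sequence[TruePopulation], config: SimulationConfig
) -> list[SeedTraitRecord]:
    """Per-seed morphology scattered around the population means (the study
    measured 30 seeds per population and analysed individual seeds)."""
    rng = np.random.default_rng((config.rng_seed, 1))
    within_sd = {
        "seed_mass": 1.5, "seed_length": 0.4, "fruit_width": 0.15,
        "fruit_length": 1.0, "awn_length": 2.0, "awn_angle": 4.0,
        "awn_contact": 0.05, "pct_hairiness": 5.0, "hair_length": 0.15,
    }
    records = []
    for pop in pops:
        for s in range(config.n_seeds_measured):
            vals = {}
            for t in CONTINUOUS_TRAITS:
                v = pop.trait_means[t] + rng.normal(0.0, within_sd[t])
                if t == "awn_contact":
                    v = float(np.clip(v, 0.0, 1.0))
                vals[t] = max(float(v), 0.0)
            records.append(
                SeedTraitRecord(
                    population_id=pop.meta.population_id,
                    seed_id=f"{pop.meta.population_id}_s{s + 1:02d}",
                    colour=pop.colour,
                    **vals,
                )
            )
    return records


def simulate_counts(
    pop: TruePopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[GerminationExperiment]:
    """Generate count experiments for one population at every temperature.

    The dish rate is r = Rmax * f(T) times a shared multiplicative noise
    term per population x temperature (SD ``noise_sd_rate``).  Viable seeds
    (probability ``viability_mean``) draw Weibull germination times; counts
    are censored at the end of the window and accumulated on the 24-h grid.
    In deterministic mode the counts are the exact expected values
    n * viability * CDF(t), as real numbers.
    """
    if rng is None:
        rng = np.random.default_rng((config.rng_seed, 2))
    grid = config.observation_grid
    kappa = config.weibull_shape
    out = []
    for T in config.temperatures:
        r = dent_rate(T, pop.Tb, pop.To, pop.Tc, pop.Rmax)
        if r > 0 and config.noise_sd_rate > 0 and not config.deterministic_counts:
            r *= max(1.0 + rng.normal(0.0, config.noise_sd_rate), 0.05)
        for rep in range(1, config.n_replicates + 1):
            n = config.n_seeds_per_dish
            if r <= 0:
                counts = np.zeros_like(grid)
            elif config.deterministic_counts:
                t50 = 1.0 / r
                lam = t50 / np.log(2.0) ** (1.0 / kappa)
                cdf = 1.0 - np.exp(-((grid / lam) ** kappa))
                counts = n * config.viability_mean * cdf
            else:
                t50 = 1.0 / r
                lam = t50 / np.log(2.0) ** (1.0 / kappa)
                viable = rng.random(n) < config.viability_mean
                times = lam * rng.weibull(kappa, size=n)
                times[~viable] = np.inf
                counts = (times[None, :] <= grid[:, None]).sum(axis=1).astype(float)
            out.append(
                GerminationExperiment(
                    population_id=pop.meta.population_id,
                    temperature=float(T),
                    replicate=rep,
                    times=grid.copy(),
                    cumulative_counts=counts,
                    n_seeds=float(n),
                )
            )
    return out


def simulate_study(config: SimulationConfig) -> dict:
    """Run the full generator: populations, seed records, count experiments
    and the ground-truth table.

    Returns a dict with keys ``populations`` (list of TruePopulation),
    ``experiments`` (list of GerminationExperiment), ``seed_records``,
    and ``truth`` (DataFrame population_id, true_Tb, true_To, true_Tc,
    true_Rmax, colour).
    """
    pops = simulate_populations(config)
    records = simulate_seed_records(pops, config)
    rng = np.random.default_rng((config.rng_seed, 2))
    experiments: list[GerminationExperiment] = []
    for pop in pops:
        experiments.extend(simulate_counts(pop, config, rng=rng))
    truth = pd.DataFrame(
        {
            "population_id": [p.meta.population_id for p in pops],
            "true_Tb": [p.Tb for p in pops],
            "true_To": [p.To for p in pops],
            "true_Tc": [p.Tc for p in pops],
            "true_Rmax": [p.Rmax for p in pops],
            "colour": [p.colour for p in pops],
        }
    )
    return {
        "populations": pops,
        "seed_records": records,
        "experiments": experiments,
        "truth": truth,
    }
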