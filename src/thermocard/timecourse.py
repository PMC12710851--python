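"""Germination time-courses: CGF curves, Weibull fits, T50 and GR50.

The cumulative germination fraction at time t is CGF_t = N_t / N_total
(cumulative germinated over total seeds tested).  Each population x
temperature curve is described by a three-parameter Weibull rise

    g(t) = g_max * (1 - exp(-(t / lambda)^kappa))

whose asymptote g_max is the final germination fraction.  The time to half
of the final CGF has the closed form T50 = lambda * (ln 2)^(1/kappa), and
GR50 = 1/T50 is the germination rate passed on to the cardinal-temperature
fit.  Dishes that barely germinate (final pooled CGF below a threshold,
default 0.1) are marked unusable: T50 of a near-flat curve is not
identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data_model import GerminationExperiment

#: Multi-start shape values for the Weibull fit.
KAPPA_STARTS = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class CGFSeries:
    """Cumulative germination fraction curve for one dish (or pooled dishes)."""

    times: np.ndarray
    cgf: np.ndarray
    n_seeds: float
    population_id: str
    temperature: float
    replicate: str  # replicate index as text, or "pooled"


@dataclass
class WeibullFit:
    g_max: float
    lam: float  # scale, hours
    kappa: float  # shape
    rss: float
    converged: bool
    usable: bool = True
    reason: str = ""


@dataclass
class RateEstimate:
    population_id: str
    temperature: float
    t50: float
    gr50: float
    usable: bool
    reason: str = ""


def compute_cgf(
    experiments: GerminationExperiment | Sequence[GerminationExperiment],
    pool_replicates: bool = True,
) -> CGFSeries:
    """CGF_t = N_t / N_total; pooling sums counts and seeds across replicates
    of one population x temperature before dividing."""
    if isinstance(experiments, GerminationExperiment):
        experiments = [experiments]
    if not experiments:
        raise ValueError("no experiments given")
    first = experiments[0]
    if len(experiments) == 1:
        e = first
        if e.n_seeds == 0:
            raise ValueError("n_seeds is zero")
        return CGFSeries(
            times=e.times.copy(),
            cgf=e.cumulative_counts / e.n_seeds,
            n_seeds=e.n_seeds,
            population_id=e.population_id,
            temperature=e.temperature,
            replicate=str(e.replicate),
        )
    if not pool_replicates:
        raise ValueError("multiple experiments require pool_replicates=True")
    for e in experiments[1:]:
        if (
            e.population_id != first.population_id
            or e.temperature != first.temperature
            or not np.array_equal(e.times, first.times)
        ):
            raise ValueError("can only pool replicates sharing population, "
                             "temperature and observation times")
    total_counts = np.sum([e.cumulative_counts for e in experiments], axis=0)
    total_seeds = float(np.sum([e.n_seeds for e in experiments]))
    if total_seeds == 0:
        raise ValueError("n_seeds is zero")
    return CGFSeries(
        times=first.times.copy(),
        cgf=total_counts / total_seeds,
        n_seeds=total_seeds,
        population_id=first.population_id,
        temperature=first.temperature,
        replicate="pooled",
    )


def weibull_cgf(t, g_max: float, lam: float, kappa: float):
    """The fitted time-course model g(t) = g_max (1 - exp(-(t/lam)^kappa))."""
    t = np.asarray(t, dtype=float)
    return g_max * (1.0 - np.exp(-((t / lam) ** kappa)))


def fit_weibull(series: CGFSeries) -> WeibullFit:
    """Least-squares Weibull fit with multi-start over the shape parameter.

    Starts: kappa in {0.5, 1, 2, 4, 8}; lambda at the first observation time
    where the curve reaches half its final value; g_max at the observed final
    CGF.  Returns the best local optimum.  A curve with zero final CGF is
    flagged unusable, and non-convergence from all starts is flagged rather
    than raised.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.cgf, dtype=float)
    if t.size < 4:
        return WeibullFit(np.nan, np.nan, np.nan, np.nan, False, False,
                          "fewer than 4 time points")
    g_obs = float(y[-1])
    if g_obs <= 0:
        return WeibullFit(np.nan, np.nan, np.nan, np.nan, False, False,
                          "no germination (final CGF = 0)")
    reached = t[y >= g_obs / 2]
    lam0 = float(reached[0]) if reached.size else float(t[-1])

    def resid(p):
        return weibull_cgf(t, *p) - y

    lo = np.array([1e-6, 1e-3, 0.05])
    hi = np.array([1.0, 1e6, 60.0])
    best = None
    for k0 in KAPPA_STARTS:
        p0 = np.clip(np.array([g_obs, lam0, k0]), lo, hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # numerical failure from this start only
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return WeibullFit(np.nan, np.nan, np.nan, np.nan, False, False,
                          "optimizer failed from all starts")
    rss, sol = best
    g_max, lam, kappa = (float(v) for v in sol.x)
    return WeibullFit(g_max=g_max, lam=lam, kappa=kappa, rss=rss,
                      converged=bool(sol.success), usable=True)


def t50_gr50(
    fit: WeibullFit, population_id: str = "", temperature: float = np.nan
) -> RateEstimate:
    """T50 = lambda (ln 2)^(1/kappa) — the time at which the curve reaches
    half of its fitted asymptote g_max — and GR50 = 1/T50."""
    if not fit.usable:
        return RateEstimate(population_id, temperature, np.nan, np.nan, False,
                            fit.reason or "unusable fit")
    t50 = fit.lam * np.log(2.0) ** (1.0 / fit.kappa)
    return RateEstimate(population_id, temperature, float(t50), float(1.0 / t50),
                        True)


def estimate_rates(
    experiments: Iterable[GerminationExperiment],
    pool_replicates: bool = True,
    min_final_cgf: float = 0.1,
) -> pd.DataFrame:
    """Full time-course stage: group experiments by population x temperature,
    pool replicates (default), fit the Weibull, and tabulate T50/GR50.

    Curves whose final pooled CGF is below ``min_final_cgf`` are marked
    unusable and excluded from cardinal fitting downstream.
    """
    groups: dict[tuple[str, float], list[GerminationExperiment]] = {}
    for e in experiments:
        groups.setdefault((e.population_id, e.temperature), []).append(e)
    rows = []
    for (pop, temp), exps in sorted(groups.items()):
        if pool_replicates:
            series_list = [compute_cgf(exps, pool_replicates=True)]
        else:
            series_list = [compute_cgf(e) for e in exps]
        for series in series_list:
            final = float(series.cgf[-1])
            if final < min_final_cgf:
                fit = WeibullFit(np.nan, np.nan, np.nan, np.nan, False, False,
                                 f"final CGF {final:.3f} < {min_final_cgf}")
            else:
                fit = fit_weibull(series)
            est = t50_gr50(fit, pop, temp)
            rows.append(
                {
                    "population_id": pop,
                    "temperature": temp,
                    "replicate": series.replicate,
                    "t50_h": est.t50,
                    "gr50_per_h": est.gr50,
                    "gmax": fit.g_max,
                    "lambda": fit.lam,
                    "kappa": fit.kappa,
                    "rss": fit.rss,
                    "usable": est.usable,
                    "reason": est.reason,
                }
            )
    return pd.DataFrame(rows)
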