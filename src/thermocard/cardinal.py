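"""Segmented ("Dent-like") cardinal-temperature model of germination rate.

The germination rate GR50 as a function of temperature T is modelled as a
triangular piecewise-linear response with three cardinal temperatures —
base (Tb), optimum (To) and ceiling (Tc) — scaled by the maximum rate Rmax:

    GR50(T) = Rmax * f(T),   f(T) = (T - Tb)/(To - Tb)   for Tb < T <= To
                             f(T) = (Tc - T)/(Tc - To)   for To < T < Tc
                             f(T) = 0                    for T <= Tb or T >= Tc

so the rate rises linearly from zero at Tb to Rmax at To and falls linearly
back to zero at Tc.  The thermal germination range is TGR = Tc - Tb.

An alternative supra-optimal branch 1 - (Tc - T)/(Tc - To) is available via
``supra="inverted"`` for forensic comparison only: it is zero at To and
maximal at Tc, i.e. it makes To a minimum, not an optimum.

Fitting is least squares over (Tb, To, Tc) with Rmax profiled analytically,
started from an exhaustive coarse grid and polished with Nelder-Mead (the
objective is piecewise-smooth, so derivative-free polishing is the robust
choice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize


@dataclass
class CardinalFit:
    """Fitted cardinal temperatures for one population."""

    population_id: str
    Tb: float
    To: float
    Tc: float
    Rmax: float
    TGR: float
    r_squared: float
    rmse: float
    n_points: int
    converged: bool
    reason: str = ""


def dent_rate(
    T,
    Tb: float,
    To: float,
    Tc: float,
    Rmax: float,
    supra: str = "corrected",
):
    """Evaluate the segmented rate model at temperature(s) ``T``.

    Parameters must satisfy Tb < To < Tc and Rmax >= 0.  ``supra`` selects
    the supra-optimal branch: ``"corrected"`` (decreasing from Rmax at To to
    0 at Tc, the default) or ``"inverted"`` (the increasing variant, kept
    only for comparison).
    """
    if not (Tb < To < Tc):
        raise ValueError(f"cardinal ordering violated: Tb={Tb}, To={To}, Tc={Tc}")
    if Rmax < 0:
        raise ValueError(f"Rmax must be >= 0, got {Rmax}")
    if supra not in ("corrected", "inverted"):
        raise ValueError(f"unknown supra branch {supra!r}")
    T = np.asarray(T, dtype=float)
    f = np.zeros_like(T)
    sub = (T > Tb) & (T <= To)
    f[sub] = (T[sub] - Tb) / (To - Tb)
    over = (T > To) & (T < Tc)
    frac = (Tc - T[over]) / (Tc - To)
    f[over] = frac if supra == "corrected" else 1.0 - frac
    out = Rmax * f
    return out if out.ndim else float(out)


def _profiled_rss(f: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Least-squares Rmax given the unit-response values f, and the RSS."""
    denom = float(np.dot(f, f))
    if denom == 0.0:
        rmax = 0.0
    else:
        rmax = max(float(np.dot(f, r)) / denom, 0.0)
    resid = r - rmax * f
    return rmax, float(np.dot(resid, resid))


def _unit_response(T: np.ndarray, Tb, To, Tc) -> np.ndarray:
    """Vectorized f(T) over broadcastable parameter grids (corrected branch)."""
    T = T.reshape((1,) * np.ndim(Tb) + T.shape)
    Tb = np.asarray(Tb)[..., None]
    To = np.asarray(To)[..., None]
    Tc = np.asarray(Tc)[..., None]
    sub = np.where((T > Tb) & (T <= To), (T - Tb) / (To - Tb), 0.0)
    over = np.where((T > To) & (T < Tc), (Tc - T) / (Tc - To), 0.0)
    return sub + over


def fit_cardinal(
    temperatures: Sequence[float],
    gr50: Sequence[float],
    population_id: str = "",
    grid_step: float = 1.0,
    tc_upper: float = 45.0,
) -> CardinalFit:
    """Fit (Tb, To, Tc, Rmax) to observed (temperature, GR50) points.

    Requires >= 4 points with at least one positive rate.  A coarse grid over
    Tb in [0, min germinating T), To in the observed germinating span, and
    Tc in (max germinating T, ``tc_upper``] locates the best basin (Rmax
    profiled in closed form at every node); Nelder-Mead then polishes.
    Ties in the grid are broken by lowest RSS then lowest Tc.
    """
    T = np.asarray(temperatures, dtype=float)
    r = np.asarray(gr50, dtype=float)
    n = T.size
    nan = float("nan")
    if n < 4:
        return CardinalFit(population_id, nan, nan, nan, nan, nan, nan, nan, n,
                           False, "fewer than 4 usable points")
    if not np.any(r > 0):
        return CardinalFit(population_id, nan, nan, nan, nan, nan, nan, nan, n,
                           False, "no positive rates")
    pos = T[r > 0]
    tmin, tmax = pos.min(), pos.max()
    if np.ptp(r[r > 0]) == 0 and (r > 0).sum() >= 3:
        return CardinalFit(population_id, nan, nan, nan, nan, nan, nan, nan, n,
                           False, "flat positive rates: optimum not identifiable")

    # coarse grid with Rmax profiled
    tb_grid = np.arange(0.0, tmin, grid_step)
    if tb_grid.size == 0:
        tb_grid = np.array([tmin - grid_step])
    to_grid = np.arange(tmin, tmax + 1e-9, grid_step)
    tc_grid = np.arange(tmax + grid_step / 2, tc_upper + 1e-9, grid_step)
    B, O, C = np.meshgrid(tb_grid, to_grid, tc_grid, indexing="ij")
    valid = (B < O) & (O < C)
    f = _unit_response(T, B, O, C)  # (nb, no, nc, n)
    denom = np.einsum("...i,...i->...", f, f)
    num = np.einsum("...i,i->...", f, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmax = np.clip(np.where(denom > 0, num / denom, 0.0), 0.0, None)
    resid = r - rmax[..., None] * f
    rss = np.einsum("...i,...i->...", resid, resid)
    rss = np.where(valid, rss, np.inf)
    # tie-break: lowest RSS, then lowest Tc (C varies fastest in flat order)
    flat_order = np.lexsort((C.ravel(), rss.ravel()))
    best = flat_order[0]
    theta0 = np.array([B.ravel()[best], O.ravel()[best], C.ravel()[best]])

    def objective(theta: np.ndarray) -> float:
        tb, to, tc = theta
        if not (tb < to < tc):
            return 1e12 * (1.0 + abs(tb - to) + abs(to - tc))
        fv = np.zeros_like(T)
        subm = (T > tb) & (T <= to)
        fv[subm] = (T[subm] - tb) / (to - tb)
        overm = (T > to) & (T < tc)
        fv[overm] = (tc - T[overm]) / (tc - to)
        return _profiled_rss(fv, r)[1]

    res = minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000, "maxfev": 8000},
    )
    tb, to, tc = (res.x if res.fun <= objective(theta0) else theta0)
    fv = _unit_response(T, np.array(tb), np.array(to), np.array(tc))[..., :]
    rmax_hat, rss_hat = _profiled_rss(np.ravel(fv), r)
    tss = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - rss_hat / tss if tss > 0 else nan
    return CardinalFit(
        population_id=population_id,
        Tb=float(tb),
        To=float(to),
        Tc=float(tc),
        Rmax=rmax_hat,
        TGR=float(tc) - float(tb),
        r_squared=r2,
        rmse=float(np.sqrt(rss_hat / n)),
        n_points=n,
        converged=bool(res.success or res.fun < 1e-20),
    )


def fit_cardinal_table(
    rates: pd.DataFrame,
    grid_step: float = 1.0,
    include_boundary_zeros: bool = False,
) -> pd.DataFrame:
    """Fit the segmented model for every population in a rates table.

    ``rates`` needs columns ``population_id, temperature, gr50_per_h, usable``.
    Unusable temperatures contribute nothing by default; with
    ``include_boundary_zeros`` unusable temperatures lying outside the
    observed germinating span enter as explicit zero rates.
    """
    fits = []
    for pop, g in rates.groupby("population_id", sort=True):
        ok = g[g["usable"].astype(bool)]
        T = ok["temperature"].to_numpy(dtype=float)
        r = ok["gr50_per_h"].to_numpy(dtype=float)
        if include_boundary_zeros and len(T):
            out = g[~g["usable"].astype(bool)]
            outside = out[
                (out["temperature"] < T.min()) | (out["temperature"] > T.max())
            ]
            T = np.concatenate([T, outside["temperature"].to_numpy(dtype=float)])
            r = np.concatenate([r, np.zeros(len(outside))])
        fit = fit_cardinal(T, r, population_id=str(pop), grid_step=grid_step)
        fits.append(fit.__dict__)
    return pd.DataFrame(fits)


def summarize_cardinal(
    fits: pd.DataFrame,
    parameters: Sequence[str] = ("Tb", "To", "Tc", "Rmax", "TGR"),
) -> pd.DataFrame:
    """Mean, sample SD (n-1), min and max per cardinal parameter over
    converged fits — the distribution summary reported alongside the
    per-parameter histograms."""
    conv = fits[fits["converged"].astype(bool)]
    if conv.empty:
        raise ValueError("no converged fits to summarize")
    rows = []
    for p in parameters:
        v = conv[p].to_numpy(dtype=float)
        rows.append(
            {
                "parameter": p,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "min": float(v.min()),
                "max": float(v.max()),
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def cardinal_histograms(
    fits: pd.DataFrame,
    parameters: Sequence[str] = ("Tb", "To", "Tc", "Rmax"),
    bins: int = 10,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Histogram-ready (counts, bin_edges) per parameter over converged fits."""
    conv = fits[fits["converged"].astype(bool)]
    return {
        p: np.histogram(conv[p].to_numpy(dtype=float), bins=bins)
        for p in parameters
    }
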