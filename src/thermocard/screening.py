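"""Response screening of thermal parameters against seed traits and geography.

Each response (GR50, Tb, To, Tc) is tested against each predictor one pair
at a time: a simple linear-regression slope test (two-sided t) for
continuous predictors, a one-way ANOVA F-test for categorical ones.  The
evidence is reported as the log-worth, -log10(P); pairs with log-worth
strictly above 2 (P < 0.01) are flagged significant.  No multiplicity
correction enters the headline ranking; a Benjamini-Hochberg adjusted
p-value column is emitted for reference only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Log-worth values are capped here to keep underflowing p-values finite.
LOGWORTH_CAP = 300.0
#: Significance threshold on the log-worth scale: 2 = -log10(0.01).
LOGWORTH_THRESHOLD = 2.0


@dataclass
class ScreeningResult:
    response: str
    predictor: str
    kind: str  # "continuous" | "categorical"
    p_value: float
    logworth: float
    significant: bool
    n_obs: int
    valid: bool = True
    note: str = ""


def logworth(p: float) -> float:
    """-log10(p), capped at 300 for underflowing p-values."""
    if p <= 0.0:
        return LOGWORTH_CAP
    return min(-np.log10(p), LOGWORTH_CAP)


def screen_pair(
    y,
    x,
    kind: str,
    response: str = "y",
    predictor: str = "x",
) -> ScreeningResult:
    """Test one response-predictor pair and report its log-worth.

    Zero-variance inputs (or categorical predictors without two adequately
    filled levels) yield an invalid, flagged result rather than an error.
    """
    y = np.asarray(y, dtype=float)
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown predictor kind {kind!r}")

    def invalid(n, note):
        return ScreeningResult(response, predictor, kind, np.nan, np.nan,
                               False, n, valid=False, note=note)

    if kind == "continuous":
        x = np.asarray(x, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = x.size
        if n < 3:
            return invalid(n, "fewer than 3 complete pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return invalid(n, "zero variance")
        res = stats.linregress(x, y)
        p = float(res.pvalue)
    else:
        x = pd.Series(x).astype(str).to_numpy()
        keep = np.isfinite(y)
        x, y = x[keep], y[keep]
        levels, counts = np.unique(x, return_counts=True)
        levels = levels[counts >= 2]  # levels need >= 2 observations
        groups = [y[x == lv] for lv in levels]
        n = int(sum(len(g) for g in groups))
        if len(groups) < 2 or n < 3:
            return invalid(n, "fewer than 2 usable levels")
        if np.ptp(np.concatenate(groups)) == 0:
            return invalid(n, "zero variance")
        if all(np.ptp(g) == 0 for g in groups):
            # group means differ but within-group variance is zero: F -> inf
            p = 0.0
        else:
            p = float(stats.f_oneway(*groups).pvalue)
    lw = logworth(p)
    return ScreeningResult(response, predictor, kind, p, lw,
                           bool(lw > LOGWORTH_THRESHOLD), n)


def screen_all(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    on: str = "population_id",
    response_cols: list[str] | None = None,
    categorical: tuple[str, ...] = ("colour",),
) -> pd.DataFrame:
    """Screen every response x predictor pair after joining on ``on``.

    Returns one row per pair with p-value, log-worth, significance flag, a
    per-response rank (log-worth descending, ties alphabetical by
    predictor), and a BH-adjusted p-value column (reference only).
    """
    merged = responses.merge(predictors, on=on, how="inner")
    if len(merged) < 3:
        raise ValueError(
            f"join on {on!r} produced only {len(merged)} rows; need >= 3"
        )
    if response_cols is None:
        response_cols = [c for c in responses.columns if c != on]
    predictor_cols = [c for c in predictors.columns
                      if c != on and not c.endswith("_tie")
                      and c != "n_seeds_measured"]
    results = []
    for resp in response_cols:
        for pred in predictor_cols:
            kind = "categorical" if pred in categorical else "continuous"
            results.append(
                screen_pair(merged[resp], merged[pred], kind,
                            response=resp, predictor=pred)
            )
    df = pd.DataFrame([r.__dict__ for r in results])
    df["p_fdr_bh"] = np.nan
    ok = df["valid"] & np.isfinite(df["p_value"])
    if ok.any():
        df.loc[ok, "p_fdr_bh"] = stats.false_discovery_control(
            df.loc[ok, "p_value"].to_numpy(), method="bh"
        )
    # rank within each response: log-worth descending, alphabetical ties
    df = df.sort_values(
        ["response", "logworth", "predictor"],
        ascending=[True, False, True],
        na_position="last",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("response").cumcount() + 1
    return df
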