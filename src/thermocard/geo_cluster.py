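"""Geographic structure of thermal traits: clustering and correlation.

Populations are clustered on four thermal germination traits (Tb, Tc, GR50,
TGR) after z-scoring, using agglomerative (Ward, Euclidean) linkage cut at
k groups, with the mean silhouette index as the cohesion/separation
summary.  The eastward cline in thermal breadth is quantified by the
Pearson correlation between TGR and longitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

THERMAL_FEATURES = ("Tb", "Tc", "GR50", "TGR")


@dataclass
class ClusterReport:
    features: tuple[str, ...]
    k: int
    labels: pd.Series  # indexed by population_id
    silhouette: float
    cluster_means: pd.DataFrame
    linkage_matrix: np.ndarray
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False
    note: str = ""


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    pearson_r: float
    p_value: float
    n: int
    valid: bool = True
    note: str = ""


def cluster_thermal(
    fits: pd.DataFrame,
    k: int = 4,
    features: tuple[str, ...] = THERMAL_FEATURES,
    scan_k: tuple[int, int] | None = (2, 8),
) -> ClusterReport:
    """Ward-linkage clustering of populations on z-scored thermal traits.

    ``fits`` needs ``population_id`` plus the feature columns (a ``Rmax``
    column is accepted for ``GR50``: the population germination rate at the
    optimum).  ``scan_k`` optionally reports silhouette for a range of cut
    levels as a diagnostic.
    """
    df = fits.copy()
    if "GR50" in features and "GR50" not in df.columns and "Rmax" in df.columns:
        df["GR50"] = df["Rmax"]
    if "TGR" in features and "TGR" not in df.columns:
        df["TGR"] = df["Tc"] - df["Tb"]
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    df = df.dropna(subset=list(features))
    n = len(df)
    if k > n:
        raise ValueError(f"k={k} exceeds number of populations n={n}")
    X = df[list(features)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        labels = pd.Series(np.ones(n, dtype=int),
                           index=df["population_id"], name="cluster")
        return ClusterReport(features, 1, labels, np.nan,
                             df.head(0), np.empty((0, 4)),
                             degenerate=True, note="all points identical")
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    lk = linkage(Z, method="ward")
    labels = fcluster(lk, t=k, criterion="maxclust")
    sil = (
        float(silhouette_score(Z, labels)) if len(np.unique(labels)) > 1 else np.nan
    )
    means = (
        pd.DataFrame(X, columns=list(features))
        .assign(cluster=labels)
        .groupby("cluster")
        .agg(["mean", "count"])
    )
    means.columns = [
        f"mean_{c}" if s == "mean" else "n" for c, s in means.columns
    ]
    means = means.loc[:, ~means.columns.duplicated()].reset_index()
    scan: dict[int, float] = {}
    if scan_k is not None:
        for kk in range(scan_k[0], min(scan_k[1], n - 1) + 1):
            lab = fcluster(lk, t=kk, criterion="maxclust")
            if len(np.unique(lab)) > 1:
                scan[kk] = float(silhouette_score(Z, lab))
    return ClusterReport(
        features=tuple(features),
        k=k,
        labels=pd.Series(labels, index=df["population_id"], name="cluster"),
        silhouette=sil,
        cluster_means=means,
        linkage_matrix=lk,
        silhouette_by_k=scan,
    )


def correlate(x, y, names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        return CorrelationResult(names, np.nan, np.nan, n, valid=False,
                                 note="fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(names, np.nan, np.nan, n, valid=False,
                                 note="zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(names, float(res.statistic), float(res.pvalue), n)
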