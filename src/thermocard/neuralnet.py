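"""Mixed-activation feed-forward networks for thermal-parameter regression.

A two-hidden-layer network predicts one thermal response (GR50, Tb, To or
Tc) from seed morphology.  Each hidden node applies one of three
activations to its affine input z = w.x + b:

* TanH:     tanh(z)
* Linear:   z
* Gaussian: exp(-z^2)   (a radial bump, the bounded option)

The output is a linear combination of the second layer.  Inputs and the
response are z-scored on the training split only.  Training is per-sample
stochastic gradient descent on squared error at a fixed learning rate
(default 0.1), with the best-validation-epoch weights retained; a model is
fitted in several independent "tours" from random initial weights and the
tour with minimal validation SSE wins.

Feature preparation follows the study protocol: redundant features
(|Spearman rho| > 0.7) are excluded, colour enters as one-hot indicators,
and rows are split 45/30/25 into training/validation/test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import COLOURS, CONTINUOUS_TRAITS

TANH, LINEAR, GAUSS = 0, 1, 2

#: Printed architecture for the GR50 response: (TanH, Linear, Gaussian)
#: node counts for the first and second hidden layers.
GR50_LAYERS = ((6, 2, 11), (8, 2, 18))


@dataclass
class NetworkSpec:
    """Architecture: per-layer (n_tanh, n_linear, n_gaussian) node counts."""

    layer1: tuple[int, int, int]
    layer2: tuple[int, int, int]
    features: tuple[str, ...]
    response: str

    def __post_init__(self) -> None:
        if sum(self.layer1) < 1 or sum(self.layer2) < 1:
            raise ValueError("each hidden layer needs at least one node")
        if not self.features:
            raise ValueError("feature list must be non-empty")

    def node_types(self, layer: int) -> np.ndarray:
        counts = self.layer1 if layer == 1 else self.layer2
        return np.repeat([TANH, LINEAR, GAUSS], counts)


def _activate(z: np.ndarray, types: np.ndarray) -> np.ndarray:
    a = np.empty_like(z)
    m = types == TANH
    a[..., m] = np.tanh(z[..., m])
    m = types == LINEAR
    a[..., m] = z[..., m]
    m = types == GAUSS
    a[..., m] = np.exp(-np.square(z[..., m]))
    return a


def _activate_prime(z: np.ndarray, a: np.ndarray, types: np.ndarray) -> np.ndarray:
    d = np.empty_like(z)
    m = types == TANH
    d[..., m] = 1.0 - np.square(a[..., m])
    m = types == LINEAR
    d[..., m] = 1.0
    m = types == GAUSS
    d[..., m] = -2.0 * z[..., m] * a[..., m]
    return d


@dataclass
class TrainedNetwork:
    spec: NetworkSpec
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    w_out: np.ndarray
    b_out: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    history: list = field(default_factory=list)  # (epoch, train_sse, val_sse)
    tour: int = 0
    best_val_sse: float = np.inf
    diverged: bool = False

    def _forward_std(self, Xs: np.ndarray) -> np.ndarray:
        """Prediction on the standardized scale for standardized inputs."""
        t1 = self.spec.node_types(1)
        t2 = self.spec.node_types(2)
        Z1 = Xs @ self.W1.T + self.b1
        A1 = _activate(Z1, t1)
        Z2 = A1 @ self.W2.T + self.b2
        A2 = _activate(Z2, t2)
        return A2 @ self.w_out + self.b_out

    def predict(self, X) -> np.ndarray:
        """De-standardized predictions for raw feature rows (n x d)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.spec.features):
            raise ValueError(
                f"expected {len(self.spec.features)} features, got {X.shape[1]}"
            )
        Xs = (X - self.x_mean) / self.x_sd
        return self._forward_std(Xs) * self.y_sd + self.y_mean


def forward(net: TrainedNetwork, x) -> float:
    """Single-vector prediction on the response scale."""
    return float(net.predict(np.asarray(x, dtype=float).reshape(1, -1))[0])


def loss_and_grads(
    net: TrainedNetwork, x_std: np.ndarray, y_std: float
) -> tuple[float, dict[str, np.ndarray]]:
    """Squared-error loss 0.5 (yhat - y)^2 and analytic gradients for one
    standardized sample.  Exposed for gradient verification."""
    t1 = net.spec.node_types(1)
    t2 = net.spec.node_types(2)
    z1 = net.W1 @ x_std + net.b1
    a1 = _activate(z1, t1)
    z2 = net.W2 @ a1 + net.b2
    a2 = _activate(z2, t2)
    yhat = float(net.w_out @ a2 + net.b_out)
    e = yhat - y_std
    loss = 0.5 * e * e
    g_w_out = e * a2
    g_b_out = e
    d_z2 = (e * net.w_out) * _activate_prime(z2, a2, t2)
    g_W2 = np.outer(d_z2, a1)
    g_b2 = d_z2
    d_z1 = (net.W2.T @ d_z2) * _activate_prime(z1, a1, t1)
    g_W1 = np.outer(d_z1, x_std)
    g_b1 = d_z1
    return loss, {
        "W1": g_W1, "b1": g_b1, "W2": g_W2, "b2": g_b2,
        "w_out": g_w_out, "b_out": np.array(g_b_out),
    }


def _init_network(
    spec: NetworkSpec,
    x_mean: np.ndarray,
    x_sd: np.ndarray,
    y_mean: float,
    y_sd: float,
    rng: np.random.Generator,
    init_scale: float = 0.3,
) -> TrainedNetwork:
    d = len(spec.features)
    h1, h2 = sum(spec.layer1), sum(spec.layer2)
    u = lambda *shape: rng.uniform(-init_scale, init_scale, size=shape)
    return TrainedNetwork(
        spec=spec,
        W1=u(h1, d), b1=u(h1),
        W2=u(h2, h1), b2=u(h2),
        w_out=u(h2), b_out=float(u(1)[0]),
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
    )


def train(
    spec: NetworkSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 0.1,
    epochs: int = 500,
    seed=0,
    init_scale: float = 0.3,
) -> TrainedNetwork:
    """Train one network by per-sample SGD at a fixed learning rate.

    Standardization constants come from the training split only.  The
    weights from the epoch with minimal validation SSE (including the
    initial weights at epoch 0) are retained.  A non-finite loss aborts the
    tour and marks the returned network diverged.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    x_mean = X_train.mean(axis=0)
    x_sd = X_train.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean = float(y_train.mean())
    y_sd = float(y_train.std()) or 1.0
    Xs = (X_train - x_mean) / x_sd
    ys = (y_train - y_mean) / y_sd
    Xvs = (X_val - x_mean) / x_sd
    yvs = (y_val - y_mean) / y_sd

    net = _init_network(spec, x_mean, x_sd, y_mean, y_sd, rng, init_scale)
    n = len(Xs)

    def val_sse() -> float:
        r = net._forward_std(Xvs) - yvs
        return float(r @ r)

    def snapshot() -> dict:
        return {k: np.copy(getattr(net, k))
                for k in ("W1", "b1", "W2", "b2", "w_out")} | {
                    "b_out": net.b_out}

    best = snapshot()
    best_sse = val_sse()
    net.history.append((0, np.nan, best_sse))
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        train_sse = 0.0
        for i in order:
            loss, g = loss_and_grads(net, Xs[i], ys[i])
            train_sse += 2.0 * loss
            net.W1 -= lr * g["W1"]
            net.b1 -= lr * g["b1"]
            net.W2 -= lr * g["W2"]
            net.b2 -= lr * g["b2"]
            net.w_out -= lr * g["w_out"]
            net.b_out -= lr * float(g["b_out"])
        if not np.isfinite(train_sse):
            net.diverged = True
            break
        sse = val_sse()
        net.history.append((epoch, train_sse, sse))
        if sse < best_sse:
            best_sse = sse
            best = snapshot()
    for k, v in best.items():
        setattr(net, k, v)
    net.best_val_sse = best_sse
    return net


def multi_tour(
    spec: NetworkSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    tours: int = 10,
    lr: float = 0.1,
    epochs: int = 500,
    seed=0,
    init_scale: float = 0.3,
) -> TrainedNetwork:
    """Run independent training tours from random initial weights and keep
    the tour with minimal validation SSE (ties: lowest tour index)."""
    best: TrainedNetwork | None = None
    for tour in range(tours):
        net = train(spec, X_train, y_train, X_val, y_val, lr=lr,
                    epochs=epochs, seed=(seed, tour), init_scale=init_scale)
        net.tour = tour
        if net.diverged:
            warnings.warn(f"tour {tour} diverged; abandoned")
            continue
        if best is None or net.best_val_sse < best.best_val_sse:
            best = net
    if best is None:
        raise RuntimeError("all training tours diverged")
    return best


@dataclass
class FitMetrics:
    r_squared: float
    rase: float
    mad: float
    sse: float
    negative_log_likelihood: float
    n: int
    valid: bool = True
    note: str = ""


def evaluate(net: TrainedNetwork, X, y) -> FitMetrics:
    """Goodness-of-fit metrics on the response scale: R^2, RASE =
    sqrt(SSE/n), MAD, SSE, and the Gaussian negative log-likelihood with
    variance SSE/n."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 rows to evaluate")
    resid = net.predict(X) - y
    sse = float(resid @ resid)
    rase = float(np.sqrt(sse / n))
    mad = float(np.abs(resid).mean())
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return FitMetrics(np.nan, rase, mad, sse, np.nan, n, valid=False,
                          note="zero response variance")
    r2 = 1.0 - sse / tss
    sigma2 = sse / n
    nll = (
        0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
        if sigma2 > 0 else float("-inf")
    )
    return FitMetrics(r2, rase, mad, sse, nll, n)


# ---------------------------------------------------------------------------
# feature preparation and the study protocol
# ---------------------------------------------------------------------------


def spearman_filter(
    features: pd.DataFrame, threshold: float = 0.7
) -> tuple[list[str], list[dict]]:
    """Drop redundant features with pairwise |Spearman rho| > threshold.

    Offending pairs are resolved from the strongest correlation down; the
    member with the larger mean absolute correlation to all other features
    is dropped (ties: the lexicographically later name).  Constant features
    are dropped up front with a warning.
    """
    cols = list(features.columns)
    if len(cols) < 2 or len(features) < 3:
        raise ValueError("need >= 2 features and >= 3 rows")
    dropped: list[dict] = []
    const = [c for c in cols if features[c].nunique() <= 1]
    for c in const:
        warnings.warn(f"feature {c!r} is constant; dropped (rho undefined)")
        dropped.append({"dropped": c, "kept": None, "rho": np.nan,
                        "why": "constant"})
    cols = [c for c in cols if c not in const]
    if len(cols) < 2:
        return cols, dropped
    sp = stats.spearmanr(features[cols].to_numpy())
    mat = np.atleast_2d(np.asarray(sp.statistic, dtype=float))
    if mat.shape != (len(cols), len(cols)):  # spearmanr scalar for 2 columns
        r = float(mat.ravel()[0])
        mat = np.array([[1.0, r], [r, 1.0]])
    rho = pd.DataFrame(mat, index=cols, columns=cols)
    pairs = [
        (abs(rho.iloc[i, j]), cols[i], cols[j])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(rho.iloc[i, j]) > threshold
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    retained = set(cols)
    mean_abs = rho.abs().where(~np.eye(len(cols), dtype=bool)).mean()
    for r, a, b in pairs:
        if a in retained and b in retained:
            drop = b if (mean_abs[b], b) >= (mean_abs[a], a) else a
            keep = a if drop == b else b
            retained.discard(drop)
            dropped.append({"dropped": drop, "kept": keep, "rho": r,
                            "why": f"|rho|>{threshold}"})
    return [c for c in cols if c in retained], dropped


def split_data(
    n: int,
    fractions: tuple[float, float, float] = (0.45, 0.30, 0.25),
    seed=0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 45/30/25 train/validation/test partition by seeded shuffle.

    Validation and test sizes are floor(n * fraction); the remainder goes to
    training.  Returns (train_idx, val_idx, test_idx), disjoint and
    exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n < 10:
        raise ValueError(f"need n >= 10 rows to split, got {n}")
    n_val = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n)
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train:n_train + n_val]),
        np.sort(perm[n_train + n_val:]),
    )


def build_feature_table(
    traits: pd.DataFrame,
    spearman_threshold: float = 0.7,
    extra_continuous: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, list[str], list[dict]]:
    """Numeric model matrix from a population-level trait table.

    Continuous traits pass the Spearman redundancy filter; colour becomes
    one-hot indicators over the full category set (so feature layout does
    not depend on which colours happen to occur).
    """
    cont = [c for c in CONTINUOUS_TRAITS if c in traits.columns]
    cont += [c for c in extra_continuous if c in traits.columns]
    retained, report = spearman_filter(traits[cont], spearman_threshold)
    X = traits[["population_id"] + retained].copy()
    if "colour" in traits.columns:
        for colour in COLOURS:
            X[f"colour_{colour}"] = (traits["colour"] == colour).astype(float)
    return X, retained, report


def train_response_network(
    cardinal: pd.DataFrame,
    traits: pd.DataFrame,
    response: str,
    layers: tuple[tuple[int, int, int], tuple[int, int, int]] = GR50_LAYERS,
    tours: int = 10,
    epochs: int = 300,
    lr: float = 0.1,
    seed=0,
    spearman_threshold: float = 0.7,
    include_geo_from: pd.DataFrame | None = None,
) -> dict:
    """Full protocol for one response: join thermal parameters to traits,
    filter features, split 45/30/25, run tours, evaluate per split.

    Returns a dict with ``net``, ``metrics`` (per split), ``predictions``
    (DataFrame), ``features`` and ``dropped``.
    """
    df = cardinal.merge(traits, on="population_id", how="inner")
    extra: tuple[str, ...] = ()
    if include_geo_from is not None:
        df = df.merge(include_geo_from, on="population_id", how="inner")
        extra = ("latitude", "longitude", "altitude")
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not present after join")
    df = df.dropna(subset=[response]).reset_index(drop=True)
    X_df, retained, report = build_feature_table(
        df, spearman_threshold, extra_continuous=extra
    )
    feat_cols = [c for c in X_df.columns if c != "population_id"]
    X = X_df[feat_cols].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    tr, va, te = split_data(len(df), seed=(seed, 17))
    spec = NetworkSpec(layer1=layers[0], layer2=layers[1],
                       features=tuple(feat_cols), response=response)
    net = multi_tour(spec, X[tr], y[tr], X[va], y[va], tours=tours,
                     lr=lr, epochs=epochs, seed=(seed, 23))
    metrics = {
        "train": evaluate(net, X[tr], y[tr]),
        "validation": evaluate(net, X[va], y[va]),
        "test": evaluate(net, X[te], y[te]),
    }
    split_label = np.empty(len(df), dtype=object)
    split_label[tr], split_label[va], split_label[te] = "train", "validation", "test"
    predictions = pd.DataFrame(
        {
            "population_id": df["population_id"],
            "observed": y,
            "predicted": net.predict(X),
            "split": split_label,
        }
    )
    return {
        "net": net,
        "metrics": metrics,
        "predictions": predictions,
        "features": feat_cols,
        "dropped": report,
    }


# ---------------------------------------------------------------------------
# model persistence (version-tagged JSON)
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def save_model(net: TrainedNetwork, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": {
            "layer1": list(net.spec.layer1),
            "layer2": list(net.spec.layer2),
            "features": list(net.spec.features),
            "response": net.spec.response,
        },
        "weights": {
            "W1": net.W1.tolist(), "b1": net.b1.tolist(),
            "W2": net.W2.tolist(), "b2": net.b2.tolist(),
            "w_out": net.w_out.tolist(), "b_out": net.b_out,
        },
        "standardization": {
            "x_mean": net.x_mean.tolist(), "x_sd": net.x_sd.tolist(),
            "y_mean": net.y_mean, "y_sd": net.y_sd,
        },
        "tour": net.tour,
        "best_val_sse": net.best_val_sse,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> TrainedNetwork:
    d = json.loads(Path(path).read_text())
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {d.get('format_version')}")
    spec = NetworkSpec(
        layer1=tuple(d["spec"]["layer1"]),
        layer2=tuple(d["spec"]["layer2"]),
        features=tuple(d["spec"]["features"]),
        response=d["spec"]["response"],
    )
    w = d["weights"]
    s = d["standardization"]
    return TrainedNetwork(
        spec=spec,
        W1=np.array(w["W1"]), b1=np.array(w["b1"]),
        W2=np.array(w["W2"]), b2=np.array(w["b2"]),
        w_out=np.array(w["w_out"]), b_out=float(w["b_out"]),
        x_mean=np.array(s["x_mean"]), x_sd=np.array(s["x_sd"]),
        y_mean=float(s["y_mean"]), y_sd=float(s["y_sd"]),
        tour=int(d["tour"]),
        best_val_sse=float(d["best_val_sse"]),
    )
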