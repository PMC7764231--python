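"""Neural AOD-to-PM2.5 retrieval.

A three-layer back-propagation network (BPNN) maps nine predictors —
longitude, latitude, day-of-year, AOD, and five meteorological variables
(RH, TEMP, WS, SP, HPBL) — to surface PM2.5.  The default hidden layer has
18 nodes; a classical heuristic places the optimum between ``2 + mu`` and
``2n + 1`` nodes (n = 9 inputs, mu = 1 output), so sizes outside [2, 19]
draw a warning but are not rejected.

Architecture and training follow the common regression-MLP recipe: z-score
normalisation of inputs and label, tanh hidden activation, linear output,
full-batch gradient descent with momentum, early stopping on relative loss
change.  Training is bit-deterministic given a seed.

Goodness of fit is summarised by the Pearson correlation R between observed
and retrieved concentrations and the root-mean-square error

    RMSE = sqrt( (1/n) * sum_i (y_i - y_i')^2 )

and predictive skill by sample-based 10-fold cross-validation: samples are
split randomly into ten folds of near-equal size, each fold is predicted by
a model trained on the other nine, and R/RMSE are computed on the pooled
out-of-fold predictions.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GridField, UNITS

__all__ = [
    "FEATURES",
    "FitMetrics",
    "RetrievalModel",
    "pearson_r",
    "rmse",
    "train",
    "predict",
    "predict_grid",
    "cross_validate",
    "kfold_indices",
    "grid_feature_table",
]

#: predictor columns, in network input order
FEATURES = ("lon", "lat", "doy", "aod", "rh", "temp", "ws", "sp", "hpbl")

#: heuristic bounds on the hidden layer size for 9 inputs / 1 output
HIDDEN_RANGE = (2, 19)


class DegenerateInputError(ValueError):
    """Input vectors carry no usable variation."""


# ---------------------------------------------------------------------------
# validation metrics


def _as_vectors(observed, predicted, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} vs {p.size}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} values, got {y.size}")
    return y, p


def pearson_r(observed, predicted) -> float:
    """Pearson product-moment correlation between two equal-length vectors."""
    y, p = _as_vectors(observed, predicted, min_len=2)
    yc = y - y.mean()
    pc = p - p.mean()
    denom = np.sqrt((yc * yc).sum() * (pc * pc).sum())
    if denom == 0.0:
        raise DegenerateInputError("zero variance: correlation undefined")
    return float(np.clip((yc * pc).sum() / denom, -1.0, 1.0))


def rmse(observed, predicted) -> float:
    """Root-mean-square error, in the units of the inputs (ug/m3 here)."""
    y, p = _as_vectors(observed, predicted, min_len=1)
    return float(np.sqrt(np.mean((y - p) ** 2)))


@dataclass(frozen=True)
class FitMetrics:
    r: float
    rmse: float
    n: int


# ---------------------------------------------------------------------------
# model


@dataclass
class RetrievalModel:
    """Weights and normalisation constants of the 9 -> hidden -> 1 network."""

    w1: np.ndarray  # (9, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray  # (9,)
    x_scale: np.ndarray  # (9,)
    y_mean: float
    y_scale: float
    hidden_activation: str = "tanh"
    training_log: dict = field(default_factory=dict)

    @property
    def hidden_nodes(self) -> int:
        return self.w1.shape[1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Raw (unclamped) prediction for a (n, 9) feature matrix."""
        Z = (X - self.x_mean) / self.x_scale
        H = np.tanh(Z @ self.w1 + self.b1)
        out = H @ self.w2 + self.b2
        return out * self.y_scale + self.y_mean

    def to_json(self, path) -> None:
        doc = {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "hidden_activation": self.hidden_activation,
            "features": list(FEATURES),
            "training_log": self.training_log,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RetrievalModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            w1=np.array(doc["w1"], dtype=float),
            b1=np.array(doc["b1"], dtype=float),
            w2=np.array(doc["w2"], dtype=float),
            b2=float(doc["b2"]),
            x_mean=np.array(doc["x_mean"], dtype=float),
            x_scale=np.array(doc["x_scale"], dtype=float),
            y_mean=float(doc["y_mean"]),
            y_scale=float(doc["y_scale"]),
            hidden_activation=doc.get("hidden_activation", "tanh"),
            training_log=doc.get("training_log", {}),
        )


def _feature_matrix(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURES if c not in samples.columns]
    if missing:
        raise ValueError(f"samples lack predictor columns: {missing}")
    X = samples.loc[:, list(FEATURES)].to_numpy(dtype=float)
    y = samples["pm25"].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("training samples must have no missing predictors or labels")
    return X, y


def train(
    samples: pd.DataFrame,
    hidden_nodes: int = 18,
    seed: int = 0,
    learning_rate: float = 0.1,
    momentum: float = 0.9,
    max_epochs: int = 5000,
    tol: float = 1e-6,
    patience: int = 10,
    min_samples: int = 100,
) -> RetrievalModel:
    """Fit the retrieval network by full-batch gradient descent with momentum.

    ``samples`` must carry the nine predictor columns plus a ``pm25`` label.
    Training stops when the relative MSE change stays below ``tol`` for
    ``patience`` consecutive epochs, or at ``max_epochs``.
    """
    X, y = _feature_matrix(samples)
    n = X.shape[0]
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {n}")
    if y.std() == 0.0:
        raise DegenerateInputError("constant label vector")
    lo, hi = HIDDEN_RANGE
    if not lo <= hidden_nodes <= hi:
        warnings.warn(
            f"hidden_nodes={hidden_nodes} outside the heuristic range [{lo}, {hi}]",
            stacklevel=2,
        )

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0.0] = 1.0  # constant predictors carry no signal
    y_mean = float(y.mean())
    y_scale = float(y.std())
    Z = (X - x_mean) / x_scale
    t = (y - y_mean) / y_scale

    rng = np.random.default_rng(seed)
    h = hidden_nodes
    w1 = rng.normal(0.0, np.sqrt(1.0 / Z.shape[1]), size=(Z.shape[1], h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(1.0 / h), size=h)
    b2 = 0.0
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = 0.0

    prev_loss = np.inf
    calm = 0
    epoch = 0
    loss = np.inf
    for epoch in range(1, max_epochs + 1):
        A = Z @ w1 + b1
        H = np.tanh(A)
        out = H @ w2 + b2
        err = out - t
        loss = float(np.mean(err**2))

        # backprop of the full-batch MSE
        g_out = 2.0 * err / n
        g_w2 = H.T @ g_out
        g_b2 = float(g_out.sum())
        g_h = np.outer(g_out, w2) * (1.0 - H**2)
        g_w1 = Z.T @ g_h
        g_b1 = g_h.sum(axis=0)

        v_w1 = momentum * v_w1 - learning_rate * g_w1
        v_b1 = momentum * v_b1 - learning_rate * g_b1
        v_w2 = momentum * v_w2 - learning_rate * g_w2
        v_b2 = momentum * v_b2 - learning_rate * g_b2
        w1 += v_w1
        b1 += v_b1
        w2 += v_w2
        b2 += v_b2

        if prev_loss < np.inf and abs(prev_loss - loss) <= tol * max(prev_loss, 1e-12):
            calm += 1
            if calm >= patience:
                break
        else:
            calm = 0
        prev_loss = loss

    return RetrievalModel(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        training_log={"epochs": epoch, "final_loss": loss, "seed": seed},
    )


# ---------------------------------------------------------------------------
# prediction


def predict(model: RetrievalModel, features) -> np.ndarray:
    """PM2.5 (ug/m3, clamped at 0) for a record table or (n, 9) matrix.

    Rows with any missing predictor yield NaN.
    """
    if isinstance(features, pd.DataFrame):
        X = features.loc[:, list(FEATURES)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.w1.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"input size {model.w1.shape[0]}"
        )
    ok = ~np.isnan(X).any(axis=1)
    out = np.full(X.shape[0], np.nan)
    if ok.any():
        out[ok] = np.maximum(model.forward(X[ok]), 0.0)
    return out


def grid_feature_table(fields: dict[str, GridField]) -> pd.DataFrame:
    """Flatten one day's predictor grids into a per-pixel feature table.

    ``fields`` maps lower-case predictor names (aod, rh, temp, ws, sp, hpbl)
    to same-geometry :class:`GridField` objects; lon/lat/doy are derived
    from the grid coordinates and date.
    """
    names = ("aod", "rh", "temp", "ws", "sp", "hpbl")
    missing = [k for k in names if k not in fields]
    if missing:
        raise ValueError(f"missing predictor grids: {missing}")
    ref = fields["aod"]
    for k in names:
        if not fields[k].same_geometry(ref):
            raise ValueError(f"grid geometry mismatch for {k!r}")
        if fields[k].date != ref.date:
            raise ValueError(f"grid date mismatch for {k!r}")
    lon2d, lat2d = np.meshgrid(ref.lons, ref.lats)
    doy = ref.date.timetuple().tm_yday
    tbl = {
        "lon": lon2d.ravel(),
        "lat": lat2d.ravel(),
        "doy": np.full(lon2d.size, float(doy)),
    }
    for k in names:
        tbl[k] = fields[k].data.ravel()
    return pd.DataFrame(tbl)


def predict_grid(model: RetrievalModel, fields: dict[str, GridField]) -> GridField:
    """Retrieve a daily PM2.5 grid; pixels missing any predictor stay missing."""
    tbl = grid_feature_table(fields)
    values = predict(model, tbl)
    ref = fields["aod"]
    return ref.copy_with(
        values.reshape(ref.data.shape), variable="PM2.5", units=UNITS["PM2.5"]
    )


# ---------------------------------------------------------------------------
# cross-validation


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return list(np.array_split(perm, k))


def cross_validate(
    samples: pd.DataFrame, k: int = 10, seed: int = 0, **train_kwargs
) -> FitMetrics:
    """Pooled out-of-fold R and RMSE from sample-based k-fold validation."""
    X, y = _feature_matrix(samples)  # early validation of completeness
    n = len(samples)
    folds = kfold_indices(n, k, seed=seed)
    pooled = np.full(n, np.nan)
    samples = samples.reset_index(drop=True)
    for fold in folds:
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        model = train(samples[~mask], seed=seed, **train_kwargs)
        pooled[fold] = predict(model, samples.iloc[fold])
    return FitMetrics(r=pearson_r(y, pooled), rmse=rmse(y, pooled), n=n)
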