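"""Comparator models and the benchmark harness.

* plain RBF network ("RBNNA"): farthest-point centers from the training
  inputs, a shared width set to the mean nearest-center distance, output
  layer by linear least squares — the conventional RBF recipe.
* BPNN: one hidden layer of logistic-sigmoid units with a linear output,
  trained by seeded mini-batch gradient descent on squared error with the
  per-epoch step-size schedule lr_e = lr / (1 + decay·e).

The benchmark trains every requested model per seed on identical splits and
identical training-split standardization (fairness contract), evaluates
MAPE/MAE/R² on the validation split in original target units, aggregates by
the median across seeds, and renders the comparison table with
relative-change columns for the hybrid model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import hybrid_trainer, metrics, synthetic
from .data_io import NUTRIENT_COLUMNS, apply_standardization, standardize
from .rbf_network import RBFNetwork, fit_output_layer

__all__ = [
    "BPNNConfig",
    "BPNN",
    "farthest_point_centers",
    "train_plain_rbnna",
    "bpnn_gradients",
    "train_bpnn",
    "BenchmarkResult",
    "run_benchmark",
]


def farthest_point_centers(X: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """Greedy maximin subset of K training rows (seeded random start)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of training rows {n}")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    dmin = cdist(X, X[chosen]).ravel()
    while len(chosen) < K:
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, cdist(X, X[[nxt]]).ravel())
    return X[chosen].copy()


def train_plain_rbnna(X, y, K: int, seed: int = 0) -> RBFNetwork:
    """Conventional RBF fit: maximin centers, shared mean-NN width, LS output."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    centers = farthest_point_centers(X, K, seed=seed)
    if K > 1:
        D = cdist(centers, centers)
        np.fill_diagonal(D, np.inf)
        sigma = float(np.mean(D.min(axis=1)))
    else:
        sigma = float(np.mean(cdist(X, centers)))
    if sigma <= 0 or not np.isfinite(sigma):
        sigma = 1.0
    widths = np.full(K, sigma)
    weights, bias = fit_output_layer(centers, widths, X, y)
    return RBFNetwork(centers, widths, weights, bias)


@dataclass
class BPNNConfig:
    """Backpropagation network hyperparameters (sigmoid hidden, linear output)."""

    hidden: int = 10
    batch: int = 6
    epochs: int = 100
    lr: float = 0.01
    decay: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch < 1:
            raise ValueError("batch must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class BPNN:
    """One-hidden-layer sigmoid network with linear output.

    Targets are centered/scaled internally during training (``y_loc``,
    ``y_scale``); ``predict`` returns original units.
    """

    W1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h,)
    b2: float
    y_loc: float = 0.0
    y_scale: float = 1.0

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Raw (internal-scale) network output."""
        H = _sigmoid(X @ self.W1 + self.b1)
        return H @ self.W2 + self.b2

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.forward(X) * self.y_scale + self.y_loc


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bpnn_gradients(net: BPNN, X: np.ndarray, y: np.ndarray):
    """Mean-squared-error loss and gradients on the internal target scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    A = X @ net.W1 + net.b1
    H = _sigmoid(A)
    pred = H @ net.W2 + net.b2
    resid = pred - y
    loss = float(np.mean(resid**2))
    gW2 = (2.0 / n) * (H.T @ resid)
    gb2 = float((2.0 / n) * resid.sum())
    back = (2.0 / n) * resid[:, None] * net.W2[None, :] * H * (1.0 - H)  # (n, h)
    gW1 = X.T @ back
    gb1 = back.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def _init_bpnn(d: int, config: BPNNConfig) -> BPNN:
    rng = np.random.default_rng(config.seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, config.hidden))
    b1 = np.zeros(config.hidden)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(config.hidden), size=config.hidden)
    return BPNN(W1, b1, W2, 0.0)


def train_bpnn(X, y, config: BPNNConfig) -> BPNN:
    """Seeded mini-batch gradient descent with lr_e = lr / (1 + decay·e)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    net = _init_bpnn(X.shape[1], config)
    y_loc = float(y.mean())
    y_scale = float(y.std()) or 1.0
    net.y_loc, net.y_scale = y_loc, y_scale
    ys = (y - y_loc) / y_scale
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    for epoch in range(config.epochs):
        lr_e = config.lr / (1.0 + config.decay * epoch)
        order = rng.permutation(n)
        for start in range(0, n, config.batch):
            idx = order[start:start + config.batch]
            loss, (gW1, gb1, gW2, gb2) = bpnn_gradients(net, X[idx], ys[idx])
            if not np.isfinite(loss):
                raise ValueError("diverging loss; try a smaller lr")
            net.W1 -= lr_e * gW1
            net.b1 -= lr_e * gb1
            net.W2 -= lr_e * gW2
            net.b2 -= lr_e * gb2
    return net


# ---------------------------------------------------------------------------
# Benchmark harness

DEFAULT_MODELS = ("gwo-rbf", "rbnna", "bpnn")


@dataclass
class BenchmarkResult:
    """Per-seed metrics, aggregated comparison table, and split fingerprints."""

    per_seed: pd.DataFrame        # columns: model, seed, mape, mae, r2
    table: pd.DataFrame           # metric × model (+ relative-change columns)
    split_fingerprints: dict      # seed -> hash of validation row indices
    failures: list = field(default_factory=list)


def _train_predict(model: str, X_tr, y_tr, X_va, seed: int,
                   K: int, gwo_config: hybrid_trainer.TrainConfig | None,
                   bpnn_config: BPNNConfig | None):
    if model == "gwo-rbf":
        # The benchmark runs the full hybrid method: global GWO search plus
        # the gradient fine-tuning pass (the method's backpropagation step).
        cfg = gwo_config or hybrid_trainer.TrainConfig(
            K=K, n_wolves=40, k_max=400, refine=True, refine_epochs=12000,
        )
        cfg = hybrid_trainer.TrainConfig(**{**cfg.__dict__, "seed": seed})
        net, _ = hybrid_trainer.train(X_tr, y_tr, cfg)
        return net.predict(X_va)
    if model == "rbnna":
        net = train_plain_rbnna(X_tr, y_tr, K=K, seed=seed)
        return net.predict(X_va)
    if model == "bpnn":
        cfg = bpnn_config or BPNNConfig()
        cfg = BPNNConfig(**{**cfg.__dict__, "seed": seed})
        return train_bpnn(X_tr, y_tr, cfg).predict(X_va)
    raise ValueError(f"unknown model {model!r}")


def run_benchmark(data, models=DEFAULT_MODELS, seeds=range(10),
                  target: str = "yield_actual", features=None, ratio: float = 0.7,
                  K: int = 15, gwo_config=None, bpnn_config=None,
                  subject: str = "gwo-rbf") -> BenchmarkResult:
    """Benchmark several models on one dataset (or a synthetic config).

    For each seed the dataset is split 7:3 (seeded shuffle), features are
    standardized on the training split only, every model is trained on the
    same matrices and evaluated on validation in original target units.
    Aggregation is the median metric across seeds; the table carries
    relative-change columns for ``subject``.  A model failure is recorded
    and the benchmark continues.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    if isinstance(data, synthetic.SyntheticConfig):
        data, _ = synthetic.generate(data)
    features = list(features) if features is not None else list(NUTRIENT_COLUMNS)
    rows, failures, fingerprints = [], [], {}
    for seed in seeds:
        train_df, val_df = synthetic.split(data, ratio=ratio, seed=seed)
        fingerprints[seed] = hash(tuple(val_df["plot_id"]))
        X_tr, params = standardize(train_df, columns=features)
        X_va = apply_standardization(val_df, params)
        y_tr = train_df[target].to_numpy(dtype=float)
        y_va = val_df[target].to_numpy(dtype=float)
        for model in models:
            try:
                pred = _train_predict(model, X_tr, y_tr, X_va, seed, K,
                                      gwo_config, bpnn_config)
                rep = metrics.MetricsReport.from_pair(y_va, pred)
                rows.append({"model": model, "seed": seed, "mape": rep.mape,
                             "mae": rep.mae, "r2": rep.r2})
            except Exception as exc:  # noqa: BLE001 - benchmark continues per contract
                failures.append({"model": model, "seed": seed, "error": str(exc)})
                rows.append({"model": model, "seed": seed, "mape": np.nan,
                             "mae": np.nan, "r2": np.nan})
    per_seed = pd.DataFrame(rows)
    med = per_seed.groupby("model")[["mape", "mae", "r2"]].median()
    reports = {
        m: metrics.MetricsReport(mape=med.loc[m, "mape"], mae=med.loc[m, "mae"],
                                 r2=med.loc[m, "r2"])
        for m in models if m in med.index and np.isfinite(med.loc[m, "mape"])
    }
    table = metrics.comparison_table(
        reports, subject=subject if subject in reports and len(reports) > 1 else None
    )
    return BenchmarkResult(per_seed=per_seed, table=table,
                           split_fingerprints=fingerprints, failures=failures)
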