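"""GWO-trained Gaussian RBF regression (the hybrid "improved" network).

The grey wolf optimizer searches the network's *entire* parameter vector —
centers, log-widths, output weights and bias — with the mean relative
prediction error (MAPE/100) between predicted and true target values as the
fitness.  An optional post-search gradient fine-tuning pass ("refine")
polishes the leader wolves by full-batch gradient descent on squared error
and keeps the best by training fitness; it is off by default so the
headline behaviour is the metaheuristic search alone.

Search box (inputs are expected standardized, targets in original positive
units):

* centers — each feature's [min, max] widened by ``bounds_margin`` × range
* log-widths — [log 0.05, log 5]
* output weights — ±``weight_scale`` × sd(y)
* bias — mean(y) ± ``weight_scale`` × sd(y) (centered on the target level so
  the constant term of a positive-valued target is reachable)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import gwo
from .data_io import StandardizationParams
from .metrics import MAPE_EPS
from .rbf_network import RBFNetwork, decode, encode

__all__ = [
    "TrainConfig",
    "fitness",
    "make_bounds",
    "train",
    "refine",
    "loss_and_gradient",
    "save_model",
    "load_model",
]

LOG_WIDTH_BOUNDS = (np.log(0.05), np.log(5.0))


@dataclass
class TrainConfig:
    """Hybrid-trainer settings.

    K is the hidden-unit count; ``n_wolves``/``k_max`` the pack size and
    iteration budget; ``bounds_margin`` widens the center box beyond the data
    range; ``fitness_split`` chooses whether the search fitness is measured
    on the training data (default) or a supplied validation split; ``refine``
    switches on gradient fine-tuning with step size ``refine_lr`` for
    ``refine_epochs`` full-batch epochs.
    """

    K: int = 10
    n_wolves: int = 30
    k_max: int = 100
    seed: int = 0
    bounds_margin: float = 0.5
    weight_scale: float = 10.0
    fitness_split: str = "train"
    refine: bool = False
    refine_lr: float = 1e-3
    refine_epochs: int = 2000

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_wolves < 3:
            raise ValueError("n_wolves must be >= 3")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.fitness_split not in ("train", "validation"):
            raise ValueError(f"unknown fitness_split {self.fitness_split!r}")


def fitness(vec, X, y, K: int, eps: float = MAPE_EPS) -> float:
    """Mean relative error (fraction, MAPE/100) of the decoded network on (X, y)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if (np.abs(y) < eps).any():
        raise ValueError(
            f"target with |y| < {eps:g}; relative-error fitness undefined near zero "
            "(raise eps only for strictly positive rescaled targets)"
        )
    net = decode(vec, K, X.shape[1])
    pred = net.predict(X)
    return float(np.mean(np.abs(y - pred) / np.abs(y)))


def make_bounds(X, y, config: TrainConfig) -> gwo.Bounds:
    """Search box for the flat parameter vector given the training data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    lo_x, hi_x = X.min(axis=0), X.max(axis=0)
    rng_x = hi_x - lo_x
    for j in range(d):
        if rng_x[j] == 0:
            raise ValueError(f"feature column {j} is constant; bounds degenerate")
    margin = config.bounds_margin * rng_x
    c_lo = np.tile(lo_x - margin, config.K)
    c_hi = np.tile(hi_x + margin, config.K)
    w_scale = config.weight_scale * float(y.std())
    if w_scale == 0:
        raise ValueError("target is constant; weight bounds degenerate")
    y_mean = float(y.mean())
    lower = np.concatenate([
        c_lo,
        np.full(config.K, LOG_WIDTH_BOUNDS[0]),
        np.full(config.K, -w_scale),
        [y_mean - w_scale],
    ])
    upper = np.concatenate([
        c_hi,
        np.full(config.K, LOG_WIDTH_BOUNDS[1]),
        np.full(config.K, w_scale),
        [y_mean + w_scale],
    ])
    return gwo.Bounds(lower, upper)


def loss_and_gradient(net: RBFNetwork, X, y):
    """Mean squared error and its gradient w.r.t. (centers, widths, weights, bias)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    G = net.activations(X)                      # (n, K)
    resid = G @ net.weights + net.bias - y      # (n,)
    loss = float(np.mean(resid**2))
    common = (2.0 / n) * resid[:, None] * G * net.weights[None, :]   # (n, K)
    diff = X[:, None, :] - net.centers[None, :, :]                   # (n, K, d)
    grad_centers = np.einsum("nk,nkd->kd", common, diff) / net.widths[None, :].T**2
    sq = np.sum(diff**2, axis=2)                                     # (n, K)
    grad_widths = np.sum(common * sq, axis=0) / net.widths**3
    grad_weights = (2.0 / n) * (G.T @ resid)
    grad_bias = float((2.0 / n) * resid.sum())
    return loss, (grad_centers, grad_widths, grad_weights, grad_bias)


def refine(net: RBFNetwork, X, y, lr: float = 1e-4, epochs: int = 200) -> RBFNetwork:
    """Full-batch gradient descent on squared error over all parameters.

    ``lr`` is the initial step size; each epoch takes one gradient step and
    the step size adapts (grows 1.2× on improvement, halves on a rejected
    step) so convergence does not hinge on a hand-picked constant.  Returns
    the epoch-best network by training loss, so the result is never worse
    than the input.  Widths are floored at a tiny positive value to keep the
    network valid along the trajectory.
    """
    if lr <= 0:
        raise ValueError("lr must be positive")
    centers = net.centers.copy()
    widths = net.widths.copy()
    weights = net.weights.copy()
    bias = net.bias
    loss, grads = loss_and_gradient(net, X, y)
    best_loss = loss
    best = (centers.copy(), widths.copy(), weights.copy(), bias)
    step = lr
    for _ in range(epochs):
        gc, gs, gw, gb = grads
        if not all(np.isfinite(g).all() for g in (gc, gs, gw)) or not np.isfinite(gb):
            raise ValueError("non-finite gradient; try a smaller lr")
        trial = RBFNetwork(
            centers - step * gc,
            np.maximum(widths - step * gs, 1e-6),
            weights - step * gw,
            bias - step * gb,
        )
        trial_loss, trial_grads = loss_and_gradient(trial, X, y)
        if np.isfinite(trial_loss) and trial_loss <= loss:
            centers, widths, weights, bias = (
                trial.centers, trial.widths, trial.weights, trial.bias,
            )
            loss, grads = trial_loss, trial_grads
            step *= 1.2
            if loss < best_loss:
                best_loss = loss
                best = (centers.copy(), widths.copy(), weights.copy(), bias)
        else:
            step *= 0.5
            if step < 1e-15:
                break
    return RBFNetwork(*best)


def train(X, y, config: TrainConfig, X_val=None, y_val=None):
    """Train the GWO-searched RBF network; return ``(network, fitness trace)``.

    Inputs should be standardized features (training-split parameters) and
    strictly positive targets in original units.  The trace is the GWO
    best-so-far mean relative error per iteration and is non-increasing.
    Identical config (including seed) gives an identical network.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < config.K:
        import warnings

        warnings.warn(
            f"fewer training rows ({n}) than hidden units ({config.K})",
            stacklevel=2,
        )
    if config.fitness_split == "validation":
        if X_val is None or y_val is None:
            raise ValueError("validation fitness requested but no validation split given")
        X_fit, y_fit = np.atleast_2d(np.asarray(X_val, float)), np.asarray(y_val, float).ravel()
    else:
        X_fit, y_fit = X, y
    bounds = make_bounds(X, y, config)

    def objective(vec):
        return fitness(vec, X_fit, y_fit, config.K)

    def canonicalize(P):
        # The network is invariant under permutation of its hidden units, so
        # each wolf is mapped to the representative with units sorted by the
        # first center coordinate.  This aligns corresponding parameters
        # across wolves and makes the leader-averaged recombination coherent;
        # the unit-wise boxes are identical, so sorting stays within bounds.
        P = np.array(P, dtype=float)
        K, dd = config.K, d
        for i in range(P.shape[0]):
            centers = P[i, : K * dd].reshape(K, dd)
            order = np.argsort(centers[:, 0], kind="stable")
            P[i, : K * dd] = centers[order].ravel()
            logw = P[i, K * dd : K * dd + K]
            w = P[i, K * dd + K : K * dd + 2 * K]
            P[i, K * dd : K * dd + K] = logw[order]
            P[i, K * dd + K : K * dd + 2 * K] = w[order]
        return P

    rng = np.random.default_rng(config.seed)
    positions = canonicalize(bounds.sample(config.n_wolves, rng))
    fitnesses = np.array([objective(w) for w in positions])
    state = gwo.GWOState(positions=positions, fitnesses=fitnesses, bounds=bounds,
                         k=0, k_max=max(config.k_max, 1), rng=rng)
    state.absorb(positions, fitnesses)
    state.trace.append(state.best_fitness)
    for _ in range(config.k_max):
        gwo.update_positions(state, objective, transform=canonicalize)
    trace = np.array(state.trace)
    net = decode(state.best_position, config.K, d)
    if config.refine and config.refine_epochs > 0:
        # Fine-tune every leader wolf, not just alpha: the three best-so-far
        # packs sit in different basins and gradient descent sorts out which
        # one actually fits best.  Selection is by the training fitness.
        best_fit, best_net = fitness(encode(net), X_fit, y_fit, config.K), net
        for _, _, leader_pos in state.leaders:
            cand = refine(decode(leader_pos, config.K, d), X, y,
                          lr=config.refine_lr, epochs=config.refine_epochs)
            cand_fit = fitness(encode(cand), X_fit, y_fit, config.K)
            if cand_fit < best_fit:
                best_fit, best_net = cand_fit, cand
        net = best_net
    return net, trace


def save_model(path, net: RBFNetwork, params: StandardizationParams | None = None,
               config: TrainConfig | None = None, extra: dict | None = None) -> None:
    """Serialize network + standardization + training config to one JSON file."""
    doc = {
        "model": {
            "K": net.K,
            "d": net.d,
            "centers": net.centers.tolist(),
            "widths": net.widths.tolist(),
            "weights": net.weights.tolist(),
            "bias": net.bias,
        },
        "standardization": params.to_dict() if params is not None else None,
        "config": asdict(config) if config is not None else None,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path):
    """Load a model JSON; returns (network, StandardizationParams|None, config dict|None)."""
    doc = json.loads(Path(path).read_text())
    m = doc["model"]
    net = RBFNetwork(np.array(m["centers"]), np.array(m["widths"]),
                     np.array(m["weights"]), m["bias"])
    params = (StandardizationParams.from_dict(doc["standardization"])
              if doc.get("standardization") else None)
    return net, params, doc.get("config")
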