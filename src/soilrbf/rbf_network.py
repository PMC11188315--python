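"""Gaussian radial basis function regression network.

A single hidden layer of K Gaussian units, each responding to the squared
Euclidean distance between the input and its center,

    G_s(x) = exp(-||x - o_s||^2 / (2 σ_s^2)),

combined by a linear output layer with weights w and a scalar bias
(threshold):  ŷ(x) = Σ_s w_s G_s(x) + b.

For metaheuristic search the full parameter set is packed into one flat
vector, ordered [centers row-major | log-widths | output weights | bias];
widths travel in log-space so any real vector decodes to a valid network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "RBFNetwork",
    "gaussian_basis",
    "fit_output_layer",
    "param_vector_length",
    "encode",
    "decode",
]


def gaussian_basis(x, center, sigma: float) -> float:
    """Gaussian activation exp(-||x - center||^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ValueError("width sigma must be positive")
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    d2 = float(np.sum((x - center) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


@dataclass
class RBFNetwork:
    """Gaussian RBF network: K centers (K×d), widths (K), weights (K), bias."""

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.bias = float(self.bias)
        K = self.centers.shape[0]
        if self.widths.shape != (K,) or self.weights.shape != (K,):
            raise ValueError("widths and weights must have one entry per center")
        if (self.widths <= 0).any():
            raise ValueError("all widths must be positive")

    @property
    def K(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def activations(self, X) -> np.ndarray:
        """Hidden-layer design matrix, shape (n, K), entries in (0, 1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d} input columns, got {X.shape[1]}")
        d2 = cdist(X, self.centers, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.widths**2))

    def predict(self, X) -> np.ndarray:
        """Network output Σ_s w_s G_s(x) + bias for each row of X."""
        return self.activations(X) @ self.weights + self.bias


def fit_output_layer(centers, widths, X, y):
    """Least-squares fit of output weights and bias for fixed centers/widths.

    Returns the minimum-norm solution of ``[G | 1] @ [w; b] ≈ y`` so the
    underdetermined case is well defined.
    """
    net = RBFNetwork(centers, widths, np.zeros(np.atleast_2d(centers).shape[0]), 0.0)
    G = net.activations(X)
    y = np.asarray(y, dtype=float).ravel()
    design = np.hstack([G, np.ones((G.shape[0], 1))])
    if not np.isfinite(design).all():
        raise ValueError("non-finite entries in the design matrix")
    sol, *_ = np.linalg.lstsq(design, y, rcond=None)
    return sol[:-1], float(sol[-1])


def param_vector_length(K: int, d: int) -> int:
    """Flat parameter-vector length: K·d centers + K log-widths + K weights + bias."""
    return K * d + 2 * K + 1


def encode(net: RBFNetwork) -> np.ndarray:
    """Pack a network into [centers row-major | log-widths | weights | bias]."""
    return np.concatenate(
        [net.centers.ravel(), np.log(net.widths), net.weights, [net.bias]]
    )


def decode(vec, K: int, d: int) -> RBFNetwork:
    """Unpack a flat parameter vector (widths recovered as exp(log-width))."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != param_vector_length(K, d):
        raise ValueError(
            f"expected vector of length {param_vector_length(K, d)}, got {vec.size}"
        )
    if not np.isfinite(vec).all():
        raise ValueError("non-finite entries in parameter vector")
    centers = vec[: K * d].reshape(K, d)
    widths = np.exp(vec[K * d : K * d + K])
    weights = vec[K * d + K : K * d + 2 * K]
    bias = float(vec[-1])
    return RBFNetwork(centers, widths, weights, bias)
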