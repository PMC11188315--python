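"""Grey wolf optimizer over bounded real vectors.

A population of candidate solutions ("wolves") moves toward the three best
solutions found so far — alpha, beta and delta — under a convergence factor
ω that decreases linearly from 2 to 0 over the iteration budget.  For each
wolf and each leader, fresh per-component random coefficients are drawn:

    M = 2ω·p1 − ω        (exploration coefficient, components in [−ω, ω])
    N = 2·p2             (prey-weighting coefficient, components in [0, 2])

and the leader-guided candidate is ``leader − M ⊙ |N ⊙ leader − w|``.  The
wolf's new position is the arithmetic mean of its three candidates, clipped
to the search box.  Leaders are the best-so-far top three across *all*
evaluations (ties broken by earliest evaluation), which makes the
best-fitness trace non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bounds",
    "GWOState",
    "convergence_factor",
    "coefficient_vectors",
    "encircle_distance",
    "update_positions",
    "optimize",
]


@dataclass
class Bounds:
    """Axis-aligned search box, in the decision variable's units."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper must have equal shape")
        if not (self.lower < self.upper).all():
            raise ValueError("require lower < upper elementwise")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.lower, self.upper)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))


def convergence_factor(k: int, k_max: int) -> float:
    """Linear 2→0 schedule: ω = 2·(1 − k/k_max)."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not 0 <= k <= k_max:
        raise ValueError(f"iteration k={k} outside [0, {k_max}]")
    return 2.0 * (1.0 - k / k_max)


def coefficient_vectors(omega: float, rng: np.random.Generator, dim: int):
    """Draw the (M, N) coefficient vectors for one leader interaction."""
    if not 0.0 <= omega <= 2.0:
        raise ValueError("omega must lie in [0, 2]")
    p1 = rng.random(dim)
    p2 = rng.random(dim)
    return 2.0 * omega * p1 - omega, 2.0 * p2


def encircle_distance(W, W_target, N) -> np.ndarray:
    """Componentwise distance to a coefficient-weighted target, |N⊙target − W|."""
    W = np.asarray(W, dtype=float)
    W_target = np.asarray(W_target, dtype=float)
    N = np.asarray(N, dtype=float)
    if not (W.shape == W_target.shape == N.shape):
        raise ValueError("W, W_target and N must have equal shape")
    return np.abs(N * W_target - W)


@dataclass
class GWOState:
    """Mutable optimizer state: pack positions, best-so-far leaders, counters."""

    positions: np.ndarray
    fitnesses: np.ndarray
    bounds: Bounds
    k: int
    k_max: int
    rng: np.random.Generator
    # leaders[i] = (fitness, eval_order, position); sorted best-first
    leaders: list = field(default_factory=list)
    n_evals: int = 0
    trace: list = field(default_factory=list)

    @property
    def omega(self) -> float:
        return convergence_factor(self.k, self.k_max)

    @property
    def leader_positions(self) -> np.ndarray:
        return np.array([pos for _, _, pos in self.leaders])

    @property
    def leader_fitnesses(self) -> np.ndarray:
        return np.array([f for f, _, _ in self.leaders])

    @property
    def best_position(self) -> np.ndarray:
        return self.leaders[0][2].copy()

    @property
    def best_fitness(self) -> float:
        return self.leaders[0][0]

    def absorb(self, positions: np.ndarray, fitnesses: np.ndarray) -> None:
        """Fold new evaluations into the best-so-far leader triple."""
        cand = list(self.leaders)
        for pos, f in zip(positions, fitnesses):
            cand.append((float(f), self.n_evals, pos.copy()))
            self.n_evals += 1
        cand.sort(key=lambda t: (t[0], t[1]))
        self.leaders = cand[:3]


def _evaluate(fitness, positions: np.ndarray) -> np.ndarray:
    out = np.empty(len(positions))
    for i, w in enumerate(positions):
        f = float(fitness(w))
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness for wolf {i}")
        out[i] = f
    return out


def update_positions(state: GWOState, fitness, coeff_sampler=None,
                     transform=None) -> GWOState:
    """Advance the pack one iteration in place.

    Each wolf's new position averages three leader-guided candidates built
    with per-leader, per-component fresh (M, N) draws, then is clipped to the
    bounds.  ``coeff_sampler(omega, rng, shape) -> (M, N)`` may replace the
    random draws (used in tests to pin coefficients).  ``transform`` maps the
    clipped position matrix to a fitness-equivalent representative (for
    objectives with symmetries); it must keep positions within bounds.
    """
    n, dim = state.positions.shape
    omega = state.omega
    if coeff_sampler is None:
        p1 = state.rng.random((n, 3, dim))
        p2 = state.rng.random((n, 3, dim))
        M = 2.0 * omega * p1 - omega
        N = 2.0 * p2
    else:
        M, N = coeff_sampler(omega, state.rng, (n, 3, dim))
        M = np.broadcast_to(np.asarray(M, float), (n, 3, dim))
        N = np.broadcast_to(np.asarray(N, float), (n, 3, dim))
    leaders = state.leader_positions[None, :, :]  # (1, 3, dim)
    dist = np.abs(N * leaders - state.positions[:, None, :])
    candidates = leaders - M * dist
    new_positions = state.bounds.clip(candidates.mean(axis=1))
    if transform is not None:
        new_positions = transform(new_positions)
    new_fitnesses = _evaluate(fitness, new_positions)
    state.positions = new_positions
    state.fitnesses = new_fitnesses
    state.absorb(new_positions, new_fitnesses)
    state.k += 1
    state.trace.append(state.best_fitness)
    return state


def optimize(fitness, bounds: Bounds, n_wolves: int = 30, k_max: int = 100,
             seed: int | None = None):
    """Minimize ``fitness`` over the box; return (best position, best fitness, trace).

    The trace has ``k_max + 1`` entries (initial pack best, then one per
    iteration) and is non-increasing.  Identical seeds give identical output.
    """
    if n_wolves < 3:
        raise ValueError("need at least 3 wolves (alpha, beta, delta)")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    rng = np.random.default_rng(seed)
    positions = bounds.sample(n_wolves, rng)
    fitnesses = _evaluate(fitness, positions)
    state = GWOState(positions=positions, fitnesses=fitnesses, bounds=bounds,
                     k=0, k_max=max(k_max, 1), rng=rng)
    state.absorb(positions, fitnesses)
    state.trace.append(state.best_fitness)
    for _ in range(k_max):
        update_positions(state, fitness)
    return state.best_position, state.best_fitness, np.array(state.trace)
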