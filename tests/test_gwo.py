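import numpy as np
import pytest

from soilrbf.gwo import (
    Bounds,
    GWOState,
    coefficient_vectors,
    convergence_factor,
    encircle_distance,
    optimize,
    update_positions,
)


def sphere(w):
    return float(np.sum(np.asarray(w) ** 2))


def make_state(positions, fitness, bounds, k_max=10, seed=0):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    fits = np.array([fitness(w) for w in positions])
    state = GWOState(positions=positions, fitnesses=fits, bounds=bounds,
                     k=0, k_max=k_max, rng=np.random.default_rng(seed))
    state.absorb(positions, fits)
    state.trace.append(state.best_fitness)
    return state


class TestConvergenceFactor:
    @pytest.mark.parametrize("k,k_max,expected", [(0, 100, 2.0), (100, 100, 0.0), (50, 100, 1.0)])
    def test_linear_schedule(self, k, k_max, expected):
        assert convergence_factor(k, k_max) == expected

    def test_k_beyond_budget_rejected(self):
        with pytest.raises(ValueError):
            convergence_factor(101, 100)


class TestCoefficientVectors:
    def test_ranges(self):
        rng = np.random.default_rng(0)
        for omega in (0.0, 0.7, 2.0):
            M, N = coefficient_vectors(omega, rng, 50)
            assert (np.abs(M) <= omega + 1e-12).all()
            assert ((N >= 0) & (N <= 2)).all()

    def test_endpoints_of_the_formula(self):
        # p1 = p2 = 0.5 gives the midpoints M = 0, N = 1; p = 1 the maxima
        omega = 1.3
        assert 2 * omega * 0.5 - omega == pytest.approx(0.0)
        assert 2 * 0.5 == 1.0
        assert 2 * 2.0 * 1.0 - 2.0 == 2.0 and 2 * 1.0 == 2.0


class TestEncircleDistance:
    def test_coincident_with_unit_coefficient(self):
        w = np.array([1.5, -2.0])
        assert np.all(encircle_distance(w, w, np.ones(2)) == 0)

    def test_direct_evaluation(self):
        d = encircle_distance(np.array([0.5, 3.0]), np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert d == pytest.approx([1.5, 1.0])

    def test_symmetry_of_absolute_value(self):
        rng = np.random.default_rng(3)
        W, T, N = rng.normal(size=(3, 6))
        # |N⊙T − W| is unchanged when W and N⊙T trade places
        direct = encircle_distance(W, T, N)
        swapped = encircle_distance(N * T, W, np.ones(6))
        assert np.allclose(direct, swapped)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            encircle_distance(np.zeros(2), np.zeros(3), np.zeros(3))


class TestUpdatePositions:
    def test_fixed_point_when_everything_coincides(self):
        bounds = Bounds([-5, -5], [5, 5])
        point = np.array([1.0, 2.0])
        state = make_state([point, point, point], sphere, bounds)
        update_positions(state, sphere,
                         coeff_sampler=lambda o, r, s: (np.zeros(s), np.ones(s)))
        assert np.allclose(state.positions, point)

    def test_direct_average_of_leader_candidates(self):
        # single wolf at 0, leaders at 1, M=0 and N=1: new position (1+1+1)/3
        bounds = Bounds([-5], [5])
        state = make_state([[1.0], [1.0], [1.0], [0.0]], sphere, bounds)
        # leaders are the three wolves at 1 ... but sphere ranks 0 best, so pin leaders
        state.leaders = [(1.0, i, np.array([1.0])) for i in range(3)]
        state.positions = np.array([[0.0]])
        update_positions(state, sphere,
                         coeff_sampler=lambda o, r, s: (np.zeros(s), np.ones(s)))
        assert state.positions[0, 0] == pytest.approx(1.0)

    def test_best_so_far_never_worsens_after_update(self):
        bounds = Bounds([-5] * 3, [5] * 3)
        rng = np.random.default_rng(42)
        state = make_state(rng.uniform(-5, 5, (30, 3)), sphere, bounds, k_max=50)
        before = state.best_fitness
        update_positions(state, sphere)
        assert state.best_fitness <= before

    def test_nonfinite_fitness_identifies_wolf(self):
        bounds = Bounds([-5], [5])
        state = make_state([[1.0], [2.0], [3.0]], sphere, bounds)
        with pytest.raises(ValueError, match="wolf"):
            update_positions(state, lambda w: float("nan"))


class TestOptimize:
    def test_zero_iterations_returns_best_initial_wolf(self):
        bounds = Bounds([-5] * 2, [5] * 2)
        pos, fit, trace = optimize(sphere, bounds, n_wolves=10, k_max=0, seed=3)
        rng = np.random.default_rng(3)
        init = rng.uniform(bounds.lower, bounds.upper, size=(10, 2))
        fits = np.array([sphere(w) for w in init])
        assert fit == fits.min()
        assert np.array_equal(pos, init[np.argmin(fits)])
        assert len(trace) == 1

    def test_sphere_converges(self):
        bounds = Bounds([-5] * 5, [5] * 5)
        _, fit, trace = optimize(sphere, bounds, n_wolves=30, k_max=200, seed=42)
        assert fit < 1e-2
        assert len(trace) == 201

    def test_rastrigin_improves_over_initialization(self):
        def rastrigin(w):
            w = np.asarray(w)
            return float(10 * w.size + np.sum(w**2 - 10 * np.cos(2 * np.pi * w)))

        bounds = Bounds([-5.12] * 2, [5.12] * 2)
        _, fit, trace = optimize(rastrigin, bounds, n_wolves=30, k_max=200, seed=7)
        assert fit < trace[0]

    def test_fewer_than_three_wolves_rejected(self):
        with pytest.raises(ValueError):
            optimize(sphere, Bounds([-1], [1]), n_wolves=2, k_max=5)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_trace_non_increasing_and_bounded_positions(self, seed):
        rng = np.random.default_rng(seed)
        dim = int(rng.integers(1, 6))
        lo = rng.uniform(-10, 0, dim)
        hi = lo + rng.uniform(0.5, 10, dim)
        shift = rng.uniform(-1, 1, dim)

        def obj(w):
            return float(np.sum((np.asarray(w) - shift) ** 2))

        pos, fit, trace = optimize(obj, Bounds(lo, hi), n_wolves=8,
                                   k_max=30, seed=seed)
        assert np.all(np.diff(trace) <= 0)
        assert np.all(pos >= lo) and np.all(pos <= hi)

    def test_equal_seeds_bit_identical(self):
        bounds = Bounds([-3] * 4, [3] * 4)
        out1 = optimize(sphere, bounds, n_wolves=12, k_max=40, seed=11)
        out2 = optimize(sphere, bounds, n_wolves=12, k_max=40, seed=11)
        assert np.array_equal(out1[2], out2[2])
        assert np.array_equal(out1[0], out2[0])

    def test_longer_budgets_reach_lower_fitness(self):
        # sanity of the omega schedule on a convex quadratic
        bounds = Bounds([-5] * 3, [5] * 3)
        medians = []
        for k_max in (10, 50, 200):
            finals = [optimize(sphere, bounds, n_wolves=10, k_max=k_max, seed=s)[1]
                      for s in range(20)]
            medians.append(np.median(finals))
        assert medians[0] > medians[1] > medians[2]

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            Bounds([0, 0], [1, 0])
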