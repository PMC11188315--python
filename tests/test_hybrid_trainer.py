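import numpy as np
import pytest

from soilrbf import hybrid_trainer, metrics, synthetic
from soilrbf.data_io import NUTRIENT_COLUMNS, apply_standardization, standardize
from soilrbf.hybrid_trainer import TrainConfig, fitness, loss_and_gradient, make_bounds, refine, train
from soilrbf.rbf_network import RBFNetwork, decode, encode, param_vector_length


def random_net(seed, K=3, d=2):
    rng = np.random.default_rng(seed)
    return RBFNetwork(rng.normal(size=(K, d)), rng.uniform(0.5, 2, K),
                      rng.normal(size=K), float(rng.normal()))


class TestFitness:
    def test_perfect_predictor_scores_zero(self):
        net = RBFNetwork([[0.0]], [1.0], [0.0], 5.0)
        X = np.linspace(-1, 1, 7)[:, None]
        assert fitness(encode(net), X, np.full(7, 5.0), K=1) == 0.0

    def test_direct_relative_error(self):
        # constant predictions 110 and 180 against targets 100 and 200
        net1 = RBFNetwork([[0.0]], [1.0], [0.0], 110.0)
        assert fitness(encode(net1), [[0.0]], [100.0], K=1) == pytest.approx(0.10)
        net2 = RBFNetwork([[0.0]], [1.0], [0.0], 180.0)
        f = 0.5 * (fitness(encode(net1), [[0.0]], [100.0], K=1)
                   + fitness(encode(net2), [[0.0]], [200.0], K=1))
        assert f == pytest.approx(0.10)

    def test_matches_definitional_loop_and_metrics_module(self):
        rng = np.random.default_rng(3)
        net = random_net(4, K=4, d=3)
        X = rng.normal(size=(30, 3))
        y = rng.uniform(50, 150, 30)
        got = fitness(encode(net), X, y, K=4)
        pred = net.predict(X)
        loop = sum(abs(a - b) / abs(a) for a, b in zip(y, pred)) / len(y)
        assert got == pytest.approx(loop, abs=1e-12)
        assert got == pytest.approx(metrics.mape(y, pred) / 100.0, abs=1e-12)

    def test_near_zero_target_guarded(self):
        net = random_net(5)
        with pytest.raises(ValueError, match="eps"):
            fitness(encode(net), [[0.0, 0.0]], [0.0], K=3)


class TestBounds:
    def test_constant_feature_named(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="column 0"):
            make_bounds(X, np.arange(10.0) + 1, TrainConfig(K=2))

    def test_box_layout(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = rng.uniform(100, 200, 20)
        cfg = TrainConfig(K=3)
        b = make_bounds(X, y, cfg)
        assert b.dim == param_vector_length(3, 2)
        # bias box is centred on the target mean
        assert b.lower[-1] < y.mean() < b.upper[-1]


class TestRefine:
    def test_zero_epochs_is_identity(self):
        net = random_net(1)
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(10, 2)), rng.uniform(1, 2, 10)
        out = refine(net, X, y, lr=1e-3, epochs=0)
        assert np.array_equal(out.centers, net.centers)
        assert np.array_equal(out.weights, net.weights)

    def test_loss_never_increases(self):
        rng = np.random.default_rng(3)
        net = random_net(3)
        X, y = rng.normal(size=(25, 2)), rng.uniform(50, 150, 25)
        before, _ = loss_and_gradient(net, X, y)
        after, _ = loss_and_gradient(refine(net, X, y, lr=1e-3, epochs=100), X, y)
        assert after <= before

    def test_single_unit_single_point_first_step_descends(self):
        net = RBFNetwork([[0.0]], [1.0], [1.0], 0.0)
        X, y = np.array([[0.5]]), np.array([2.0])
        before, _ = loss_and_gradient(net, X, y)
        after, _ = loss_and_gradient(refine(net, X, y, lr=1e-4, epochs=1), X, y)
        assert after < before

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(7)
        net = random_net(11, K=3, d=2)
        X = rng.normal(size=(15, 2))
        y = rng.uniform(10, 20, 15)
        _, (gc, gs, gw, gb) = loss_and_gradient(net, X, y)
        h = 1e-6

        def loss_of(vec):
            n = decode(vec, 3, 2)
            return loss_and_gradient(n, X, y)[0]

        vec = encode(net)
        # map analytic grads into the encoded layout (log-width chain rule)
        analytic = np.concatenate(
            [gc.ravel(), gs * net.widths, gw, [gb]]
        )
        num = np.empty_like(vec)
        for i in range(vec.size):
            up, dn = vec.copy(), vec.copy()
            up[i] += h
            dn[i] -= h
            num[i] = (loss_of(up) - loss_of(dn)) / (2 * h)
        assert np.allclose(analytic, num, atol=1e-5)

    def test_invalid_lr(self):
        with pytest.raises(ValueError):
            refine(random_net(1), np.zeros((2, 2)), np.ones(2), lr=0.0, epochs=1)


@pytest.fixture(scope="module")
def standardized_data():
    cfg = synthetic.plantation_config(n=500, seed=11)
    data, _ = synthetic.generate(cfg)
    tr, va = synthetic.split(data, 0.7, seed=11)
    X, p = standardize(tr, columns=NUTRIENT_COLUMNS)
    Xv = apply_standardization(va, p)
    return X, tr["yield_actual"].to_numpy(), Xv, va["yield_actual"].to_numpy()


class TestTrain:

    def test_deterministic_per_seed(self, standardized_data):
        X, y, _, _ = standardized_data
        cfg = TrainConfig(K=4, n_wolves=10, k_max=20, seed=5)
        n1, t1 = train(X, y, cfg)
        n2, t2 = train(X, y, cfg)
        assert np.array_equal(t1, t2)
        assert np.array_equal(n1.centers, n2.centers)
        assert np.array_equal(n1.weights, n2.weights)

    def test_trace_non_increasing(self, standardized_data):
        X, y, _, _ = standardized_data
        _, trace = train(X, y, TrainConfig(K=4, n_wolves=10, k_max=30, seed=2))
        assert len(trace) == 31
        assert np.all(np.diff(trace) <= 0)

    def test_smooth_target_validation_mape(self, standardized_data):
        # generic smooth nutrient->yield response, default-scale problem
        X, y, Xv, yv = standardized_data
        net, _ = train(X, y, TrainConfig(K=10, n_wolves=30, k_max=100, seed=11))
        assert metrics.mape(yv, net.predict(Xv)) < 15.0

    def test_validation_fitness_split_requires_data(self, standardized_data):
        X, y, _, _ = standardized_data
        cfg = TrainConfig(K=3, n_wolves=5, k_max=5, fitness_split="validation")
        with pytest.raises(ValueError):
            train(X, y, cfg)

    def test_underparameterized_warning(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 2))
        y = rng.uniform(10, 20, 4)
        with pytest.warns(UserWarning):
            train(X, y, TrainConfig(K=6, n_wolves=5, k_max=2, seed=0))


class TestSerialization:
    def test_model_roundtrip(self, tmp_path):
        from soilrbf.data_io import StandardizationParams
        from soilrbf.hybrid_trainer import load_model, save_model

        net = random_net(8, K=2, d=3)
        params = StandardizationParams(["a", "b", "c"], [1, 2, 3], [1, 1, 2])
        cfg = TrainConfig(K=2, seed=9)
        path = tmp_path / "model.json"
        save_model(path, net, params, cfg)
        net2, params2, cfg2 = load_model(path)
        assert np.allclose(net2.centers, net.centers)
        assert np.allclose(net2.widths, net.widths)
        assert params2.columns == params.columns
        assert cfg2["seed"] == 9
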