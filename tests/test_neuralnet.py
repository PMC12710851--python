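import math

import numpy as np
import pandas as pd
import pytest

from thermocard.neuralnet import (
    GAUSS,
    LINEAR,
    TANH,
    FitMetrics,
    NetworkSpec,
    TrainedNetwork,
    _init_network,
    evaluate,
    forward,
    load_model,
    loss_and_grads,
    multi_tour,
    save_model,
    spearman_filter,
    split_data,
    train,
)


def _manual_net(spec, **kw):
    d = len(spec.features)
    h1, h2 = sum(spec.layer1), sum(spec.layer2)
    defaults = dict(
        W1=np.zeros((h1, d)), b1=np.zeros(h1),
        W2=np.zeros((h2, h1)), b2=np.zeros(h2),
        w_out=np.zeros(h2), b_out=0.0,
        x_mean=np.zeros(d), x_sd=np.ones(d), y_mean=0.0, y_sd=1.0,
    )
    defaults.update(kw)
    return TrainedNetwork(spec=spec, **defaults)


class TestSpearmanFilter:
    def _frame(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        return pd.DataFrame(
            {"a": a, "b": a + rng.normal(0, 0.1, n), "c": rng.normal(size=n)}
        )

    def test_duplicate_feature_dropped(self):
        df = self._frame()
        df["b"] = df["a"]
        retained, report = spearman_filter(df)
        assert len(retained) == 2 and "c" in retained
        assert len({"a", "b"} & set(retained)) == 1

    def test_independent_features_all_retained(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("wxyz"))
        retained, report = spearman_filter(df)
        assert retained == list("wxyz") and report == []

    def test_correlated_pair_resolved_keeping_independent_feature(self):
        retained, report = spearman_filter(self._frame())
        assert "c" in retained
        assert len(retained) == 2
        assert report[0]["why"].startswith("|rho|")

    def test_constant_feature_dropped_with_warning(self):
        df = self._frame()
        df["k"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            retained, report = spearman_filter(df)
        assert "k" not in retained


class TestSplitData:
    def test_printed_fractions_at_n100(self):
        tr, va, te = split_data(100, seed=1)
        assert (len(tr), len(va), len(te)) == (45, 30, 25)

    def test_remainder_goes_to_training_at_n10(self):
        tr, va, te = split_data(10, seed=1)
        assert (len(tr), len(va), len(te)) == (5, 3, 2)

    def test_partition_is_disjoint_exhaustive_and_reproducible(self):
        tr, va, te = split_data(37, seed=9)
        allidx = np.concatenate([tr, va, te])
        assert sorted(allidx) == list(range(37))
        tr2, va2, te2 = split_data(37, seed=9)
        assert np.array_equal(tr, tr2) and np.array_equal(te, te2)

    def test_too_small_n_raises(self):
        with pytest.raises(ValueError, match="n >= 10"):
            split_data(9)


class TestForward:
    def test_zero_weights_give_destandardized_bias(self):
        spec = NetworkSpec((1, 1, 1), (1, 1, 1), ("x",), "y")
        net = _manual_net(spec, b_out=0.5, y_mean=10.0, y_sd=2.0)
        # gaussian nodes at z=0 output 1, but w_out=0 kills layer outputs
        assert forward(net, [123.0]) == pytest.approx(10.0 + 0.5 * 2.0)

    def test_gaussian_node_peaks_at_one(self):
        spec = NetworkSpec((0, 0, 1), (0, 1, 0), ("x",), "y")
        net = _manual_net(spec, W2=np.ones((1, 1)), w_out=np.ones(1))
        # layer1 gaussian: z=0 -> exp(0)=1; layer2 linear passes it through
        assert forward(net, [0.0]) == pytest.approx(1.0)

    def test_single_tanh_node_hand_value(self):
        spec = NetworkSpec((1, 0, 0), (0, 1, 0), ("x",), "y")
        net = _manual_net(
            spec, W1=np.array([[1.0]]), W2=np.array([[1.0]]),
            w_out=np.array([2.0]),
        )
        assert forward(net, [0.5]) == pytest.approx(2 * math.tanh(0.5))

    def test_matches_naive_per_node_oracle(self):
        rng = np.random.default_rng(8)
        spec = NetworkSpec((2, 1, 3), (3, 2, 1), ("a", "b", "c", "d"), "y")
        net = _init_network(spec, rng.normal(size=4), rng.uniform(0.5, 2, 4),
                            1.3, 0.7, rng, 0.8)

        def phi(z, t):
            return math.tanh(z) if t == TANH else z if t == LINEAR \
                else math.exp(-z * z)

        t1, t2 = spec.node_types(1), spec.node_types(2)
        for _ in range(25):
            x = rng.normal(size=4)
            xs = (x - net.x_mean) / net.x_sd
            a1 = [phi(sum(net.W1[j, i] * xs[i] for i in range(4)) + net.b1[j],
                      t1[j]) for j in range(6)]
            a2 = [phi(sum(net.W2[j, i] * a1[i] for i in range(6)) + net.b2[j],
                      t2[j]) for j in range(6)]
            want = (sum(net.w_out[j] * a2[j] for j in range(6)) + net.b_out)
            want = want * net.y_sd + net.y_mean
            assert abs(forward(net, x) - want) < 1e-12

    def test_dimension_mismatch_raises(self):
        spec = NetworkSpec((1, 1, 1), (1, 1, 1), ("a", "b"), "y")
        with pytest.raises(ValueError, match="features"):
            _manual_net(spec).predict(np.zeros((3, 5)))


class TestTraining:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        spec = NetworkSpec((2, 1, 2), (1, 1, 2), ("a", "b", "c"), "y")
        net = _init_network(spec, np.zeros(3), np.ones(3), 0.0, 1.0, rng, 0.5)
        x, y = rng.normal(size=3), 0.7
        _, g = loss_and_grads(net, x, y)
        eps = 1e-6
        for name in ("W1", "b1", "W2", "b2", "w_out"):
            arr = getattr(net, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = loss_and_grads(net, x, y)
                arr[idx] = orig - eps
                lm, _ = loss_and_grads(net, x, y)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[name][idx]) <= 1e-6 * max(abs(fd), 1.0)

    def test_linear_target_reaches_near_perfect_validation_r2(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-2, 2, size=(60, 1))
        y = 3 * X[:, 0] + 2
        spec = NetworkSpec((1, 1, 1), (1, 1, 1), ("x",), "y")
        net = multi_tour(spec, X[:40], y[:40], X[40:], y[40:],
                         tours=5, epochs=500, seed=2)
        assert evaluate(net, X[40:], y[40:]).r_squared >= 0.999

    def test_zero_epochs_returns_initialized_network(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        net = train(NetworkSpec((1, 1, 1), (1, 1, 1), ("a", "b"), "y"),
                    X[:12], y[:12], X[12:], y[12:], epochs=0, seed=3)
        assert len(net.history) == 1
        assert np.all(np.isfinite(net.predict(X)))

    def test_same_seed_gives_bit_identical_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(0, 0.1, 30)
        spec = NetworkSpec((2, 1, 2), (2, 1, 2), ("a", "b", "c"), "y")
        nets = [train(spec, X[:20], y[:20], X[20:], y[20:], epochs=20, seed=7)
                for _ in range(2)]
        for name in ("W1", "b1", "W2", "b2", "w_out"):
            assert np.array_equal(getattr(nets[0], name),
                                  getattr(nets[1], name))
        assert nets[0].b_out == nets[1].b_out


class TestEvaluate:
    class _Fixed(TrainedNetwork):
        """Network stub returning canned predictions."""

        def __init__(self, preds):
            self._preds = np.asarray(preds, float)

        def predict(self, X):
            return self._preds

    def test_perfect_predictions(self):
        y = np.array([0.0, 1.0, 2.0])
        m = evaluate(self._Fixed(y), None, y)
        assert m.r_squared == 1.0 and m.rase == 0.0 and m.mad == 0.0

    def test_constant_at_mean_gives_zero_r2(self):
        y = np.array([0.0, 1.0, 2.0])
        m = evaluate(self._Fixed([1.0, 1.0, 1.0]), None, y)
        assert m.r_squared == pytest.approx(0.0)

    def test_hand_computed_metrics(self):
        y = np.array([0.0, 1.0, 2.0])
        m = evaluate(self._Fixed([0.0, 1.0, 1.0]), None, y)
        assert m.sse == pytest.approx(1.0)
        assert m.rase == pytest.approx(np.sqrt(1 / 3))
        assert m.mad == pytest.approx(1 / 3)

    def test_zero_response_variance_flagged(self):
        m = evaluate(self._Fixed([1.0, 1.0]), None, np.array([3.0, 3.0]))
        assert not m.valid and np.isnan(m.r_squared)


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    spec = NetworkSpec((2, 1, 2), (1, 1, 1), ("a", "b"), "Rmax")
    net = _init_network(spec, rng.normal(size=2), rng.uniform(1, 2, 2),
                        0.01, 0.004, rng, 0.4)
    save_model(net, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    X = rng.normal(size=(5, 2))
    assert np.allclose(net.predict(X), back.predict(X), atol=1e-15)
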