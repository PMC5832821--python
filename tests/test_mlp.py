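"""The three-layer perceptron: initialisation, forward pass, backprop, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anninfer import Hyperparameters, MLPModel, init_model, train
from anninfer.mlp import backprop_step, forward, gradient


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestInit:
    def test_deterministic(self):
        a = init_model(5, seed=3)
        b = init_model(5, seed=3)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)

    def test_architecture_shapes(self):
        m = init_model(99, Hyperparameters(n_hidden=2), seed=0)
        assert m.W1.shape == (100, 2)
        assert m.W2.shape == (3,)
        assert m.n_inputs == 99

    def test_weight_sd_matches_init_sd(self):
        # ~10k draws: sample SD within a chi-square-style band around 0.1
        m = init_model(2499, Hyperparameters(n_hidden=4), seed=1)
        draws = np.concatenate([m.W1.ravel(), m.W2.ravel()])
        assert draws.size >= 10_000
        assert abs(draws.std(ddof=1) - 0.1) < 0.005

    def test_velocity_starts_at_zero(self):
        m = init_model(3, seed=0)
        assert not m.vW1.any() and not m.vW2.any()

    @pytest.mark.parametrize("kwargs", [
        {"learning_rate": 0.0}, {"momentum": 1.0}, {"init_sd": -1.0},
        {"n_hidden": 0}, {"patience": 0},
    ])
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparameters(**kwargs)


class TestForward:
    def test_zero_weights_give_half(self):
        m = MLPModel(np.zeros((4, 2)), np.zeros(3), Hyperparameters())
        _, out = forward(m, [0.3, 0.9, 0.1])
        assert out == 0.5

    @pytest.mark.parametrize("z", [1.0, 3.7])
    def test_sigmoid_symmetry(self, z):
        assert sigmoid(0) == 0.5
        assert sigmoid(z) + sigmoid(-z) == pytest.approx(1.0, abs=1e-15)

    def test_hand_computed_output(self):
        # 1 input, 1 hidden, unit weights, zero biases, x=0:
        # hidden = sigmoid(0) = 0.5; output = sigmoid(0.5) ~ 0.6225
        hyper = Hyperparameters(n_hidden=1)
        m = MLPModel(np.array([[1.0], [0.0]]), np.array([1.0, 0.0]), hyper)
        hidden, out = forward(m, [0.0])
        assert hidden[0] == 0.5
        assert out == pytest.approx(sigmoid(0.5), abs=1e-12)
        assert out == pytest.approx(0.62245933, abs=1e-7)

    def test_dimension_mismatch_rejected(self):
        m = init_model(3, seed=0)
        with pytest.raises(ValueError, match="length"):
            forward(m, [0.1, 0.2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_in_open_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = init_model(4, seed=seed)
        _, out = forward(m, rng.random(4))
        assert 0.0 < out < 1.0


class TestBackprop:
    def test_zero_rates_leave_weights_unchanged(self):
        hyper = Hyperparameters(learning_rate=1e-300, momentum=0.0)
        m = init_model(3, hyper, seed=2)
        W1, W2 = m.W1.copy(), m.W2.copy()
        backprop_step(m, [0.1, 0.5, 0.9], 1.0)
        np.testing.assert_allclose(m.W1, W1, atol=1e-290)
        np.testing.assert_allclose(m.W2, W2, atol=1e-290)

    def test_gradient_matches_finite_differences(self):
        # analytic backprop vs central differences on a random 3-input model
        rng = np.random.default_rng(7)
        m = init_model(3, seed=7)
        x = rng.random(3)
        y = 0.3
        gW1, gW2, _ = gradient(m, x, y)

        def loss(W1, W2):
            mm = MLPModel(W1, W2, m.hyper)
            _, out = forward(mm, x)
            return 0.5 * (out - y) ** 2

        h = 1e-6
        for (i, j), g in np.ndenumerate(gW1):
            W1p, W1m = m.W1.copy(), m.W1.copy()
            W1p[i, j] += h
            W1m[i, j] -= h
            num = (loss(W1p, m.W2) - loss(W1m, m.W2)) / (2 * h)
            assert g == pytest.approx(num, rel=1e-5, abs=1e-12)
        for j, g in enumerate(gW2):
            W2p, W2m = m.W2.copy(), m.W2.copy()
            W2p[j] += h
            W2m[j] -= h
            num = (loss(m.W1, W2p) - loss(m.W1, W2m)) / (2 * h)
            assert g == pytest.approx(num, rel=1e-5, abs=1e-12)

    def test_momentum_recurrence_on_frozen_gradient(self):
        # second of two identical updates is 1.5x a single -lr*g step
        # (to first order; a tiny lr freezes the gradient)
        hyper = Hyperparameters(learning_rate=1e-9, momentum=0.5)
        m = init_model(2, hyper, seed=4)
        x, y = np.array([0.2, 0.8]), 1.0
        g0, _, _ = gradient(m, x, y)
        backprop_step(m, x, y)
        step1 = m.vW1.copy()
        backprop_step(m, x, y)
        step2 = m.vW1.copy()
        np.testing.assert_allclose(step1, -1e-9 * g0, rtol=1e-6)
        np.testing.assert_allclose(step2, 1.5 * step1, rtol=1e-6)

    def test_velocity_stores_applied_update(self):
        m = init_model(2, seed=5)
        W1_before = m.W1.copy()
        backprop_step(m, [0.4, 0.6], 0.0)
        np.testing.assert_allclose(m.W1 - W1_before, m.vW1)


class TestTrain:
    def _separable_toy(self):
        # one informative input: class equals x > 0.5; last two rows are
        # held-out monitor points
        X = np.array([[0.0], [0.1], [0.9], [1.0], [0.2], [0.8]])
        y = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        return X, y

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = self._separable_toy()
        hyper = Hyperparameters(learning_rate=0.5, max_epochs=3000, patience=3000)
        model, _ = train(X, y, np.arange(4), np.array([4, 5]), hyper, seed=0)
        from anninfer._kernels import predict_batch
        pred = predict_batch(model.W1, model.W2, X[:4])
        assert np.all((pred > 0.5).astype(float) == y[:4])

    def test_training_reduces_mse_on_toy(self):
        X, y = self._separable_toy()
        hyper = Hyperparameters(learning_rate=0.5, max_epochs=500, patience=500)
        model, trace = train(X, y, np.arange(4), np.array([4, 5]),
                             hyper, seed=1)
        init = init_model(1, hyper, seed=1)
        from anninfer._kernels import predict_batch
        mse = lambda m: float(np.mean((predict_batch(m.W1, m.W2, X[:4]) - y[:4]) ** 2))
        assert mse(model) <= mse(init)

    def test_single_epoch_when_capped(self):
        X, y = self._separable_toy()
        hyper = Hyperparameters(max_epochs=1, patience=1)
        _, trace = train(X, y, np.array([0, 1, 2]), np.array([3]), hyper, seed=0)
        assert trace.n_epochs == 1
        assert trace.epoch_selected == 0

    def test_deterministic_trace(self):
        rng = np.random.default_rng(2)
        X, y = rng.random((30, 2)), rng.integers(0, 2, 30).astype(float)
        idx = np.arange(30)
        args = (X, y, idx[:20], idx[20:], Hyperparameters(max_epochs=30), 12)
        m1, t1 = train(*args)
        m2, t2 = train(*args)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(t1.test_mse, t2.test_mse)
        assert t1.epoch_selected == t2.epoch_selected

    def test_overlapping_splits_rejected(self):
        X, y = self._separable_toy()
        with pytest.raises(ValueError, match="disjoint"):
            train(X, y, np.array([0, 1]), np.array([1, 2]))

    def test_empty_split_rejected(self):
        X, y = self._separable_toy()
        with pytest.raises(ValueError, match="non-empty"):
            train(X, y, np.array([], dtype=int), np.array([0]))

    def test_targets_outside_unit_interval_rejected(self):
        X = np.random.default_rng(0).random((5, 1))
        with pytest.raises(ValueError, match="0, 1"):
            train(X, np.array([0, 1, 2, 0, 1.0]), np.arange(3), np.arange(3, 5))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_weights_stay_finite_on_scaled_inputs(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((25, 3))
        y = rng.integers(0, 2, 25).astype(float)
        hyper = Hyperparameters(max_epochs=40)
        model, _ = train(X, y, np.arange(15), np.arange(15, 25), hyper, seed=seed)
        assert np.all(np.isfinite(model.W1)) and np.all(np.isfinite(model.W2))

    def test_model_json_round_trip(self, tmp_path):
        m = init_model(4, seed=6)
        path = tmp_path / "model.json"
        m.to_json(path, seed=6)
        back = MLPModel.from_json(path)
        np.testing.assert_array_equal(back.W1, m.W1)
        np.testing.assert_array_equal(back.W2, m.W2)
        assert back.hyper == m.hyper
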