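import numpy as np
import pytest

import fitrx as fx
from fitrx.network import (
    LayerSpec,
    LMState,
    NetworkState,
    TrainConfig,
    _zero_params,
    forward,
    forward_batch,
    gradient,
    hidden_neuron_range,
    init_network,
    jacobian,
    lm_step,
    load_checkpoint,
    loss,
    save_checkpoint,
    train,
)


def zero_net(sizes, hidden="tanh", output="identity"):
    spec = LayerSpec(sizes=sizes, hidden_activation=hidden, output_activation=output)
    return NetworkState(spec, *_zero_params(spec))


def naive_forward(state, x):
    """Independent loop-based evaluation used as the oracle."""
    a = list(state._scale_inputs(np.asarray(x, dtype=float)))
    n_layers = len(state.weights)
    for l, (W, b) in enumerate(zip(state.weights, state.biases)):
        z = [sum(a[i] * W[i, j] for i in range(W.shape[0])) + b[j]
             for j in range(W.shape[1])]
        if l == n_layers - 1 and state.spec.output_activation == "identity":
            a = z
        else:
            a = [np.tanh(v) for v in z]
    return np.array(a)


class TestForward:
    def test_zero_network_outputs_zero(self):
        net = zero_net((5, 12, 10, 8, 4))
        np.testing.assert_array_equal(forward(net, [70, 1, 25, 20, 0.1]), np.zeros(4))

    def test_single_unit_composition(self):
        net = zero_net((1, 1))
        net.weights[0][0, 0] = 1.0
        # single layer uses the identity output activation
        assert forward(net, [0.7])[0] == pytest.approx(0.7)
        net2 = zero_net((1, 1, 1))
        net2.weights[0][0, 0] = 1.0
        net2.weights[1][0, 0] = 1.0
        assert forward(net2, [0.7])[0] == pytest.approx(np.tanh(0.7))

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        net = init_network(LayerSpec((5, 6, 4)), rng)
        for _ in range(5):
            x = rng.uniform(-1, 1, 5)
            np.testing.assert_allclose(forward(net, x), naive_forward(net, x), atol=1e-12)

    def test_nonfinite_input_rejected(self):
        net = zero_net((5, 4))
        with pytest.raises(ValueError):
            forward(net, [np.nan, 0, 0, 0, 0])


class TestLoss:
    def test_perfect_fit_zero_loss(self):
        net = zero_net((2, 1))
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        Y = np.zeros((2, 1))
        parts = loss(net, X, Y, alpha=0.0)
        assert parts.total == 0.0

    def test_penalty_isolated_from_fit(self):
        rng = np.random.default_rng(1)
        net = init_network(LayerSpec((2, 3, 1)), rng)
        X = rng.uniform(-1, 1, (10, 2))
        Y = forward_batch(net, X)
        parts = loss(net, X, Y, alpha=0.01)
        w = net.flatten()[net.weight_mask()]
        assert parts.mse == pytest.approx(0.0, abs=1e-25)
        assert parts.penalty == pytest.approx(0.01 * np.sum(w**2))

    def test_single_residual_definition(self):
        net = zero_net((1, 1))
        parts = loss(net, np.array([[1.0]]), np.array([[3.0]]), alpha=0.0)
        assert parts.total == pytest.approx(9.0)

    def test_biases_included_when_requested(self):
        net = zero_net((1, 1))
        net.biases[0][0] = 2.0
        X, Y = np.array([[0.0]]), np.array([[2.0]])
        assert loss(net, X, Y, 0.1).penalty == 0.0
        assert loss(net, X, Y, 0.1, penalize_biases=True).penalty == pytest.approx(0.4)

    def test_empty_data_rejected(self):
        net = zero_net((1, 1))
        with pytest.raises(ValueError):
            loss(net, np.empty((0, 1)), np.empty((0, 1)), 0.0)


class TestJacobian:
    def test_analytic_matches_finite_difference(self):
        rng = np.random.default_rng(2)
        net = init_network(LayerSpec((5, 12, 10, 8, 4)), rng)
        X = rng.uniform(-1, 1, (8, 5))
        Y = rng.uniform(-1, 1, (8, 4))
        Ja, ra = jacobian(net, X, Y, mode="analytic")
        Jf, rf = jacobian(net, X, Y, mode="finite-difference", fd_step=1e-5)
        np.testing.assert_array_equal(ra, rf)
        rel = np.max(np.abs(Ja - Jf)) / np.max(np.abs(Ja))
        assert rel <= 1e-4

    def test_linear_net_columns_equal_inputs(self):
        net = zero_net((3, 1))
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (6, 3))
        Y = np.zeros((6, 1))
        J, _ = jacobian(net, X, Y, mode="analytic")
        # columns 0..2 are the output-layer weights; they equal the inputs
        np.testing.assert_allclose(J[:, :3], X, atol=1e-12)
        np.testing.assert_allclose(J[:, 3], np.ones(6), atol=1e-12)

    def test_forward_difference_error_scales_with_step(self):
        rng = np.random.default_rng(4)
        net = init_network(LayerSpec((3, 5, 2)), rng)
        X = rng.uniform(-1, 1, (6, 3))
        Y = rng.uniform(-1, 1, (6, 2))
        Ja, _ = jacobian(net, X, Y, mode="analytic")
        err = {}
        for step in (1e-5, 2e-5):
            Jf, _ = jacobian(net, X, Y, mode="finite-difference", fd_step=step)
            err[step] = np.linalg.norm(Jf - Ja)
        ratio = err[2e-5] / err[1e-5]
        assert 1.4 < ratio < 2.9  # first-order truncation: error ~ O(step)

    def test_row_ordering_is_sample_major(self):
        rng = np.random.default_rng(5)
        net = init_network(LayerSpec((2, 3, 2)), rng)
        X = rng.uniform(-1, 1, (4, 2))
        Y = np.zeros((4, 2))
        _, r = jacobian(net, X, Y)
        np.testing.assert_allclose(r, (forward_batch(net, X) - Y).ravel())


class TestLMStep:
    def test_one_step_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (20, 2))
        w_true, b_true = np.array([1.5, -0.7]), 0.3
        Y = (X @ w_true + b_true)[:, None]
        net = zero_net((2, 1))
        cfg = TrainConfig(alpha=1e-12, lambda0=1e-9)
        lm = LMState(lam=1e-9)
        new, accepted = lm_step(lm, net, X, Y, cfg)
        assert accepted
        A = np.hstack([X, np.ones((20, 1))])
        closed = np.linalg.lstsq(A, Y.ravel(), rcond=None)[0]
        np.testing.assert_allclose(new.flatten(), closed, atol=1e-8)

    def test_accepted_losses_monotone_nonincreasing(self, teacher_data):
        X, Y, _ = teacher_data
        cfg = TrainConfig(alpha=0.001, lambda0=0.01)
        net = init_network(LayerSpec(), np.random.default_rng(7))
        lm = LMState(lam=cfg.lambda0)
        losses = [loss(net, X, Y, cfg.alpha).total]
        for _ in range(40):
            net, accepted = lm_step(lm, net, X, Y, cfg)
            if accepted:
                losses.append(loss(net, X, Y, cfg.alpha).total)
        assert all(b <= a + 1e-15 for a, b in zip(losses, losses[1:]))
        assert len(losses) > 10

    def test_large_damping_gives_scaled_gradient_step(self):
        rng = np.random.default_rng(8)
        net = init_network(LayerSpec((3, 4, 2)), rng)
        X = rng.uniform(-1, 1, (10, 3))
        Y = rng.uniform(-1, 1, (10, 2))
        lam = 1e8
        cfg = TrainConfig(alpha=1e-12, lambda0=lam)
        lm = LMState(lam=lam)
        _, accepted = lm_step(lm, net, X, Y, cfg)
        assert accepted
        J, r = jacobian(net, X, Y)
        expected = (J.T @ r) / r.size / lam  # Delta w -> J^T e / lambda
        np.testing.assert_allclose(lm.delta_w, expected, rtol=1e-3)

    def test_damping_stays_positive_and_bounded(self, teacher_data):
        X, Y, _ = teacher_data
        cfg = TrainConfig(alpha=0.0, lambda0=0.01)
        net = init_network(LayerSpec(), np.random.default_rng(10))
        lm = LMState(lam=cfg.lambda0)
        for _ in range(30):
            net, _ = lm_step(lm, net, X[:100], Y[:100], cfg)
            assert cfg.lambda_min <= lm.lam <= cfg.lambda_max


class TestTrain:
    def test_realizable_target_reaches_low_mse(self, teacher_fit):
        final_mse = teacher_fit.history.train_mse.iloc[-1]
        assert final_mse < 1e-6

    def test_fixed_seed_reproduces_trajectory(self, teacher_data):
        X, Y, _ = teacher_data
        cfg = TrainConfig(alpha=0.001, max_epochs=30, patience=30)
        runs = []
        for _ in range(2):
            net = init_network(LayerSpec(), np.random.default_rng(11))
            runs.append(train(net, X[:150], Y[:150], X[150:200], Y[150:200], cfg))
        np.testing.assert_array_equal(runs[0].state.flatten(), runs[1].state.flatten())
        assert runs[0].history.equals(runs[1].history)

    def test_patience_one_with_val_equal_train_runs_to_plateau(self, teacher_data):
        X, Y, _ = teacher_data
        cfg = TrainConfig(alpha=0.0, max_epochs=100, patience=1)
        net = init_network(LayerSpec(), np.random.default_rng(12))
        res = train(net, X[:150], Y[:150], X[:150], Y[:150], cfg)
        # every epoch but possibly the last must be an accepted improvement
        assert res.history.accepted.iloc[:-1].all()
        assert len(res.history) > 5

    def test_best_validation_snapshot_returned(self, teacher_data):
        X, Y, _ = teacher_data
        cfg = TrainConfig(alpha=0.0, max_epochs=60, patience=10)
        net = init_network(LayerSpec(), np.random.default_rng(13))
        res = train(net, X[:150], Y[:150], X[150:250], Y[150:250], cfg)
        returned = loss(res.state, X[150:250], Y[150:250], 0.0).mse
        assert returned == pytest.approx(res.history.val_mse.min())

    def test_gradient_descent_divergence_aborts(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(-1, 1, (20, 2))
        Y = X @ np.array([[1.0], [2.0]])
        net = init_network(LayerSpec((2, 1)), rng)
        cfg = TrainConfig(alpha=0.0, algorithm="gd", eta=10.0, beta=0.9,
                          max_epochs=500, patience=500)
        with pytest.raises(FloatingPointError):
            train(net, X, Y, X, Y, cfg)

    def test_gradient_descent_baseline_learns(self, teacher_data):
        X, Y, _ = teacher_data
        cfg = TrainConfig(alpha=0.0, algorithm="gd", eta=0.05, beta=0.9,
                          max_epochs=200, patience=200)
        net = init_network(LayerSpec(), np.random.default_rng(15))
        start = loss(net, X[:150], Y[:150], 0.0).mse
        res = train(net, X[:150], Y[:150], X[150:200], Y[150:200], cfg)
        assert res.history.train_mse.iloc[-1] < start


class TestLinearLimit:
    def test_matches_penalty_matched_ridge_closed_form(self):
        rng = np.random.default_rng(16)
        X = rng.uniform(-1, 1, (60, 5))
        Y = X @ rng.normal(size=(5, 4)) + rng.normal(size=4)
        alpha = 0.001
        cfg = TrainConfig(alpha=alpha, max_epochs=300, patience=300,
                          error_precision=1e-15)
        net = init_network(LayerSpec((5, 4)), rng)
        res = train(net, X, Y, X, Y, cfg)
        n, m = Y.shape
        A = np.hstack([X, np.ones((n, 1))])
        D = np.diag([1.0] * 5 + [0.0])  # bias unpenalized
        P = np.linalg.solve(A.T @ A / (n * m) + alpha * D, A.T @ Y / (n * m))
        W_fit = res.final_state.weights[0]
        b_fit = res.final_state.biases[0]
        np.testing.assert_allclose(W_fit, P[:5], atol=1e-6)
        np.testing.assert_allclose(b_fit, P[5], atol=1e-6)


class TestGradient:
    def test_matches_finite_difference_of_loss(self):
        rng = np.random.default_rng(17)
        net = init_network(LayerSpec((3, 4, 2)), rng)
        X = rng.uniform(-1, 1, (10, 3))
        Y = rng.uniform(-1, 1, (10, 2))
        g = gradient(net, X, Y, alpha=0.01)
        w0 = net.flatten()
        num = np.empty_like(w0)
        h = 1e-6
        for j in range(len(w0)):
            wp, wm = w0.copy(), w0.copy()
            wp[j] += h
            wm[j] -= h
            num[j] = (
                loss(net.with_params(wp), X, Y, 0.01).total
                - loss(net.with_params(wm), X, Y, 0.01).total
            ) / (2 * h)
        np.testing.assert_allclose(g, num, atol=1e-6)


class TestHiddenNeuronRange:
    def test_default_range(self):
        assert hidden_neuron_range(5, 4) == [4, 5, 6, 7, 8, 9, 10, 11, 12, 13]

    def test_small_case(self):
        assert hidden_neuron_range(3, 1, a_range=[1]) == [3]

    def test_strictly_increasing_in_a(self):
        widths = hidden_neuron_range(5, 4)
        assert all(b == a + 1 for a, b in zip(widths, widths[1:]))

    def test_a_outside_rule_rejected(self):
        with pytest.raises(ValueError):
            hidden_neuron_range(5, 4, a_range=[0, 1])


def test_checkpoint_round_trip(tmp_path, teacher_fit):
    path = tmp_path / "model.json"
    state = teacher_fit.state
    save_checkpoint(state, path, cfg=TrainConfig(), meta={"note": "test"})
    back = load_checkpoint(path)
    np.testing.assert_array_equal(back.flatten(), state.flatten())
    assert back.spec == state.spec


def test_checkpoint_preserves_input_scaling(tmp_path):
    rng = np.random.default_rng(18)
    net = init_network(LayerSpec((5, 4)), rng)
    X = rng.uniform(0, 100, (20, 5))
    net.set_input_scaling(X)
    path = tmp_path / "m.json"
    save_checkpoint(net, path)
    back = load_checkpoint(path)
    np.testing.assert_allclose(
        forward_batch(back, X[:5]), forward_batch(net, X[:5]), atol=1e-12
    )
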