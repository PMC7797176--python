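"""Cell arithmetic, output heads, masked loss and gradient correctness."""

import math

import numpy as np
import pytest

import adprog as ap
from adprog.training import (
    TrainConfig,
    _loss_and_grads,
    init_params,
    lss_step,
    minimal_rnn_step,
    predict_next,
    sequence_loss,
)


def _zero_params(cfg, nv=25):
    params = init_params(cfg, np.random.default_rng(0), nv)
    return {k: np.zeros_like(v) for k, v in params.items()}


class TestMinimalRnnStep:
    def test_zero_parameters_halve_the_state(self):
        cfg = TrainConfig(hidden=4, layers=1)
        params = _zero_params(cfg)
        h_prev = np.array([1.0, -2.0, 0.5, 3.0])
        h = minimal_rnn_step(h_prev, np.ones(25), params)
        # u = tanh(0) = 0, f = sigmoid(0) = 0.5, h = 0.5 * h_prev
        np.testing.assert_allclose(h, 0.5 * h_prev)

    def test_saturated_gate_gives_perfect_memory(self):
        cfg = TrainConfig(hidden=3, layers=1)
        params = _zero_params(cfg)
        params["l0.bf"] = np.full(3, 50.0)
        h_prev = np.array([0.3, -0.7, 1.1])
        h = minimal_rnn_step(h_prev, np.random.default_rng(1).normal(size=25), params)
        np.testing.assert_allclose(h, h_prev, atol=1e-12)

    def test_matches_scalar_oracle_on_toy_weights(self):
        # independent element-by-element evaluation of the update equations
        rng = np.random.default_rng(7)
        d, nin = 2, 3
        Wx = rng.normal(size=(d, nin))
        bu = rng.normal(size=d)
        Uh = rng.normal(size=(d, d))
        Uu = rng.normal(size=(d, d))
        bf = rng.normal(size=d)
        params = {"l0.Wx": Wx, "l0.bu": bu, "l0.Uh": Uh, "l0.Uu": Uu, "l0.bf": bf}
        x = rng.normal(size=nin)
        h_prev = rng.normal(size=d)
        h = minimal_rnn_step(h_prev, x, params)
        for i in range(d):
            u_i = math.tanh(sum(Wx[i, j] * x[j] for j in range(nin)) + bu[i])
            # the gate needs the full u vector
            u = [math.tanh(sum(Wx[r, j] * x[j] for j in range(nin)) + bu[r])
                 for r in range(d)]
            a = sum(Uh[i, j] * h_prev[j] for j in range(d))
            a += sum(Uu[i, j] * u[j] for j in range(d)) + bf[i]
            f_i = 1.0 / (1.0 + math.exp(-a))
            expected = f_i * h_prev[i] + (1 - f_i) * u_i
            assert abs(h[i] - expected) < 1e-12

    def test_gate_keeps_state_bounded(self):
        rng = np.random.default_rng(3)
        cfg = TrainConfig(hidden=8, layers=1)
        params = init_params(cfg, rng)
        h = np.zeros(8)
        for _ in range(200):
            h = minimal_rnn_step(h, rng.normal(size=25), params)
            assert np.max(np.abs(h)) <= 1.0 + 1e-12  # convex mix of h and tanh


class TestLssStep:
    def test_identity_dynamics(self):
        d = 4
        params = {"l0.A": np.eye(d), "l0.B": np.zeros((d, 25)), "l0.b": np.zeros(d)}
        h = np.array([1.0, 2.0, -3.0, 0.5])
        for _ in range(5):
            h_new = lss_step(h, np.random.default_rng(0).normal(size=25), params)
            np.testing.assert_allclose(h_new, h)
            h = h_new

    def test_memoryless_when_A_zero(self):
        rng = np.random.default_rng(2)
        d = 3
        B = rng.normal(size=(d, 25))
        b = rng.normal(size=d)
        params = {"l0.A": np.zeros((d, d)), "l0.B": B, "l0.b": b}
        x = rng.normal(size=25)
        h1 = lss_step(rng.normal(size=d), x, params)
        h2 = lss_step(rng.normal(size=d) * 100, x, params)
        np.testing.assert_allclose(h1, h2)
        np.testing.assert_allclose(h1, B @ x + b)

    def test_stable_A_decays_to_closed_form(self):
        rng = np.random.default_rng(5)
        d = 4
        A = rng.normal(size=(d, d))
        A *= 0.8 / max(abs(np.linalg.eigvals(A)))
        params = {"l0.A": A, "l0.B": np.zeros((d, 25)), "l0.b": np.zeros(d)}
        h0 = rng.normal(size=d)
        h = h0.copy()
        for t in range(1, 30):
            h = lss_step(h, np.zeros(25), params)
            np.testing.assert_allclose(h, np.linalg.matrix_power(A, t) @ h0,
                                       rtol=1e-9, atol=1e-12)
        assert np.linalg.norm(h) < 1e-2 * np.linalg.norm(h0)


class TestPredictNext:
    def test_zero_weights_give_uniform_softmax_and_bias(self):
        cfg = TrainConfig(hidden=6, layers=1)
        params = _zero_params(cfg)
        params["bg"] = np.arange(22.0)
        probs, g = predict_next(np.random.default_rng(0).normal(size=6), params)
        np.testing.assert_allclose(probs, 1.0 / 3.0)
        np.testing.assert_allclose(g, np.arange(22.0))

    def test_probabilities_on_simplex_for_random_params(self):
        rng = np.random.default_rng(4)
        cfg = TrainConfig(hidden=5, layers=1)
        for _ in range(200):
            params = init_params(cfg, rng)
            probs, _ = predict_next(rng.normal(size=5) * 10, params)
            assert probs.sum() == pytest.approx(1.0)
            # mathematically in (0,1); saturated logits may round to {0,1}
            assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(9)
        Ws = rng.normal(size=(3, 2))
        bs = rng.normal(size=3)
        Wg = rng.normal(size=(22, 2))
        bg = rng.normal(size=22)
        params = {"Ws": Ws, "bs": bs, "Wg": Wg, "bg": bg}
        h = rng.normal(size=2)
        probs, g = predict_next(h, params)
        logits = Ws @ h + bs
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(probs, e / e.sum(), atol=1e-12)
        np.testing.assert_allclose(g, Wg @ h + bg, atol=1e-12)


class TestSequenceLoss:
    def test_perfect_predictions_give_zero(self):
        T = 4
        targets = np.zeros((T, 25))
        targets[:, 1] = 1.0  # MCI throughout
        targets[:, 3:] = 0.7
        observed = np.ones((T, 23), dtype=bool)
        probs = np.tile([0.0, 1.0, 0.0], (T - 1, 1))
        g_hat = np.full((T - 1, 22), 0.7)
        assert sequence_loss(probs, g_hat, targets, observed) == pytest.approx(0.0)

    def test_uniform_softmax_single_diagnosis_is_ln3(self):
        T = 2
        targets = np.zeros((T, 25))
        targets[1, 0] = 1.0
        observed = np.zeros((T, 23), dtype=bool)
        observed[1, 0] = True
        probs = np.full((1, 3), 1.0 / 3.0)
        g_hat = np.zeros((1, 22))
        loss = sequence_loss(probs, g_hat, targets, observed)
        assert loss == pytest.approx(math.log(3.0), abs=1e-12)

    def test_masked_equals_dense_subsequence(self):
        # brute-force recomputation on the extracted observed subset
        rng = np.random.default_rng(12)
        T = 8
        targets = rng.normal(size=(T, 25))
        targets[:, :3] = 0
        targets[np.arange(T), rng.integers(0, 3, T)] = 1
        observed = rng.random((T, 23)) < 0.5
        probs = rng.dirichlet(np.ones(3), size=T - 1)
        g_hat = rng.normal(size=(T - 1, 22))
        loss = sequence_loss(probs, g_hat, targets, observed)
        manual = 0.0
        for t in range(1, T):
            if observed[t, 0]:
                c = int(np.argmax(targets[t, :3]))
                manual -= math.log(probs[t - 1, c])
            for j in range(22):
                if observed[t, 1 + j]:
                    manual += abs(targets[t, 3 + j] - g_hat[t - 1, j]) / 22.0
        assert loss == pytest.approx(manual, rel=1e-12)

    def test_no_observed_target_raises(self):
        targets = np.zeros((3, 25))
        observed = np.zeros((3, 23), dtype=bool)
        observed[0, :] = True  # first timepoint is never a target
        with pytest.raises(ValueError):
            sequence_loss(np.ones((2, 3)) / 3, np.zeros((2, 22)), targets, observed)


def _grad_check(cell, strategy, layers, seed=0):
    rng = np.random.default_rng(seed)
    cfg = TrainConfig(cell=cell, hidden=4, layers=layers, l2=1e-4,
                      input_dropout=0.0, recurrent_dropout=0.0)
    B, T, nv, nf = 2, 5, 25, 23
    params = init_params(cfg, rng, nv)
    X = rng.normal(size=(B, T, nv))
    X[:, :, :3] = 0
    X[np.arange(B)[:, None], np.arange(T)[None, :], rng.integers(0, 3, (B, T))] = 1
    obs = rng.random((B, T, nf)) < 0.6
    valid = np.ones((B, T), dtype=bool)
    vm = np.concatenate([np.repeat(obs[..., :1], 3, -1), obs[..., 1:]], -1)
    Xn = X.copy()
    Xn[~vm] = np.nan
    means = rng.normal(size=nv) * 0.1
    X_in = Xn if strategy == "model" else X
    _, grads, _, _ = _loss_and_grads(
        params, cfg, X_in, Xn, obs, valid, means, strategy, training=False
    )
    for k in params:
        num = np.zeros_like(params[k])
        it = np.nditer(num, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            eps = 1e-6
            params[k][i] += eps
            lp = _loss_and_grads(params, cfg, X_in, Xn, obs, valid, means,
                                 strategy, training=False)[0]
            params[k][i] -= 2 * eps
            lm = _loss_and_grads(params, cfg, X_in, Xn, obs, valid, means,
                                 strategy, training=False)[0]
            params[k][i] += eps
            num[i] = (lp - lm) / (2 * eps)
        scale = max(1e-8, np.max(np.abs(num)))
        assert np.max(np.abs(num - grads[k])) / scale < 1e-5, k


@pytest.mark.parametrize(
    "cell,strategy,layers",
    [
        ("minimal_rnn", "forward", 1),
        ("minimal_rnn", "model", 1),
        ("minimal_rnn", "model", 2),
        ("lss", "model", 1),
    ],
)
def test_backprop_matches_finite_differences(cell, strategy, layers):
    """The hand-derived backward pass agrees with numerical gradients."""
    _grad_check(cell, strategy, layers)
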