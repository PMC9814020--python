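"""Recurrent learners: cell equations, T-BPTT and RTRL gradient oracles,
trace augmentation, and training-protocol properties."""

import numpy as np
import pytest

from tracebench import _cells
from tracebench.environments import TraceConditioningConfig, make_env
from tracebench.recurrent import (
    RecurrentAgent, RecurrentConfig, TraceAugmenter, augment_with_traces,
    init_params, run_recurrent_agent,
)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Independent reference implementations of the gate equations.  These use
# split weight matrices (input / recurrent / bias) rather than the packed
# [o; h; 1] layout of the kernels.
# ---------------------------------------------------------------------------

def ref_rnn(W, h, o, m, n):
    Wx, Wh, b = W[:, :m], W[:, m:m + n], W[:, -1]
    return np.tanh(Wx @ o + Wh @ h + b)


def ref_lstm(W, h, c, o, m, n):
    def block(j):
        rows = slice(j * n, (j + 1) * n)
        return W[rows, :m] @ o + W[rows, m:m + n] @ h + W[rows, -1]

    i = sigmoid(block(0))
    f = sigmoid(block(1))
    g = np.tanh(block(2))
    out = sigmoid(block(3))
    c_new = f * c + i * g
    return out * np.tanh(c_new), c_new


def ref_gru(Wz, Wr, Wc, h, o, m, n):
    def lin(W, hvec):
        return W[:, :m] @ o + W[:, m:m + n] @ hvec + W[:, -1]

    z = sigmoid(lin(Wz, h))
    r = sigmoid(lin(Wr, h))
    cand = np.tanh(lin(Wc, r * h))
    return (1.0 - z) * h + z * cand


@pytest.mark.parametrize("arch", ["rnn", "lstm", "gru"])
def test_cell_forward_matches_reference(arch):
    m, n = 5, 7
    rng = np.random.default_rng(0)
    params = init_params(arch, m, n, rng)
    for k, v in params.items():
        if k not in ("w_out", "b_out"):
            params[k] = rng.normal(scale=0.4, size=v.shape)
    h = rng.normal(scale=0.3, size=n)
    c = rng.normal(scale=0.3, size=n)
    for _ in range(20):
        o = rng.random(m)
        if arch == "rnn":
            got = _cells.rnn_cell(params["W"], h, o)
            want = ref_rnn(params["W"], h, o, m, n)
            h = got
        elif arch == "lstm":
            got, c_got = _cells.lstm_cell(params["W"], h, c, o)
            want, c_want = ref_lstm(params["W"], h, c, o, m, n)
            assert np.abs(c_got - c_want).max() < 1e-6
            h, c = got, c_got
        else:
            got = _cells.gru_cell(params["Wz"], params["Wr"], params["Wc"], h, o)
            want = ref_gru(params["Wz"], params["Wr"], params["Wc"], h, o, m, n)
            h = got
        assert np.abs(got - want).max() < 1e-6


def test_zero_weights_zero_state_value_is_bias():
    cfg = RecurrentConfig(architecture="rnn", n_hidden=4)
    agent = RecurrentAgent(3, cfg, rng=np.random.default_rng(0))
    agent.params["W"][:] = 0.0
    agent.params["b_out"][0] = 0.25
    v = agent.observe(np.zeros(3), 0.0)
    assert np.all(agent.h == 0.0)
    assert v == pytest.approx(0.25)


def test_gru_saturated_update_gate_copies_candidate():
    m, n = 3, 5
    rng = np.random.default_rng(1)
    params = init_params("gru", m, n, rng)
    params["Wz"][:, -1] = 50.0  # drive the update gate to 1
    h = rng.normal(scale=0.5, size=n)
    o = rng.random(m)
    h_new = _cells.gru_cell(params["Wz"], params["Wr"], params["Wc"], h, o)
    r = sigmoid(params["Wr"] @ np.r_[o, h, 1.0])
    cand = np.tanh(params["Wc"] @ np.r_[o, r * h, 1.0])
    assert np.abs(h_new - cand).max() < 1e-6


# ---------------------------------------------------------------------------
# Gradient oracles
# ---------------------------------------------------------------------------

def window_loss_frozen_targets(params, arch, h0, c0, obs, targets):
    """Forward-only window loss with the TD targets held fixed."""
    h, c = h0.copy(), c0.copy()
    values = []
    for k in range(obs.shape[0]):
        if arch == "rnn":
            h = _cells.rnn_cell(params["W"], h, obs[k])
        elif arch == "lstm":
            h, c = _cells.lstm_cell(params["W"], h, c, obs[k])
        else:
            h = _cells.gru_cell(params["Wz"], params["Wr"], params["Wc"],
                                h, obs[k])
        values.append(float(params["w_out"] @ h + params["b_out"][0]))
    values = np.asarray(values)
    return 0.5 * np.sum((targets - values) ** 2), values


@pytest.mark.parametrize("arch", ["rnn", "lstm", "gru"])
def test_window_gradient_matches_finite_differences(arch):
    """T-BPTT window gradients of the summed semi-gradient TD(0) loss agree
    with central finite differences of the frozen-target loss."""
    m, n, T, gamma = 5, 6, 10, 0.9
    rng = np.random.default_rng(2)
    cfg = RecurrentConfig(architecture=arch, n_hidden=n, gamma=gamma,
                          truncation=T)
    agent = RecurrentAgent(m, cfg, rng=np.random.default_rng(3))
    agent.params["w_out"][:] = rng.normal(scale=0.3, size=n)
    agent.params["b_out"][0] = 0.1
    obs = rng.random((T, m))
    us_next = (rng.random(T) < 0.3).astype(float)
    v_boot = 0.4
    h0 = rng.normal(scale=0.2, size=n)
    c0 = rng.normal(scale=0.2, size=n)
    grads = agent.window_gradients(h0, c0, obs, us_next, v_boot)
    _, values = window_loss_frozen_targets(agent.params, arch, h0, c0, obs,
                                           np.zeros(T))
    targets = us_next + gamma * np.r_[values[1:], v_boot]
    eps = 1e-6
    for key, g in grads.items():
        num = np.zeros_like(agent.params[key])
        it = np.nditer(agent.params[key], flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = agent.params[key][idx]
            agent.params[key][idx] = orig + eps
            lp, _ = window_loss_frozen_targets(agent.params, arch, h0, c0,
                                               obs, targets)
            agent.params[key][idx] = orig - eps
            lm, _ = window_loss_frozen_targets(agent.params, arch, h0, c0,
                                               obs, targets)
            agent.params[key][idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        scale = max(1e-8, np.abs(num).max())
        assert np.abs(g - num).max() / scale < 1e-4


def collect_rtrl_gradient(arch, n=8, m=4, steps=50, gamma=0.9, seed=5):
    """Run frozen-parameter RTRL and accumulate sum_t(-delta_t dV_t/dtheta);
    return it with everything needed for the full-unroll oracle."""
    rng = np.random.default_rng(seed)
    cfg = RecurrentConfig(architecture=arch, n_hidden=n, trainer="rtrl",
                          gamma=gamma)
    agent = RecurrentAgent(m, cfg, rng=np.random.default_rng(seed + 1))
    agent.params["w_out"][:] = rng.normal(scale=0.3, size=n)
    agent.params["b_out"][0] = 0.05
    agent.update_enabled = False
    obs = rng.random((steps, m))
    us = (rng.random(steps) < 0.2).astype(float)
    values, grads_rec, grads_head = [], [], []
    for t in range(steps):
        v = agent.observe(obs[t], us[t])
        values.append(v)
        grads_rec.append(agent._prev[1].copy())
        grads_head.append(agent._prev[2].copy())
    values = np.asarray(values)
    deltas = np.empty(steps)
    for t in range(steps):
        v_next = values[t + 1] if t < steps - 1 else 0.0
        us_next = us[t + 1] if t < steps - 1 else 0.0
        deltas[t] = us_next + gamma * v_next - values[t]
    acc_rec = sum(-deltas[t] * grads_rec[t] for t in range(steps))
    acc_head = sum(-deltas[t] * grads_head[t] for t in range(steps))
    return agent.params, obs, us, values, acc_rec, acc_head, -deltas.sum()


@pytest.mark.parametrize("arch", ["rnn", "lstm", "gru"])
def test_rtrl_equals_full_unroll_backprop(arch):
    """With parameters frozen, the RTRL-accumulated gradient over a 50-step
    sequence equals backprop through the full unroll from the origin."""
    n, m, steps, gamma = 8, 4, 50, 0.9
    params, obs, us, values, acc_rec, acc_head, acc_b = \
        collect_rtrl_gradient(arch, n, m, steps, gamma)
    us_next = np.r_[us[1:], 0.0]
    h0 = np.zeros(n)
    c0 = np.zeros(n)
    if arch == "rnn":
        dW, dw, db, v2 = _cells.rnn_window_grads(
            params["W"], params["w_out"], params["b_out"][0], h0, obs,
            us_next, gamma, 0.0)
        flat = dW.ravel()
    elif arch == "lstm":
        dW, dw, db, v2 = _cells.lstm_window_grads(
            params["W"], params["w_out"], params["b_out"][0], h0, c0, obs,
            us_next, gamma, 0.0)
        flat = dW.ravel()
    else:
        dWz, dWr, dWc, dw, db, v2 = _cells.gru_window_grads(
            params["Wz"], params["Wr"], params["Wc"], params["w_out"],
            params["b_out"][0], h0, obs, us_next, gamma, 0.0)
        flat = np.concatenate([dWz.ravel(), dWr.ravel(), dWc.ravel()])
    assert np.abs(v2 - values).max() < 1e-12
    assert np.abs(acc_rec - flat).max() / np.abs(flat).max() < 1e-6
    assert np.abs(acc_head - dw).max() / max(1e-12, np.abs(dw).max()) < 1e-6
    assert abs(acc_b - db) < 1e-9


def test_rtrl_zero_recurrent_weights_gives_local_gradients():
    """With zero recurrent weight blocks the influence matrix carries no
    history: dV/dtheta reduces to the one-step local gradient."""
    m, n = 3, 4
    L = m + n + 1
    rng = np.random.default_rng(6)
    cfg = RecurrentConfig(architecture="rnn", n_hidden=n, trainer="rtrl")
    agent = RecurrentAgent(m, cfg, rng=np.random.default_rng(7))
    agent.params["W"][:, m:m + n] = 0.0  # no recurrence
    agent.params["w_out"][:] = rng.normal(size=n)
    agent.update_enabled = False
    for _ in range(5):
        o = rng.random(m)
        agent.observe(o, 0.0)
        # local gradient of h_j wrt its own row: (1 - h_j^2) * [o; h_prev; 1]
        J = agent._Jh
        for j in range(n):
            block = J[j].reshape(n, L)
            off_rows = np.delete(np.arange(n), j)
            assert np.abs(block[off_rows]).max() < 1e-12


class TestTBPTTProtocol:
    def test_no_update_before_buffer_fills(self):
        cfg = RecurrentConfig(architecture="lstm", n_hidden=4, truncation=6)
        agent = RecurrentAgent(3, cfg, rng=np.random.default_rng(0))
        w0 = agent.params["W"].copy()
        rng = np.random.default_rng(1)
        agent.params["w_out"][:] = 0.3
        for _ in range(6):  # buffer needs T+1 observations
            agent.observe(rng.random(3), 1.0)
        assert np.array_equal(agent.params["W"], w0)
        agent.observe(rng.random(3), 1.0)
        assert not np.array_equal(agent.params["W"], w0)

    def test_zero_us_zero_head_parameters_stay_fixed(self):
        cfg = RecurrentConfig(architecture="lstm", n_hidden=5, truncation=4)
        agent = RecurrentAgent(3, cfg, rng=np.random.default_rng(2))
        w0 = {k: v.copy() for k, v in agent.params.items()}
        rng = np.random.default_rng(3)
        for _ in range(50):
            agent.observe(rng.random(3), 0.0)  # delta == 0 throughout
        for k in w0:
            assert np.array_equal(agent.params[k], w0[k])

    def test_stride_spaces_out_updates(self):
        cfg = RecurrentConfig(architecture="rnn", n_hidden=4, truncation=2,
                              stride=3)
        agent = RecurrentAgent(3, cfg, rng=np.random.default_rng(8))
        agent.params["w_out"][:] = 0.5
        rng = np.random.default_rng(9)
        snapshots = []
        for _ in range(12):
            agent.observe(rng.random(3), 1.0)
            snapshots.append(agent.params["W"].copy())
        changes = [not np.array_equal(a, b)
                   for a, b in zip(snapshots, snapshots[1:])]
        assert sum(changes) < 11  # some steps skip the update entirely

    def test_t_equal_one_is_one_step_td0(self):
        """A T=1 window reduces to the one-step recurrent semi-gradient:
        -delta * dV_t/dtheta with the previous state held constant."""
        m, n = 3, 4
        cfg = RecurrentConfig(architecture="rnn", n_hidden=n, truncation=1,
                              gamma=0.8)
        agent = RecurrentAgent(m, cfg, rng=np.random.default_rng(4))
        rng = np.random.default_rng(5)
        agent.params["w_out"][:] = rng.normal(size=n)
        h_prev = rng.normal(scale=0.3, size=n)
        o = rng.random(m)
        us_next, v_boot = 1.0, 0.6
        grads = agent.window_gradients(h_prev, np.zeros(n), o[None, :],
                                       np.array([us_next]), v_boot)
        u = np.r_[o, h_prev, 1.0]
        h = np.tanh(agent.params["W"] @ u)
        v = float(agent.params["w_out"] @ h)
        delta = us_next + 0.8 * v_boot - v
        expected_dW = -delta * np.outer(
            agent.params["w_out"] * (1 - h ** 2), u)
        assert np.allclose(grads["W"], expected_dW)
        assert np.allclose(grads["w_out"], -delta * h)


class TestAugmentation:
    def test_disabled_is_identity(self):
        aug = TraceAugmenter(4, ())
        o = np.array([1.0, 0.0, 1.0, 0.0])
        assert np.array_equal(augment_with_traces(o, aug), o)

    def test_dimension_grows_per_tau(self):
        assert TraceAugmenter(4, (0.9,)).n_out == 8
        assert TraceAugmenter(4, (0.9, 0.95)).n_out == 12

    def test_traces_follow_onsets(self):
        aug = TraceAugmenter(2, (0.5,))
        x1 = aug.transform(np.array([1, 0], dtype=np.uint8))
        assert x1[2] == 1.0 and x1[3] == 0.0
        x2 = aug.transform(np.array([1, 0], dtype=np.uint8))
        assert x2[2] == pytest.approx(0.5)  # decays while stimulus stays on


class TestTruncationMonotonicity:
    def test_msre_non_increasing_in_window_length(self):
        """On short-ISI trace conditioning (expected ISI 10), mean MSRE over
        five seeds is non-increasing in the truncation length across
        T in {1, 5, 10, 20}, up to one standard error: windows shorter than
        the trace interval cannot credit the CS, and windows beyond it add
        nothing."""
        from tracebench.returns import ReturnSpec, aggregate_runs, \
            compute_returns, msre

        summaries = []
        for T in (1, 5, 10, 20):
            values = []
            for seed in range(5):
                env = make_env(TraceConditioningConfig(seed=seed))
                cfg = RecurrentConfig(architecture="lstm", n_hidden=8,
                                      trainer="tbptt", truncation=T,
                                      alpha=2.0 ** -9, gamma=env.gamma)
                log = run_recurrent_agent(env, cfg, 120_000,
                                          init_seed=seed + 1000)
                rs = compute_returns(log["us"], ReturnSpec(env.gamma))
                values.append(msre(log["prediction"], rs.values,
                                   rs.valid_mask))
            summaries.append(aggregate_runs(values))
        for prev, nxt in zip(summaries, summaries[1:]):
            assert nxt.msre <= prev.msre + prev.stderr + nxt.stderr
        # and the trend is substantive: a window spanning the trace interval
        # clearly improves on the one-step window
        assert summaries[2].msre + summaries[2].stderr < summaries[0].msre


class TestDeterminism:
    @pytest.mark.parametrize("trainer", ["tbptt", "rtrl"])
    def test_same_seeds_identical_logs(self, trainer):
        def one():
            env = make_env(TraceConditioningConfig(seed=9))
            cfg = RecurrentConfig(architecture="gru", n_hidden=6,
                                  trainer=trainer, truncation=3,
                                  gamma=env.gamma)
            return run_recurrent_agent(env, cfg, 2_000, init_seed=13)

        a, b = one(), one()
        assert np.array_equal(a["prediction"], b["prediction"])
        assert np.array_equal(a["us"], b["us"])

    @pytest.mark.parametrize("trainer", ["tbptt", "rtrl"])
    def test_augmented_inputs_train_cleanly(self, trainer):
        env = make_env(TraceConditioningConfig(seed=10))
        cfg = RecurrentConfig(architecture="lstm", n_hidden=6,
                              trainer=trainer, truncation=2, gamma=env.gamma,
                              augment=True, augment_taus=(0.9,))
        log = run_recurrent_agent(env, cfg, 2_000, init_seed=14)
        assert np.all(np.isfinite(log["prediction"]))
        assert log["prediction"].std() > 0  # learning is actually happening
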