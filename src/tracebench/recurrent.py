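"""Recurrent state-construction learners: vanilla RNN, LSTM, and GRU with a
linear value head, trained online on semi-gradient TD(0) targets by either
truncated backprop through time (T-BPTT) or real-time recurrent learning
(RTRL), with optional stimulating-trace input augmentation.

Protocol notes:

* The behavior hidden state is computed incrementally with the current
  parameters on every step; window recomputation in T-BPTT is for gradients
  only and never replaces the online state.
* T-BPTT unrolls from the boundary state x_{t-T-1} captured when it left the
  window, stored stale (computed under old parameters) and never recomputed.
  Updates fire every ``stride`` steps (default 1 = every step) once the
  buffer has filled; the per-step window losses are summed and the newest
  bootstrap uses the online V_t.
* RTRL carries a single influence matrix forward across parameter updates
  (the stale-Jacobian protocol) and updates the parameters on every step.
* Eligibility-trace decay is lambda = 0 for all recurrent learners (plain
  TD(0) targets).

Initialization: all cell weights uniform(-1/sqrt(n_hidden), 1/sqrt(n_hidden)),
LSTM forget-gate bias 1.0, value head zero.  Gradient clipping is off by
default and available as a config option.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from . import _cells
from .representations import StimulatingTraces

__all__ = [
    "RecurrentConfig",
    "init_params",
    "RecurrentAgent",
    "TraceAugmenter",
    "augment_with_traces",
    "run_recurrent_agent",
]

ARCHITECTURES = ("rnn", "lstm", "gru")
TRAINERS = ("tbptt", "rtrl")


@dataclass
class RecurrentConfig:
    architecture: str = "lstm"
    n_hidden: int = 16
    trainer: str = "tbptt"
    truncation: int = 10          # T-BPTT window length T
    stride: int = 1               # update every `stride` steps
    alpha: float = 2.0 ** -8
    gamma: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    optimizer: str = "adam"       # "adam" | "sgd"
    augment: bool = False
    augment_taus: tuple[float, ...] = ()
    grad_clip: float | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.trainer not in TRAINERS:
            raise ValueError(f"trainer must be one of {TRAINERS}")
        if self.truncation < 1:
            raise ValueError("truncation must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")


def init_params(architecture: str, n_in: int, n_hidden: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded small-uniform weight init; LSTM forget bias 1; zero head."""
    L = n_in + n_hidden + 1
    bound = 1.0 / np.sqrt(n_hidden)

    def mat(rows: int) -> np.ndarray:
        return rng.uniform(-bound, bound, size=(rows, L))

    if architecture == "rnn":
        params = {"W": mat(n_hidden)}
    elif architecture == "lstm":
        W = mat(4 * n_hidden)
        W[n_hidden:2 * n_hidden, -1] = 1.0  # forget-gate bias
        params = {"W": W}
    elif architecture == "gru":
        params = {"Wz": mat(n_hidden), "Wr": mat(n_hidden), "Wc": mat(n_hidden)}
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    params["w_out"] = np.zeros(n_hidden)
    params["b_out"] = np.zeros(1)
    return params


class _Optimizer:
    """Adam (bias-corrected, shared step counter) or plain SGD over a
    dict of parameter arrays, with optional global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], alpha: float,
                 beta1: float, beta2: float, eps: float,
                 kind: str = "adam", clip: float | None = None) -> None:
        self.alpha = alpha
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.kind = kind
        self.clip = clip
        self.t = 0
        self.m1 = {k: np.zeros_like(v) for k, v in params.items()}
        self.m2 = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        if self.clip is not None:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if norm > self.clip:
                scale = self.clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        if self.kind == "sgd":
            for k, g in grads.items():
                params[k] -= self.alpha * g
            return
        self.t += 1
        c1 = 1.0 - self.beta1 ** self.t
        c2 = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m1 = self.m1[k]
            m2 = self.m2[k]
            m1 *= self.beta1
            m1 += (1.0 - self.beta1) * g
            m2 *= self.beta2
            m2 += (1.0 - self.beta2) * g * g
            params[k] -= self.alpha * (m1 / c1) / (np.sqrt(m2 / c2) + self.eps)


class TraceAugmenter:
    """Appends stimulating traces of every observation channel to the input.

    One trace bank per decay value; the augmented input is
    [o_t ; y_t(tau_1) ; ... ; y_t(tau_K)], so the input dimension grows by d
    per tau.  Disabled, it is the identity on o_t.
    """

    def __init__(self, d: int, taus: tuple[float, ...] = ()) -> None:
        self.d = d
        self.taus = tuple(taus)
        self.banks = [StimulatingTraces(d, tau) for tau in self.taus]

    @property
    def n_out(self) -> int:
        return self.d * (1 + len(self.banks))

    def reset(self) -> None:
        for bank in self.banks:
            bank.reset()

    def transform(self, obs: np.ndarray) -> np.ndarray:
        if not self.banks:
            return np.asarray(obs, dtype=np.float64)
        parts = [np.asarray(obs, dtype=np.float64)]
        for bank in self.banks:
            parts.append(bank.update(obs).copy())
        return np.concatenate(parts)


def augment_with_traces(obs: np.ndarray, augmenter: TraceAugmenter) -> np.ndarray:
    """Functional wrapper over :class:`TraceAugmenter`."""
    return augmenter.transform(obs)


class RecurrentAgent:
    """Online recurrent value learner; call :meth:`observe` once per step."""

    def __init__(self, n_obs: int, config: RecurrentConfig,
                 rng: np.random.Generator | int = 0) -> None:
        rng = (rng if isinstance(rng, np.random.Generator)
               else np.random.default_rng(rng))
        self.config = config
        taus = config.augment_taus if config.augment else ()
        self.augmenter = TraceAugmenter(n_obs, taus)
        self.n_in = self.augmenter.n_out
        self.n_hidden = config.n_hidden
        self.params = init_params(config.architecture, self.n_in,
                                  config.n_hidden, rng)
        self.opt = _Optimizer(self.params, config.alpha, config.beta1,
                              config.beta2, config.eps, config.optimizer,
                              config.grad_clip)
        self.update_enabled = True
        self.reset_state()

    # -- state management ---------------------------------------------------

    def reset_state(self) -> None:
        cfg = self.config
        n = self.n_hidden
        self.h = np.zeros(n)
        self.c = np.zeros(n)  # LSTM only
        self.steps = 0
        self.augmenter.reset()
        if cfg.trainer == "tbptt":
            T = cfg.truncation
            self._obs_buf: deque = deque(maxlen=T + 1)
            self._us_buf: deque = deque(maxlen=T + 1)
            self._state_buf: deque = deque(maxlen=T + 2)
            self._state_buf.append((self.h.copy(), self.c.copy()))
        else:
            L = self.n_in + n + 1
            if cfg.architecture == "rnn":
                self._Jh = np.zeros((n, n * L))
            elif cfg.architecture == "lstm":
                self._Jh = np.zeros((n, 4 * n * L))
                self._Jc = np.zeros((n, 4 * n * L))
            else:
                self._Jh = np.zeros((n, 3 * n * L))
            self._prev: tuple | None = None

    # -- forward helpers ----------------------------------------------------

    def _cell_forward(self, x: np.ndarray) -> None:
        p = self.params
        arch = self.config.architecture
        if arch == "rnn":
            self.h = _cells.rnn_cell(p["W"], self.h, x)
        elif arch == "lstm":
            self.h, self.c = _cells.lstm_cell(p["W"], self.h, self.c, x)
        else:
            self.h = _cells.gru_cell(p["Wz"], p["Wr"], p["Wc"], self.h, x)

    def value(self) -> float:
        return float(self.params["w_out"] @ self.h + self.params["b_out"][0])

    # -- online step --------------------------------------------------------

    def observe(self, obs: np.ndarray, us: float) -> float:
        """Advance one step on observation ``obs`` (whose US component is
        ``us``) and return the online prediction V_t."""
        x = self.augmenter.transform(obs)
        if self.config.trainer == "tbptt":
            v = self._observe_tbptt(x, us)
        else:
            v = self._observe_rtrl(x, us)
        if not np.isfinite(v):
            raise FloatingPointError(
                f"non-finite value prediction at step {self.steps}")
        self.steps += 1
        return v

    def _observe_tbptt(self, x: np.ndarray, us: float) -> float:
        cfg = self.config
        self._cell_forward(x)
        v = self.value()
        self._obs_buf.append(x)
        self._us_buf.append(us)
        self._state_buf.append((self.h.copy(), self.c.copy()))
        T = cfg.truncation
        if (self.update_enabled and len(self._obs_buf) == T + 1
                and self.steps % cfg.stride == 0):
            h0, c0 = self._state_buf[0]
            obs_win = np.stack(list(self._obs_buf)[:T])
            us_next = np.asarray(list(self._us_buf)[1:], dtype=np.float64)
            self.opt.step(self.params,
                          self.window_gradients(h0, c0, obs_win, us_next, v))
        return v

    def window_gradients(self, h0, c0, obs_win, us_next,
                         v_boot) -> dict[str, np.ndarray]:
        """Summed semi-gradient TD(0) window gradients (see module docs)."""
        p = self.params
        gamma = self.config.gamma
        arch = self.config.architecture
        if arch == "rnn":
            dW, dw, db, _ = _cells.rnn_window_grads(
                p["W"], p["w_out"], p["b_out"][0], h0, obs_win, us_next,
                gamma, v_boot)
            return {"W": dW, "w_out": dw, "b_out": np.array([db])}
        if arch == "lstm":
            dW, dw, db, _ = _cells.lstm_window_grads(
                p["W"], p["w_out"], p["b_out"][0], h0, c0, obs_win, us_next,
                gamma, v_boot)
            return {"W": dW, "w_out": dw, "b_out": np.array([db])}
        dWz, dWr, dWc, dw, db, _ = _cells.gru_window_grads(
            p["Wz"], p["Wr"], p["Wc"], p["w_out"], p["b_out"][0], h0,
            obs_win, us_next, gamma, v_boot)
        return {"Wz": dWz, "Wr": dWr, "Wc": dWc,
                "w_out": dw, "b_out": np.array([db])}

    def _observe_rtrl(self, x: np.ndarray, us: float) -> float:
        cfg = self.config
        p = self.params
        n = self.n_hidden
        L = self.n_in + n + 1
        arch = cfg.architecture
        # Forward + influence propagation at the current (pre-update) params;
        # the kernels update the influence matrices in place.
        if arch == "rnn":
            self.h = _cells.rnn_rtrl_step(p["W"], self.h, self._Jh, x)
        elif arch == "lstm":
            self.h, self.c = _cells.lstm_rtrl_step(
                p["W"], self.h, self.c, self._Jh, self._Jc, x)
        else:
            self.h = _cells.gru_rtrl_step(
                p["Wz"], p["Wr"], p["Wc"], self.h, self._Jh, x)
        v = self.value()
        gv_rec = p["w_out"] @ self._Jh       # dV_t/dtheta_rec via J
        gv_h = self.h.copy()                  # dV_t/dw_out
        if self._prev is not None and self.update_enabled:
            prev_v, prev_gv_rec, prev_gv_h = self._prev
            delta = us + cfg.gamma * v - prev_v
            g_rec = -delta * prev_gv_rec
            grads: dict[str, np.ndarray] = {
                "w_out": -delta * prev_gv_h,
                "b_out": np.array([-delta]),
            }
            if arch == "gru":
                nL = n * L
                grads["Wz"] = g_rec[:nL].reshape(n, L)
                grads["Wr"] = g_rec[nL:2 * nL].reshape(n, L)
                grads["Wc"] = g_rec[2 * nL:].reshape(n, L)
            else:
                rows = 4 * n if arch == "lstm" else n
                grads["W"] = g_rec.reshape(rows, L)
            self.opt.step(self.params, grads)
        self._prev = (v, gv_rec, gv_h)
        return v

    def value_gradient(self) -> np.ndarray:
        """Current dV_t/dtheta_rec from the influence matrix (RTRL only)."""
        return self.params["w_out"] @ self._Jh


def run_recurrent_agent(env, config: RecurrentConfig, n_steps: int,
                        init_seed: int | np.random.Generator = 0
                        ) -> dict[str, np.ndarray]:
    """Online loop with the shared per-step log schema."""
    agent = RecurrentAgent(env.layout.d, config, init_seed)
    us_idx = env.layout.us_index
    prediction = np.zeros(n_steps)
    us = np.zeros(n_steps)
    phase = np.zeros(n_steps, dtype=np.int8)
    trial_id = np.zeros(n_steps, dtype=np.int64)
    pattern_active = np.zeros(n_steps, dtype=bool)
    for t in range(n_steps):
        ob = env.step()
        us_t = float(ob.values[us_idx])
        prediction[t] = agent.observe(ob.values.astype(np.float64), us_t)
        us[t] = us_t
        phase[t] = ob.annotation.phase
        trial_id[t] = ob.annotation.trial_id
        pattern_active[t] = ob.annotation.pattern_active
    return {
        "prediction": prediction,
        "us": us,
        "phase": phase,
        "trial_id": trial_id,
        "pattern_active": pattern_active,
    }
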