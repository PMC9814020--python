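"""Semi-gradient TD(lambda) with eligibility traces over fixed representations.

The value estimate is linear, V_t = w^T x_t.  On each step the learner forms
the TD error

    delta_t = US_{t+1} + gamma * V_{t+1} - V_t

with V_{t+1} evaluated under the pre-update weights (fully online
semi-gradient convention), accumulates the eligibility trace
z <- gamma * lambda * z + x_t, and applies either

* ``sgd``:   w <- w + alpha * delta * z  (the classic rule), or
* ``adam``:  the surrogate gradient -delta * z fed to a bias-corrected
  adaptive-moment update with shared step counter (the default; how the
  moment estimates interact with eligibility traces is this package's
  design choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TDHyper", "LinearTD", "run_linear_agent"]


@dataclass
class TDHyper:
    alpha: float = 2.0 ** -8
    lam: float = 0.9
    gamma: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    optimizer: str = "adam"  # "adam" | "sgd"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class LinearTD:
    """Online linear TD(lambda) learner state: weights, eligibility, moments."""

    def __init__(self, n_features: int, hyper: TDHyper) -> None:
        self.hyper = hyper
        self.n_features = n_features
        self.w = np.zeros(n_features)
        self.z = np.zeros(n_features)
        self.m1 = np.zeros(n_features)
        self.m2 = np.zeros(n_features)
        self.t = 0

    def predict(self, x: np.ndarray) -> float:
        if x.shape != (self.n_features,):
            raise ValueError(
                f"feature dimension {x.shape} does not match weights "
                f"({self.n_features},)")
        return float(self.w @ x)

    def update(self, x_t: np.ndarray, x_next: np.ndarray,
               us_next: float) -> float:
        """One TD(lambda) update from consecutive feature vectors.

        Both value estimates use the current (pre-update) weights.  Returns
        the TD error delta.
        """
        h = self.hyper
        v_t = self.predict(x_t)
        v_next = self.predict(x_next)
        delta = us_next + h.gamma * v_next - v_t
        if not np.isfinite(delta):
            raise FloatingPointError(
                f"non-finite TD error at update {self.t}: delta={delta}, "
                f"V_t={v_t}, V_t+1={v_next}")
        self.z = h.gamma * h.lam * self.z + x_t
        if h.optimizer == "sgd":
            self.w = self.w + h.alpha * delta * self.z
        else:
            g = -delta * self.z
            self.t += 1
            self.m1 = h.beta1 * self.m1 + (1.0 - h.beta1) * g
            self.m2 = h.beta2 * self.m2 + (1.0 - h.beta2) * g * g
            m1_hat = self.m1 / (1.0 - h.beta1 ** self.t)
            m2_hat = self.m2 / (1.0 - h.beta2 ** self.t)
            self.w = self.w - h.alpha * m1_hat / (np.sqrt(m2_hat) + h.eps)
        return float(delta)


def run_linear_agent(env, representation, hyper: TDHyper,
                     n_steps: int) -> dict[str, np.ndarray]:
    """Online loop: observe, featurize, predict, log, update.

    Logged predictions are the online values under the pre-update weights.
    The representation's previous-prediction input (used by the echo state
    network's feedback weights) is the prediction from the preceding step.
    """
    agent = LinearTD(representation.n_features, hyper)
    us_idx = env.layout.us_index
    prediction = np.zeros(n_steps)
    us = np.zeros(n_steps)
    phase = np.zeros(n_steps, dtype=np.int8)
    trial_id = np.zeros(n_steps, dtype=np.int64)
    pattern_active = np.zeros(n_steps, dtype=bool)
    representation.reset()
    prev_x = None
    prev_v = 0.0
    for t in range(n_steps):
        ob = env.step()
        x = representation.step(ob.values, prev_v)
        v = agent.predict(x)
        us_t = float(ob.values[us_idx])
        prediction[t] = v
        us[t] = us_t
        phase[t] = ob.annotation.phase
        trial_id[t] = ob.annotation.trial_id
        pattern_active[t] = ob.annotation.pattern_active
        if prev_x is not None:
            agent.update(prev_x, x, us_t)
        prev_x = x
        prev_v = v
    return {
        "prediction": prediction,
        "us": us,
        "phase": phase,
        "trial_id": trial_id,
        "pattern_active": pattern_active,
        "weights": agent.w,
    }
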