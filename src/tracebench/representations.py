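"""Fixed (non-learned) state constructors mapping observations to features.

Five baselines, all emitting a dense feature vector with a trailing bias:

* presence -- the observation bits themselves;
* stimulating traces -- per-channel exponential memories y reset to 1 at a
  stimulus onset and decaying as y <- tau * y on every other step (decay
  continues even while the stimulus stays on);
* tile-coded traces -- each trace discretized by several offset tilings, one
  active tile per tiling;
* microstimulus -- trace-height-modulated Gaussian basis functions over each
  trace, unfolding sequentially through a trial;
* echo state network -- a random fixed recurrent reservoir with input,
  internal, and prediction-feedback weights, of which only the linear readout
  is ever trained.

Every channel (CS, US, and distractors alike) is traced and featurized the
same way; nothing marks a channel as special to the representation.  The
feature index layout is channel-major with the bias last.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "trace_decay_from_expected_isi",
    "PresenceRepresentation",
    "StimulatingTraces",
    "TileCodedTraces",
    "MicrostimulusRepresentation",
    "EchoStateNetwork",
    "make_representation",
]


def trace_decay_from_expected_isi(expected_isi: float,
                                  mode: str = "complement") -> float:
    """Default trace decay tied to the ISI.

    ``complement`` reads the decay amount per step as 1/E(ISI), giving
    tau = 1 - 1/E(ISI) (the default); ``time-constant`` instead treats
    E(ISI) as an exponential time constant, tau = exp(-1/E(ISI)).
    """
    if expected_isi < 1:
        raise ValueError(f"expected_isi must be >= 1, got {expected_isi}")
    if mode == "complement":
        return 1.0 - 1.0 / expected_isi
    if mode == "time-constant":
        return math.exp(-1.0 / expected_isi)
    raise ValueError(f"unknown mode {mode!r}")


class Representation:
    """Streaming interface: reset(), then step(obs[, prev_prediction]) -> x."""

    n_features: int

    def reset(self) -> None:  # stateless by default
        pass

    def step(self, obs: np.ndarray, prev_prediction: float = 0.0) -> np.ndarray:
        raise NotImplementedError


class PresenceRepresentation(Representation):
    """One binary feature per stimulus plus a constant bias of 1."""

    def __init__(self, d: int) -> None:
        self.d = d
        self.n_features = d + 1

    def step(self, obs: np.ndarray, prev_prediction: float = 0.0) -> np.ndarray:
        x = np.empty(self.n_features)
        x[:-1] = obs
        x[-1] = 1.0
        return x


class StimulatingTraces:
    """Per-channel stimulating traces y in [0, 1].

    Onset detection is edge-triggered against the previous observation; a
    rising edge resets the channel's trace to exactly 1 and the trace decays
    multiplicatively afterwards, including while the stimulus remains on.
    """

    def __init__(self, d: int, tau: float) -> None:
        if not 0.0 < tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {tau}")
        self.d = d
        self.tau = tau
        self.reset()

    def reset(self) -> None:
        self.y = np.zeros(self.d)
        self._prev_obs = np.zeros(self.d, dtype=np.uint8)

    def update(self, obs: np.ndarray) -> np.ndarray:
        obs = np.asarray(obs, dtype=np.uint8)
        onset = (obs == 1) & (self._prev_obs == 0)
        self.y *= self.tau
        self.y[onset] = 1.0
        self._prev_obs = obs.copy()
        return self.y


class TileCodedTraces(Representation):
    """Tile coding of each channel's stimulating trace.

    Per channel and per tiling exactly one binary feature is active: tile
    floor((y + offset) * n_tiles), clamped to the last tile.  Tiling offsets
    are deterministic and evenly spaced, offset_j = j / (n_tilings * n_tiles).
    """

    def __init__(self, d: int, tau: float, n_tilings: int = 2,
                 n_tiles: int = 8) -> None:
        if n_tilings < 1 or n_tiles < 1:
            raise ValueError("n_tilings and n_tiles must be >= 1")
        self.d = d
        self.n_tilings = n_tilings
        self.n_tiles = n_tiles
        self.offsets = np.arange(n_tilings) / (n_tilings * n_tiles)
        self.traces = StimulatingTraces(d, tau)
        self.n_features = d * n_tilings * n_tiles + 1

    def reset(self) -> None:
        self.traces.reset()

    def active_tiles(self, y: np.ndarray) -> np.ndarray:
        """Tile index per (channel, tiling) for trace values ``y``."""
        idx = np.floor((y[:, None] + self.offsets[None, :]) * self.n_tiles)
        return np.clip(idx, 0, self.n_tiles - 1).astype(np.int64)

    def encode(self, y: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n_features)
        tiles = self.active_tiles(y)
        base = (np.arange(self.d)[:, None] * self.n_tilings
                + np.arange(self.n_tilings)[None, :]) * self.n_tiles
        x[(base + tiles).ravel()] = 1.0
        x[-1] = 1.0
        return x

    def step(self, obs: np.ndarray, prev_prediction: float = 0.0) -> np.ndarray:
        return self.encode(self.traces.update(obs))


class MicrostimulusRepresentation(Representation):
    """Gaussian microstimuli over each channel's stimulating trace.

    Feature i of a channel with trace height y is
    y * exp(-(y - c_i)^2 / (2 sigma_trace^2)) with centers c_i equally spaced
    in (0, 1].  ``sigma`` is expressed in units of the inter-center spacing
    (sigma_trace = sigma / n_rbfs), the convention of the microstimulus
    literature; with the default 0.8 the basis functions overlap their
    neighbours but still peak one after another as the trace decays, so the
    features unfold sequentially over the trial.
    """

    def __init__(self, d: int, tau: float, n_rbfs: int = 8,
                 sigma: float = 0.8) -> None:
        if n_rbfs < 1:
            raise ValueError("n_rbfs must be >= 1")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.d = d
        self.n_rbfs = n_rbfs
        self.sigma = sigma
        self.sigma_trace = sigma / n_rbfs
        self.centers = np.arange(1, n_rbfs + 1) / n_rbfs
        self.traces = StimulatingTraces(d, tau)
        self.n_features = d * n_rbfs + 1

    def reset(self) -> None:
        self.traces.reset()

    def encode(self, y: np.ndarray) -> np.ndarray:
        feats = y[:, None] * np.exp(
            -((y[:, None] - self.centers[None, :]) ** 2)
            / (2.0 * self.sigma_trace ** 2))
        x = np.empty(self.n_features)
        x[:-1] = feats.ravel()
        x[-1] = 1.0
        return x

    def step(self, obs: np.ndarray, prev_prediction: float = 0.0) -> np.ndarray:
        return self.encode(self.traces.update(obs))


class EchoStateNetwork(Representation):
    """Fixed random reservoir with prediction feedback; readout trained only.

    Input and feedback weights are symmetric two-point (+/- input_scaling);
    internal weights are sparse with the requested density and rescaled so
    their spectral radius equals ``spectral_radius`` (< 1, the echo-state
    condition).  The hidden update is
    h <- tanh(W_in o + W h + W_fb V_prev), where V_prev is the previous
    step's prediction, keeping the construction causal.
    """

    def __init__(self, d: int, n_hidden: int = 100, input_scaling: float = 0.5,
                 spectral_radius: float = 0.9, density: float = 0.1,
                 seed: int | np.random.Generator = 0) -> None:
        if not 0.0 < spectral_radius < 1.0:
            raise ValueError("spectral_radius must be in (0, 1)")
        if not 0.0 < density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        self.d = d
        self.n_hidden = n_hidden
        self.n_features = n_hidden + 1
        self.W_in = rng.choice([-1.0, 1.0], size=(n_hidden, d)) * input_scaling
        self.W_fb = rng.choice([-1.0, 1.0], size=n_hidden) * input_scaling
        W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_hidden))
        W[rng.random((n_hidden, n_hidden)) >= density] = 0.0
        radius = float(np.max(np.abs(np.linalg.eigvals(W))))
        if not np.isfinite(radius) or radius <= 0:
            raise RuntimeError(
                "internal weight matrix has no usable spectral radius; "
                "increase density or n_hidden")
        self.W = W * (spectral_radius / radius)
        self.spectral_radius = spectral_radius
        self.reset()

    def reset(self) -> None:
        self.h = np.zeros(self.n_hidden)

    def step(self, obs: np.ndarray, prev_prediction: float = 0.0) -> np.ndarray:
        self.h = np.tanh(self.W_in @ np.asarray(obs, dtype=np.float64)
                         + self.W @ self.h + self.W_fb * prev_prediction)
        x = np.empty(self.n_features)
        x[:-1] = self.h
        x[-1] = 1.0
        return x


def make_representation(kind: str, d: int, tau: float | None = None,
                        seed: int = 0, **kwargs) -> Representation:
    """Factory used by the runner; ``tau`` is required for trace-based kinds."""
    if kind == "presence":
        return PresenceRepresentation(d)
    if kind in ("tile_coded_traces", "microstimulus") and tau is None:
        raise ValueError(f"{kind} requires a trace decay tau")
    if kind == "tile_coded_traces":
        return TileCodedTraces(d, tau, **kwargs)
    if kind == "microstimulus":
        return MicrostimulusRepresentation(d, tau, **kwargs)
    if kind == "esn":
        return EchoStateNetwork(d, seed=seed, **kwargs)
    raise ValueError(f"unknown representation kind {kind!r}")
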