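"""Seeded discrete-time generators for the three conditioning benchmarks.

Each environment emits one binary observation vector per step.  A trial is a
conditioned stimulus (CS) presentation followed, after the inter-stimulus
interval (ISI), by the unconditioned stimulus (US).  The time from US onset to
the next trial's CS onset is the inter-trial interval (ITI).  Channels are laid
out CS block, then US, then distractor block.

Three variants:

* :class:`TraceConditioningEnv` -- one CS, stochastic integer-uniform ISI, a
  stimulus-free trace interval between CS offset and US onset, and
  free-running Poisson distractor channels.
* :class:`NoisyPatterningEnv` -- several CSs shown simultaneously as a binary
  configuration; the US fires (after a fixed ISI) only when the configuration
  matches one of k activation patterns, with a per-trial outcome noise flip
  and trial-locked Bernoulli distractors.
* :class:`TracePatterningEnv` -- the combination: activation-pattern logic
  with a stochastic ISI and free-running distractors.

Learners see only the binary vector; trial annotations (trial id, pattern
membership, noise flip, phase) travel on an evaluation-only side channel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "ChannelLayout",
    "TraceConditioningConfig",
    "NoisyPatterningConfig",
    "TracePatterningConfig",
    "Observation",
    "TraceConditioningEnv",
    "NoisyPatterningEnv",
    "TracePatterningEnv",
    "make_env",
    "sample_isi",
    "sample_iti",
    "distractor_step",
    "generate_activation_patterns",
    "sample_trial",
    "PHASE_CS",
    "PHASE_TRACE",
    "PHASE_US",
    "PHASE_ITI",
]

# Trial phases (annotation side channel only).
PHASE_CS = 0
PHASE_TRACE = 1
PHASE_US = 2
PHASE_ITI = 3

PHASE_NAMES = {PHASE_CS: "CS-on", PHASE_TRACE: "trace-gap",
               PHASE_US: "US-on", PHASE_ITI: "ITI"}


class ConfigError(ValueError):
    """Raised when an environment configuration violates an invariant."""


@dataclass(frozen=True)
class ChannelLayout:
    """Observation channel layout: CS block, US channel, distractor block."""

    n_cs: int
    n_distractors: int

    @property
    def d(self) -> int:
        return self.n_cs + 1 + self.n_distractors

    @property
    def cs_slice(self) -> slice:
        return slice(0, self.n_cs)

    @property
    def us_index(self) -> int:
        return self.n_cs

    @property
    def distractor_slice(self) -> slice:
        return slice(self.n_cs + 1, self.d)


def _check_range(name: str, rng: tuple[int, int]) -> None:
    lo, hi = rng
    if int(lo) != lo or int(hi) != hi:
        raise ConfigError(f"{name}: endpoints must be integers, got {rng}")
    if lo > hi:
        raise ConfigError(f"{name}: lower endpoint {lo} exceeds upper {hi}")
    if lo < 1:
        raise ConfigError(f"{name}: endpoints must be >= 1, got {rng}")


@dataclass
class TraceConditioningConfig:
    """One CS channel, stochastic ISI, free-running Poisson distractors.

    ISI and ITI ranges are inclusive integer intervals read as discrete
    uniform distributions, so e.g. (7, 13) has expectation exactly 10.
    """

    isi_range: tuple[int, int] = (7, 13)
    iti_range: tuple[int, int] = (80, 120)
    cs_duration: int = 4
    us_duration: int = 2
    distractor_mean_intervals: tuple[float, ...] = (
        10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    distractor_duration: int = 4
    seed: int = 0

    n_cs: int = field(default=1, init=False, repr=False)

    def validate(self) -> None:
        _check_range("isi_range", self.isi_range)
        _check_range("iti_range", self.iti_range)
        if self.cs_duration < 1:
            raise ConfigError(f"cs_duration: must be >= 1, got {self.cs_duration}")
        if self.us_duration < 1:
            raise ConfigError(f"us_duration: must be >= 1, got {self.us_duration}")
        if self.distractor_duration < 1:
            raise ConfigError(
                f"distractor_duration: must be >= 1, got {self.distractor_duration}")
        for mi in self.distractor_mean_intervals:
            if mi <= 0:
                raise ConfigError(
                    f"distractor_mean_intervals: must be positive, got {mi}")
            if mi < self.distractor_duration:
                warnings.warn(
                    f"distractor mean interval {mi} is shorter than the "
                    f"distractor duration {self.distractor_duration}; the "
                    "channel will be active most of the time", stacklevel=2)

    @property
    def expected_isi(self) -> float:
        return 0.5 * (self.isi_range[0] + self.isi_range[1])


@dataclass
class NoisyPatterningConfig:
    """Configuration patterning: k activation patterns over n_cs cues.

    The ISI is a fixed integer; the CSs and the trial-locked distractors are
    presented simultaneously for ``cs_duration`` steps at trial start.
    ``noise_pct`` is the percentage of trials whose US outcome is flipped
    relative to pattern membership (in either direction).
    """

    n_cs: int = 8
    k_patterns: int = 8
    n_distractors: int = 10
    noise_pct: float = 10.0
    isi: int = 4
    iti_range: tuple[int, int] = (80, 120)
    cs_duration: int = 4
    us_duration: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cs < 2 or self.n_cs % 2 != 0:
            raise ConfigError(f"n_cs: must be an even integer >= 2, got {self.n_cs}")
        max_k = math.comb(self.n_cs, self.n_cs // 2)
        if not 1 <= self.k_patterns <= max_k:
            raise ConfigError(
                f"k_patterns: must be in [1, C({self.n_cs}, {self.n_cs // 2})"
                f" = {max_k}], got {self.k_patterns}")
        if self.n_distractors < 0:
            raise ConfigError(f"n_distractors: must be >= 0, got {self.n_distractors}")
        if not 0.0 <= self.noise_pct <= 100.0:
            raise ConfigError(f"noise_pct: must be in [0, 100], got {self.noise_pct}")
        if self.isi < 1:
            raise ConfigError(f"isi: must be >= 1, got {self.isi}")
        _check_range("iti_range", self.iti_range)
        if self.cs_duration < 1:
            raise ConfigError(f"cs_duration: must be >= 1, got {self.cs_duration}")
        if self.us_duration < 1:
            raise ConfigError(f"us_duration: must be >= 1, got {self.us_duration}")

    @property
    def expected_isi(self) -> float:
        return float(self.isi)


@dataclass
class TracePatterningConfig:
    """Patterning logic combined with trace-conditioning timing."""

    n_cs: int = 8
    k_patterns: int = 8
    n_distractors: int = 10
    noise_pct: float = 10.0
    isi_range: tuple[int, int] = (7, 13)
    iti_range: tuple[int, int] = (80, 120)
    cs_duration: int = 4
    us_duration: int = 2
    distractor_mean_intervals: tuple[float, ...] | None = None
    distractor_duration: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distractor_mean_intervals is None:
            self.distractor_mean_intervals = tuple(
                10.0 * (i + 1) for i in range(self.n_distractors))

    def validate(self) -> None:
        NoisyPatterningConfig(
            n_cs=self.n_cs, k_patterns=self.k_patterns,
            n_distractors=self.n_distractors, noise_pct=self.noise_pct,
            isi=self.isi_range[0], iti_range=self.iti_range,
            cs_duration=self.cs_duration, us_duration=self.us_duration,
        ).validate()
        _check_range("isi_range", self.isi_range)
        if len(self.distractor_mean_intervals) != self.n_distractors:
            raise ConfigError(
                "distractor_mean_intervals: expected one mean interval per "
                f"distractor ({self.n_distractors}), got "
                f"{len(self.distractor_mean_intervals)}")

    @property
    def expected_isi(self) -> float:
        return 0.5 * (self.isi_range[0] + self.isi_range[1])


# Named noisy-patterning difficulty presets.  The defaults above follow the
# fully specified configuration (8 CSs, 8 activation patterns, 10 distractors,
# 10% noise); the easy and hard presets below are this package's own choices.
NOISY_PATTERNING_PRESETS: dict[str, dict] = {
    "easy": dict(n_cs=6, k_patterns=4, n_distractors=5, noise_pct=5.0),
    "medium": dict(n_cs=8, k_patterns=8, n_distractors=10, noise_pct=10.0),
    "hard": dict(n_cs=10, k_patterns=16, n_distractors=20, noise_pct=15.0),
}


@dataclass
class TrialAnnotation:
    """Evaluation-only side channel; never visible to learners."""

    trial_id: int
    pattern_active: bool
    noise_flipped: bool
    phase: int


@dataclass
class Observation:
    values: np.ndarray  # binary vector of length layout.d
    annotation: TrialAnnotation


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def sample_isi(rng: np.random.Generator, isi_range: tuple[int, int]) -> int:
    """Integer uniform on the inclusive interval ``isi_range``."""
    _check_range("isi_range", isi_range)
    return int(rng.integers(isi_range[0], isi_range[1] + 1))


def sample_iti(rng: np.random.Generator, iti_range: tuple[int, int]) -> int:
    """Integer uniform on the inclusive interval ``iti_range``."""
    _check_range("iti_range", iti_range)
    return int(rng.integers(iti_range[0], iti_range[1] + 1))


def distractor_step(
    timers: np.ndarray,
    rng: np.random.Generator,
    mean_intervals: Sequence[float],
    duration: int,
) -> np.ndarray:
    """Advance free-running Poisson distractors by one step, in place.

    Discrete-time thinning of a Poisson process: each inactive channel turns
    on with probability 1/mean_interval per step and then stays on for
    ``duration`` steps (the onset step included); onsets arriving while a
    channel is active are ignored.  Returns the binary activity vector for
    this step.  ``timers`` holds the remaining active steps per channel.
    """
    probs = 1.0 / np.asarray(mean_intervals, dtype=float)
    inactive = timers <= 0
    onsets = inactive & (rng.random(timers.shape[0]) < probs)
    timers[onsets] = duration
    bits = (timers > 0).astype(np.uint8)
    timers -= bits.astype(timers.dtype)
    return bits


def generate_activation_patterns(
    n_cs: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``k`` distinct balanced bit-vectors (exactly n_cs/2 ones each).

    Sampling is without replacement from the set of all C(n_cs, n_cs/2)
    balanced configurations.
    """
    if n_cs % 2 != 0:
        raise ConfigError(f"n_cs: must be even, got {n_cs}")
    max_k = math.comb(n_cs, n_cs // 2)
    if not 1 <= k <= max_k:
        raise ConfigError(f"k_patterns: must be in [1, {max_k}], got {k}")
    seen: set[int] = set()
    patterns = np.zeros((k, n_cs), dtype=np.uint8)
    count = 0
    while count < k:
        bits = np.zeros(n_cs, dtype=np.uint8)
        bits[rng.choice(n_cs, n_cs // 2, replace=False)] = 1
        code = _encode_bits(bits)
        if code in seen:
            continue
        seen.add(code)
        patterns[count] = bits
        count += 1
    return patterns


def _encode_bits(bits: np.ndarray) -> int:
    code = 0
    for b in bits:
        code = (code << 1) | int(b)
    return code


@dataclass
class TrialDraw:
    cs_bits: np.ndarray
    us_outcome: bool
    pattern_active: bool
    noise_flipped: bool


def sample_trial(
    rng: np.random.Generator,
    patterns: np.ndarray,
    n_cs: int,
    noise_pct: float,
) -> TrialDraw:
    """Draw one patterning trial.

    With probability 1/2 the CS configuration is a uniformly chosen activation
    pattern, otherwise a uniform draw from the complement of the activation
    set over all 2^n_cs configurations.  The US outcome equals pattern
    membership XOR a noise flip that fires with probability ``noise_pct``/100.
    """
    if len(patterns) == 0:
        raise ConfigError("patterns: activation-pattern set must be non-empty")
    pattern_codes = {_encode_bits(p) for p in patterns}
    if bool(rng.random() < 0.5):
        cs_bits = patterns[rng.integers(len(patterns))].copy()
        member = True
    else:
        while True:
            cs_bits = rng.integers(0, 2, size=n_cs).astype(np.uint8)
            if _encode_bits(cs_bits) not in pattern_codes:
                break
        member = False
    flipped = bool(rng.random() < noise_pct / 100.0)
    return TrialDraw(cs_bits, member != flipped, member, flipped)


# ---------------------------------------------------------------------------
# Environments
# ---------------------------------------------------------------------------

class _ConditioningEnv:
    """Shared trial machinery: CS onset -> (ISI) -> US onset -> (ITI) -> next CS."""

    config: object
    layout: ChannelLayout

    def __init__(self, config) -> None:
        config.validate()
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        s_init, s_stream = ss.spawn(2)
        self._rng_init = np.random.default_rng(s_init)
        self.rng = np.random.default_rng(s_stream)
        self.clock = 0
        self.trial_id = -1
        self._cs_onset = -(10 ** 9)
        self._us_onset = -(10 ** 9)
        self._us_scheduled = False
        self._pattern_active = False
        self._noise_flipped = False
        self._setup()
        self._cs_bits = np.zeros(self.layout.n_cs, dtype=np.uint8)
        # Stream opens mid-ITI: the first CS onset arrives after one ITI draw.
        self._next_trial = sample_iti(self.rng, self.config.iti_range)

    # -- subclass hooks -----------------------------------------------------

    def _setup(self) -> None:
        raise NotImplementedError

    def _draw_trial(self) -> tuple[np.ndarray, bool, bool, bool]:
        """Return (cs_bits, us_outcome, pattern_active, noise_flipped)."""
        raise NotImplementedError

    def _draw_isi(self) -> int:
        raise NotImplementedError

    def _distractor_bits(self, t: int) -> np.ndarray:
        raise NotImplementedError

    # -- public API ---------------------------------------------------------

    @property
    def expected_isi(self) -> float:
        return self.config.expected_isi

    @property
    def gamma(self) -> float:
        """Discount factor from the stated rule gamma = 1 - 1/E(ISI)."""
        return 1.0 - 1.0 / self.expected_isi

    def step(self) -> Observation:
        t = self.clock
        if t == self._next_trial:
            self._begin_trial(t)
        cfg = self.config
        obs = np.zeros(self.layout.d, dtype=np.uint8)
        in_cs = self._cs_onset <= t < self._cs_onset + cfg.cs_duration
        if in_cs:
            obs[self.layout.cs_slice] = self._cs_bits
        in_us_window = self._us_onset <= t < self._us_onset + cfg.us_duration
        if in_us_window and self._us_scheduled:
            obs[self.layout.us_index] = 1
        obs[self.layout.distractor_slice] = self._distractor_bits(t)
        if in_us_window:
            phase = PHASE_US
        elif in_cs:
            phase = PHASE_CS
        elif self._cs_onset <= t < self._us_onset:
            phase = PHASE_TRACE
        else:
            phase = PHASE_ITI
        self.clock += 1
        return Observation(obs, TrialAnnotation(
            self.trial_id, self._pattern_active, self._noise_flipped, phase))

    def _begin_trial(self, t: int) -> None:
        self.trial_id += 1
        cs_bits, outcome, member, flipped = self._draw_trial()
        self._cs_bits = cs_bits
        self._us_scheduled = outcome
        self._pattern_active = member
        self._noise_flipped = flipped
        self._cs_onset = t
        self._us_onset = t + self._draw_isi()
        self._next_trial = self._us_onset + sample_iti(self.rng, self.config.iti_range)

    def run(self, n_steps: int) -> dict[str, np.ndarray]:
        """Generate ``n_steps`` observations as columnar arrays."""
        d = self.layout.d
        obs = np.zeros((n_steps, d), dtype=np.uint8)
        phase = np.zeros(n_steps, dtype=np.int8)
        trial_id = np.zeros(n_steps, dtype=np.int64)
        pattern_active = np.zeros(n_steps, dtype=bool)
        noise_flipped = np.zeros(n_steps, dtype=bool)
        for i in range(n_steps):
            ob = self.step()
            obs[i] = ob.values
            ann = ob.annotation
            phase[i] = ann.phase
            trial_id[i] = ann.trial_id
            pattern_active[i] = ann.pattern_active
            noise_flipped[i] = ann.noise_flipped
        return {
            "obs": obs,
            "us": obs[:, self.layout.us_index].astype(np.float64),
            "phase": phase,
            "trial_id": trial_id,
            "pattern_active": pattern_active,
            "noise_flipped": noise_flipped,
        }


class TraceConditioningEnv(_ConditioningEnv):
    """Single CS, stochastic ISI, free-running Poisson distractors."""

    def _setup(self) -> None:
        cfg = self.config
        self.layout = ChannelLayout(1, len(cfg.distractor_mean_intervals))
        self._timers = np.zeros(self.layout.n_distractors, dtype=np.int64)

    def _draw_trial(self):
        return np.ones(1, dtype=np.uint8), True, True, False

    def _draw_isi(self) -> int:
        return sample_isi(self.rng, self.config.isi_range)

    def _distractor_bits(self, t: int) -> np.ndarray:
        return distractor_step(
            self._timers, self.rng,
            self.config.distractor_mean_intervals,
            self.config.distractor_duration)


class NoisyPatterningEnv(_ConditioningEnv):
    """Balanced activation patterns, fixed ISI, trial-locked distractors."""

    def _setup(self) -> None:
        cfg = self.config
        self.layout = ChannelLayout(cfg.n_cs, cfg.n_distractors)
        self.patterns = generate_activation_patterns(
            cfg.n_cs, cfg.k_patterns, self._rng_init)
        self._distractor_trial_bits = np.zeros(cfg.n_distractors, dtype=np.uint8)

    def _draw_trial(self):
        draw = sample_trial(self.rng, self.patterns, self.config.n_cs,
                            self.config.noise_pct)
        # Distractors are trial-locked: i.i.d. Bernoulli(0.5) per trial,
        # co-occurring with the CS presentation.
        self._distractor_trial_bits = self.rng.integers(
            0, 2, size=self.layout.n_distractors).astype(np.uint8)
        return draw.cs_bits, draw.us_outcome, draw.pattern_active, draw.noise_flipped

    def _draw_isi(self) -> int:
        return self.config.isi

    def _distractor_bits(self, t: int) -> np.ndarray:
        if self._cs_onset <= t < self._cs_onset + self.config.cs_duration:
            return self._distractor_trial_bits
        return np.zeros(self.layout.n_distractors, dtype=np.uint8)


class TracePatterningEnv(_ConditioningEnv):
    """Activation patterns with stochastic ISI and Poisson distractors."""

    def _setup(self) -> None:
        cfg = self.config
        self.layout = ChannelLayout(cfg.n_cs, cfg.n_distractors)
        self.patterns = generate_activation_patterns(
            cfg.n_cs, cfg.k_patterns, self._rng_init)
        self._timers = np.zeros(cfg.n_distractors, dtype=np.int64)

    def _draw_trial(self):
        draw = sample_trial(self.rng, self.patterns, self.config.n_cs,
                            self.config.noise_pct)
        return draw.cs_bits, draw.us_outcome, draw.pattern_active, draw.noise_flipped

    def _draw_isi(self) -> int:
        return sample_isi(self.rng, self.config.isi_range)

    def _distractor_bits(self, t: int) -> np.ndarray:
        return distractor_step(
            self._timers, self.rng,
            self.config.distractor_mean_intervals,
            self.config.distractor_duration)


_ENV_BY_CONFIG = {
    TraceConditioningConfig: TraceConditioningEnv,
    NoisyPatterningConfig: NoisyPatterningEnv,
    TracePatterningConfig: TracePatterningEnv,
}


def make_env(config) -> _ConditioningEnv:
    """Construct the environment matching the config type."""
    try:
        cls = _ENV_BY_CONFIG[type(config)]
    except KeyError:
        raise ConfigError(f"unknown config type {type(config).__name__}") from None
    return cls(config)


def stream_dataframe(log: dict, layout: ChannelLayout):
    """Columnar view of a generated stream: step, one column per channel
    (cs0.., us, dis0..), phase, trial_id.  Suitable for CSV dumping."""
    import pandas as pd

    obs = log["obs"]
    columns = {"step": np.arange(obs.shape[0])}
    for i in range(layout.n_cs):
        columns[f"cs{i}"] = obs[:, i]
    columns["us"] = obs[:, layout.us_index]
    for i in range(layout.n_distractors):
        columns[f"dis{i}"] = obs[:, layout.us_index + 1 + i]
    columns["phase"] = log["phase"]
    columns["trial_id"] = log["trial_id"]
    return pd.DataFrame(columns)


def config_to_dict(config) -> dict:
    out = asdict(config)
    out["kind"] = {
        TraceConditioningConfig: "trace_conditioning",
        NoisyPatterningConfig: "noisy_patterning",
        TracePatterningConfig: "trace_patterning",
    }[type(config)]
    return out
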