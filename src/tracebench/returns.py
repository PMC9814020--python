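"""Ground-truth return computation and squared-return-error evaluation.

The prediction target is the discounted return of the US channel,

    G_t = sum_{k>=0} gamma^k US_{t+k+1},

computed retrospectively from a logged US stream by the backward recursion
G_t = US_{t+1} + gamma * G_{t+1}.  Because the stream is finite, the last few
returns are biased by tail truncation; a validity mask excludes the final
H = ceil(log(tail_tolerance) / log(gamma)) steps from evaluation.

Online predictions V_t are scored by the squared return error
SRE_t = (V_t - G_t)^2, averaged over valid steps into the mean squared return
error (MSRE); multi-run results aggregate as mean and standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ReturnSpec",
    "ReturnSeries",
    "RunSummary",
    "discount_from_expected_isi",
    "compute_returns",
    "sre",
    "msre",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ReturnSpec:
    gamma: float
    tail_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.tail_tolerance <= 0:
            raise ValueError("tail_tolerance must be positive")


@dataclass
class ReturnSeries:
    values: np.ndarray
    valid_mask: np.ndarray


@dataclass
class RunSummary:
    msre: float
    n_steps: int
    n_runs: int
    stderr: float | None
    config_digest: str | None = None
    seed: int | None = None


def discount_from_expected_isi(expected_isi: float) -> float:
    """Discount factor gamma = 1 - 1/E(ISI).

    This matches the prediction horizon 1/(1-gamma) to the expected
    inter-stimulus interval, e.g. a fixed ISI of 4 gives gamma = 0.75.
    """
    if expected_isi < 1:
        raise ValueError(f"expected_isi must be >= 1, got {expected_isi}")
    return 1.0 - 1.0 / expected_isi


def truncation_horizon(gamma: float, tail_tolerance: float) -> int:
    """Number of trailing steps whose returns the tail truncation can bias
    by more than ``tail_tolerance`` times the maximum achievable return."""
    if gamma == 0.0:
        return 1
    return max(1, math.ceil(math.log(tail_tolerance) / math.log(gamma)))


def compute_returns(us_series: np.ndarray, spec: ReturnSpec) -> ReturnSeries:
    """Backward-recursion returns of a finite US stream with a tail mask."""
    us = np.asarray(us_series, dtype=np.float64)
    if us.ndim != 1:
        raise ValueError("us_series must be one-dimensional")
    if not np.all(np.isfinite(us)):
        raise ValueError("us_series must be finite")
    n = us.shape[0]
    # G_t = us_{t+1} + gamma * G_{t+1} with G_{n-1} = 0: a first-order IIR
    # filter run over the time-reversed, left-shifted stream.
    shifted = np.empty(n)
    shifted[:-1] = us[1:]
    shifted[-1] = 0.0
    values = lfilter([1.0], [1.0, -spec.gamma], shifted[::-1])[::-1].copy()
    mask = np.ones(n, dtype=bool)
    h = truncation_horizon(spec.gamma, spec.tail_tolerance)
    mask[max(0, n - h):] = False
    return ReturnSeries(values, mask)


def sre(prediction: np.ndarray, return_value: np.ndarray) -> np.ndarray:
    """Per-step squared return error (V_t - G_t)^2."""
    prediction = np.asarray(prediction, dtype=np.float64)
    return_value = np.asarray(return_value, dtype=np.float64)
    if prediction.shape != return_value.shape:
        raise ValueError("prediction and return series have different lengths")
    return (prediction - return_value) ** 2


def msre(
    predictions: np.ndarray,
    returns: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Mean squared return error over mask-valid steps."""
    errors = sre(predictions, returns)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != errors.shape:
            raise ValueError("mask length does not match the series")
        errors = errors[mask]
    if errors.size == 0:
        raise ValueError("no valid steps to evaluate")
    return float(errors.mean())


def aggregate_runs(
    msre_list,
    n_steps: int = 0,
    config_digest: str | None = None,
    seed: int | None = None,
) -> RunSummary:
    """Mean MSRE and standard error (sample std / sqrt(n)) across runs."""
    values = np.asarray(list(msre_list), dtype=np.float64)
    if values.size == 0:
        raise ValueError("at least one run is required")
    mean = float(values.mean())
    if values.size >= 2:
        stderr = float(values.std(ddof=1) / math.sqrt(values.size))
    else:
        stderr = None  # undefined for a single run
    return RunSummary(mean, n_steps, int(values.size), stderr,
                      config_digest, seed)
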