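"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np


def run_lengths(bits) -> list[int]:
    """Lengths of consecutive-1 runs in a binary sequence."""
    bits = np.asarray(bits).astype(int)
    out = []
    count = 0
    for b in bits:
        if b:
            count += 1
        elif count:
            out.append(count)
            count = 0
    if count:
        out.append(count)
    return out


def onsets(bits) -> np.ndarray:
    """Indices of rising edges in a binary sequence."""
    bits = np.asarray(bits).astype(int)
    return np.flatnonzero(np.diff(np.r_[0, bits]) == 1)
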