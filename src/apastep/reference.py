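"""Literal single-pass reference detectors.

Each function here transcribes one textual detection rule as a plain
Python loop, with no vectorization and no shared code with
:mod:`apastep.events`.  They serve two roles:

* the synthetic-trial generator applies them to its noise-free,
  filtered templates to derive ground-truth event times;
* the test suite uses them as independent oracles for the vectorized
  detectors.

All functions work on sample indices; callers convert to seconds.
"""

from __future__ import annotations

import math
from typing import Optional


def scan_onset(
    vel: "list[float]",
    dt: float,
    threshold: float = 0.05,
    sustain_s: float = 0.05,
) -> Optional[int]:
    """First index where |vel| exceeds ``threshold`` and stays above it
    for at least ``sustain_s`` seconds (>= that many consecutive
    samples).  Returns ``None`` when no qualifying interval exists."""
    n = len(vel)
    need = int(round(sustain_s / dt))
    for i in range(n - need + 1):
        ok = True
        for j in range(i, i + need):
            if abs(vel[j]) <= threshold:
                ok = False
                break
        if ok:
            return i
    return None


def _prominence(x: "list[float]", i: int) -> float:
    """Topographic prominence of the local maximum at index ``i``."""
    peak = x[i]
    # walk left until a strictly higher sample or the boundary
    left_min = peak
    j = i - 1
    while j >= 0 and x[j] <= peak:
        if x[j] < left_min:
            left_min = x[j]
        j -= 1
    # walk right likewise
    right_min = peak
    j = i + 1
    while j < len(x) and x[j] <= peak:
        if x[j] < right_min:
            right_min = x[j]
        j += 1
    return peak - max(left_min, right_min)


def scan_first_peak(x: "list[float]", prominence: float = 0.001) -> int:
    """Index of the first local maximum with at least ``prominence``.

    Falls back to the global maximum of the window (the last sample for
    a monotone rise) when no interior local maximum qualifies.
    """
    n = len(x)
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            if _prominence(x, i) >= prominence:
                return i
    best = 0
    for i in range(1, n):
        if x[i] > x[best]:
            best = i
    return best


def scan_sustained_above(
    vel: "list[float]",
    dt: float,
    threshold: float,
    sustain_s: float,
    start: int = 0,
) -> Optional[int]:
    """First index >= ``start`` where ``vel`` (signed) exceeds
    ``threshold`` for at least ``sustain_s`` seconds."""
    n = len(vel)
    need = int(round(sustain_s / dt))
    for i in range(start, n - need + 1):
        ok = True
        for j in range(i, i + need):
            if vel[j] <= threshold:
                ok = False
                break
        if ok:
            return i
    return None


def scan_foot_contact(
    vz: "list[float]",
    foot_off: int,
    threshold: float = -0.02,
) -> Optional[int]:
    """Foot contact after the fastest descent.

    Finds the global minimum of the vertical velocity after
    ``foot_off``, then returns the first index after that minimum at
    which the velocity rises above ``threshold`` (first crossing,
    earliest-index tie-break)."""
    n = len(vz)
    if foot_off >= n:
        return None
    i_min = foot_off
    for i in range(foot_off, n):
        if vz[i] < vz[i_min]:
            i_min = i
    for i in range(i_min, n):
        if vz[i] > threshold:
            return i
    return None


def scan_reveal_crossing(
    fz1: "list[float]",
    fz2: "list[float]",
    dt: float,
    go_time: float,
    t0: float,
    body_weight_n: float,
    frac: float = 0.10,
) -> Optional[float]:
    """Time of the first sample after the go cue at which the absolute
    force difference strictly exceeds ``frac`` of body weight.

    ``t0`` is the time of sample 0.  Returns ``None`` when the
    threshold is never crossed."""
    thresh = frac * body_weight_n
    n = len(fz1)
    for i in range(n):
        t = t0 + i * dt
        if t <= go_time:
            continue
        if abs(fz1[i] - fz2[i]) > thresh:
            return t
    return None
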