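"""Target-reveal trigger simulation and trial-exclusion rules.

A trial is excluded when any of five rules fires:

1. ``uneven_stance`` — between the first and second auditory cue the
   participant loaded one side with more than 55% of body weight;
2. ``early_onset`` — the COP onset was detected before the go cue;
3. ``abnormal_direction`` — just after onset the COP moved toward the
   stance side and/or anteriorly (quantified as the mean displacement
   over the first 50 ms after onset);
4. ``reveal_before_peak`` — the true target appeared before the initial
   lateral or posterior COP peak (dual-target trials only);
5. ``multiple_steps`` — more than one step was needed to stop.

The online reveal trigger fires at the first sample after the go cue
at which the vertical-force difference between the plates strictly
exceeds 10% of body weight; the on-screen reveal lags it by a fixed
display latency (default 217 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .events import CopEvents
from .preprocess import CopTrace, body_weight, cop_trace
from .trial_io import TrialRecording

RULES = (
    "uneven_stance",
    "early_onset",
    "abnormal_direction",
    "reveal_before_peak",
    "multiple_steps",
)


@dataclass
class QcThresholds:
    uneven_load_frac: float = 0.55
    trigger_frac: float = 0.10
    reveal_latency_s: float = 0.217
    direction_window_s: float = 0.05


@dataclass
class TrialVerdict:
    """QC outcome for one trial.

    ``failed_rules`` lists every exclusion rule that fired; the two
    extra sentinel values ``no_onset`` and ``no_step`` mark trials on
    which detection itself found nothing to measure."""

    failed_rules: list[str] = field(default_factory=list)
    reveal_time_s: Optional[float] = None

    @property
    def valid(self) -> bool:
        return not self.failed_rules


def reveal_time(
    trial: TrialRecording,
    body_weight_n: Optional[float] = None,
    thresholds: QcThresholds = QcThresholds(),
) -> Optional[float]:
    """Simulated on-screen reveal time for a dual-target trial.

    First raw-force sample after the go cue with
    ``|fz1 - fz2| > trigger_frac * body weight`` (strict), plus the
    display latency.  ``None`` when never crossed."""
    if body_weight_n is None:
        body_weight_n = body_weight(trial)
    t = trial.plate["time_s"].to_numpy()
    diff = np.abs(
        trial.plate["fz1_N"].to_numpy() - trial.plate["fz2_N"].to_numpy()
    )
    mask = (t > trial.meta.go_time_s) & (diff > thresholds.trigger_frac * body_weight_n)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    return float(t[idx[0]]) + thresholds.reveal_latency_s


def judge_trial(
    trial: TrialRecording,
    events: Optional[CopEvents],
    reveal_s: Optional[float] = None,
    trace: Optional[CopTrace] = None,
    thresholds: QcThresholds = QcThresholds(),
) -> TrialVerdict:
    """Apply all five exclusion rules to one trial.

    ``events`` may be ``None`` (no onset was detectable), in which case
    the trial is invalid with the ``no_onset`` sentinel.  For dual
    trials the recorded on-screen reveal time from the metadata is
    preferred over ``reveal_s``.
    """
    failed: list[str] = []
    meta = trial.meta
    is_dual = meta.n_targets == "dual"
    w = meta.body_weight_n

    # rule 1: uneven stance between the two auditory cues
    t = trial.plate["time_s"].to_numpy()
    window = (t >= meta.target_onset_time_s) & (t <= meta.go_time_s)
    fz1 = trial.plate["fz1_N"].to_numpy()[window]
    fz2 = trial.plate["fz2_N"].to_numpy()[window]
    if (fz1 > thresholds.uneven_load_frac * w).any() or (
        fz2 > thresholds.uneven_load_frac * w
    ).any():
        failed.append("uneven_stance")

    if events is None:
        failed.append("no_onset")
        return TrialVerdict(failed_rules=failed, reveal_time_s=reveal_s)

    # rule 2: onset before the go cue
    if events.onset_time_s < meta.go_time_s:
        failed.append("early_onset")

    # rule 3: initial COP direction toward stance side and/or anterior
    if trace is None:
        trace = cop_trace(trial)
    i0 = trace.index_at(events.onset_time_s)
    i1 = min(i0 + int(round(thresholds.direction_window_s / trace.dt)), len(trace.time_s) - 1)
    dx = trace.cop_x_m[i0 + 1 : i1 + 1] - trace.cop_x_m[i0]
    dy = trace.cop_y_m[i0 + 1 : i1 + 1] - trace.cop_y_m[i0]
    if dx.size and (dx.mean() < 0 or dy.mean() > 0):
        failed.append("abnormal_direction")

    # rule 4: reveal before the initial peaks (dual-target trials only)
    if is_dual:
        reveal = meta.reveal_time_s if meta.reveal_time_s is not None else reveal_s
        if reveal is None:
            failed.append("reveal_before_peak")
            reveal_s = None
        else:
            reveal_s = reveal
            if reveal < min(events.lateral_peak_time_s, events.posterior_peak_time_s):
                failed.append("reveal_before_peak")
    else:
        reveal_s = None

    # rule 5: multiple steps to stop
    if events.multiple_steps:
        failed.append("multiple_steps")

    return TrialVerdict(failed_rules=failed, reveal_time_s=reveal_s)


def qc_table(verdicts: dict[str, TrialVerdict]) -> pd.DataFrame:
    """Tabulate verdicts (trial id -> verdict) as one row per trial."""
    rows = []
    for trial_id, v in verdicts.items():
        rows.append(
            {
                "trial": trial_id,
                "valid": v.valid,
                "failed_rules": ",".join(v.failed_rules),
                "reveal_time_s": v.reveal_time_s,
            }
        )
    return pd.DataFrame(rows)
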