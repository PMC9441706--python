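"""COP and foot event detection plus dependent variables.

Detection rules (all applied to filtered signals):

* COP onset: first time the absolute mediolateral COP velocity exceeds
  0.05 m/s and stays above it for at least 50 ms.
* Initial lateral / posterior peaks: first local maximum of the
  swing-side (resp. posterior) COP excursion after onset with
  topographic prominence >= 1 mm, searched up to foot-off; the global
  maximum of the window when no interior peak qualifies (monotone
  drift).  The "initial peak" rule guards the measurements against
  feedback corrections that follow the target reveal.
* Foot-off: vertical velocity of the swing second-metatarsal marker
  exceeds +0.02 m/s sustained for 50 ms (mirror of the contact rule;
  needed to bound the peak-search window).
* Foot contact: after the fastest descent (global minimum of that
  marker's vertical velocity), the first time it rises above -0.02 m/s.

Stability margins follow the extrapolated-center-of-mass construct:
XCOM = COM + v / omega0 with omega0 = sqrt(g / L); MOS is the signed
distance from the relevant base-of-support edge marker to the XCOM at
foot contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import CopTrace, central_velocity, cop_trace, lowpass
from .trial_io import MARKER_RATE_HZ, TrialRecording

G_MPS2 = 9.81


class NoStepError(ValueError):
    """The swing foot never left the ground."""


@dataclass
class OnsetResult:
    time_s: float
    index: int
    direction: str  # "swing" or "stance"


@dataclass
class FootEvents:
    foot_off_time_s: float
    foot_contact_time_s: float
    multiple_steps: bool


@dataclass
class CopEvents:
    """Detected events and derived dependent variables for one trial."""

    onset_time_s: float
    lateral_peak_time_s: float
    posterior_peak_time_s: float
    foot_off_time_s: float
    foot_contact_time_s: float
    lateral_disp_mm: float
    posterior_disp_mm: float
    movement_time_s: float
    onset_direction: str
    multiple_steps: bool


@dataclass
class StabilityMargins:
    com_xy_m: tuple[float, float]
    com_vel_xy_mps: tuple[float, float]
    xcom_xy_m: tuple[float, float]
    pendulum_length_m: float
    mos_ml_mm: float
    mos_ap_mm: float

    @property
    def unstable(self) -> bool:
        return self.mos_ml_mm < 0


def _first_sustained(above: np.ndarray, need: int) -> Optional[int]:
    """First index i such that above[i : i + need] is all True."""
    if need <= 1:
        idx = np.flatnonzero(above)
        return int(idx[0]) if idx.size else None
    counts = np.convolve(above.astype(int), np.ones(need, dtype=int), mode="valid")
    idx = np.flatnonzero(counts == need)
    return int(idx[0]) if idx.size else None


def detect_cop_onset(
    trace: CopTrace,
    threshold_mps: float = 0.05,
    sustain_s: float = 0.05,
) -> Optional[OnsetResult]:
    """COP movement onset from the mediolateral velocity.

    Searches the whole trace (pre-go onsets must be detectable so QC
    can reject them).  Returns ``None`` when no qualifying interval
    exists."""
    need = int(round(sustain_s / trace.dt))
    above = np.abs(trace.vel_x_mps) > threshold_mps
    i = _first_sustained(above, need)
    if i is None:
        return None
    direction = "swing" if trace.vel_x_mps[i] > 0 else "stance"
    return OnsetResult(time_s=float(trace.time_s[i]), index=i, direction=direction)


def _first_peak(window: np.ndarray, prominence: float) -> int:
    """First local maximum with the required prominence; global-argmax
    fallback for monotone windows."""
    peaks, _ = sps.find_peaks(window, prominence=prominence)
    if peaks.size:
        return int(peaks[0])
    return int(np.argmax(window))


def find_initial_peaks(
    trace: CopTrace,
    onset: OnsetResult,
    foot_off_time_s: float,
    prominence_m: float = 0.001,
) -> tuple[float, float, float, float]:
    """Initial lateral and posterior COP peaks in (onset, foot-off].

    Returns ``(lateral_peak_time, posterior_peak_time, lateral_disp_mm,
    posterior_disp_mm)``; displacements are measured from the COP
    position at onset, in millimeters."""
    i0 = onset.index
    i1 = int(np.searchsorted(trace.time_s, foot_off_time_s))
    i1 = min(i1, len(trace.time_s) - 1)
    if i1 <= i0:
        raise ValueError("empty peak-search window (foot-off precedes onset)")
    lat = trace.cop_x_m[i0 : i1 + 1]
    post = -trace.cop_y_m[i0 : i1 + 1]
    i_lp = _first_peak(lat, prominence_m)
    i_pp = _first_peak(post, prominence_m)
    return (
        float(trace.time_s[i0 + i_lp]),
        float(trace.time_s[i0 + i_pp]),
        abs(lat[i_lp] - lat[0]) * 1000.0,
        abs(post[i_pp] - post[0]) * 1000.0,
    )


def detect_foot_events(
    trial: TrialRecording,
    threshold_mps: float = 0.02,
    sustain_s: float = 0.05,
    cutoff_hz: float = 4.0,
) -> FootEvents:
    """Foot-off and foot-contact of the swing foot from its
    second-metatarsal marker; also flags any second lift-off of either
    foot after landing (multiple steps)."""
    swing = "r" if trial.meta.swing_side == "right" else "l"
    stance = "l" if swing == "r" else "r"
    tm = trial.markers["time_s"].to_numpy(dtype=float)
    dt = float(tm[1] - tm[0])
    need = int(round(sustain_s / dt))

    z = lowpass(trial.markers[f"{swing}_mt2_z_m"].to_numpy(), cutoff_hz, MARKER_RATE_HZ)
    vz = central_velocity(z, dt)
    i_off = _first_sustained(vz > threshold_mps, need)
    if i_off is None:
        raise NoStepError("swing-foot marker never leaves the ground")
    i_min = i_off + int(np.argmin(vz[i_off:]))
    after = np.flatnonzero(vz[i_min:] > -threshold_mps)
    if after.size == 0:
        raise NoStepError("no foot contact after the descent minimum")
    i_contact = i_min + int(after[0])

    # a second lift-off of either foot after landing marks a multi-step
    # stop; the candidate must also gain real height (>= 10 mm above its
    # landing level) so that filter ringing at touchdown cannot qualify
    multiple = False
    for side in (swing, stance):
        zs = lowpass(
            trial.markers[f"{side}_mt2_z_m"].to_numpy(), cutoff_hz, MARKER_RATE_HZ
        )
        vzs = central_velocity(zs, dt)
        start = i_contact + need
        if start >= len(vzs):
            continue
        cand = _first_sustained(vzs[start:] > threshold_mps, need)
        if cand is not None and zs[start + cand :].max() > zs[i_contact] + 0.010:
            multiple = True
            break
    return FootEvents(
        foot_off_time_s=float(tm[i_off]),
        foot_contact_time_s=float(tm[i_contact]),
        multiple_steps=multiple,
    )


def detect_events(
    trial: TrialRecording,
    trace: Optional[CopTrace] = None,
    onset_threshold_mps: float = 0.05,
    sustain_s: float = 0.05,
    contact_threshold_mps: float = 0.02,
    prominence_m: float = 0.001,
) -> Optional[CopEvents]:
    """Run all detectors on one trial.

    Returns ``None`` when no COP onset qualifies (the trial is then
    excluded downstream); raises :class:`NoStepError` when the foot
    never lifts."""
    if trace is None:
        trace = cop_trace(trial)
    onset = detect_cop_onset(trace, onset_threshold_mps, sustain_s)
    if onset is None:
        return None
    foot = detect_foot_events(trial, contact_threshold_mps, sustain_s)
    t_lp, t_pp, d_lat, d_post = find_initial_peaks(
        trace, onset, foot.foot_off_time_s, prominence_m
    )
    return CopEvents(
        onset_time_s=onset.time_s,
        lateral_peak_time_s=t_lp,
        posterior_peak_time_s=t_pp,
        foot_off_time_s=foot.foot_off_time_s,
        foot_contact_time_s=foot.foot_contact_time_s,
        lateral_disp_mm=d_lat,
        posterior_disp_mm=d_post,
        movement_time_s=foot.foot_contact_time_s - onset.time_s,
        onset_direction=onset.direction,
        multiple_steps=foot.multiple_steps,
    )


# ---------------------------------------------------------------------------
# stability margins
# ---------------------------------------------------------------------------

_PELVIS = ("l_asis", "r_asis", "l_psis", "r_psis")


def stability_margins(
    trial: TrialRecording,
    foot_contact_time_s: float,
    cutoff_hz: float = 4.0,
    stance_window_s: float = 0.5,
) -> StabilityMargins:
    """COM, XCOM and margins of stability at foot contact.

    COM is the mean of the four pelvis markers (horizontal plane); the
    pendulum length L is the vertical distance from the COM to the mean
    heel height over the quiet-stance baseline before the go cue.
    MOS_ML uses the swing-foot fifth-metatarsal marker (lateral BOS
    edge), MOS_AP the swing-foot toe marker (anterior edge); both are
    positive when the XCOM lies inside the base of support."""
    m = trial.markers
    tm = m["time_s"].to_numpy(dtype=float)
    dt = float(tm[1] - tm[0])
    swing = "r" if trial.meta.swing_side == "right" else "l"
    required = [f"{p}_{ax}_m" for p in _PELVIS for ax in ("x", "y", "z")] + [
        f"{swing}_mt5_x_m",
        f"{swing}_toe_y_m",
        "l_heel_z_m",
        "r_heel_z_m",
    ]
    missing = [c for c in required if c not in m.columns]
    if missing:
        raise ValueError(f"missing marker channel(s): {', '.join(missing)}")

    def filt(col: str) -> np.ndarray:
        return lowpass(m[col].to_numpy(), cutoff_hz, MARKER_RATE_HZ)

    com_x = np.mean([filt(f"{p}_x_m") for p in _PELVIS], axis=0)
    com_y = np.mean([filt(f"{p}_y_m") for p in _PELVIS], axis=0)
    com_z = np.mean([filt(f"{p}_z_m") for p in _PELVIS], axis=0)
    go = trial.meta.go_time_s
    base = (tm >= go - stance_window_s) & (tm < go)
    if not base.any():
        raise ValueError("no quiet-stance window before the go cue")
    heel_z = 0.5 * (filt("l_heel_z_m") + filt("r_heel_z_m"))
    L = float(com_z[base].mean() - heel_z[base].mean())
    if L <= 0:
        raise ValueError(f"non-positive pendulum length L = {L:g} m")

    vx = central_velocity(com_x, dt)
    vy = central_velocity(com_y, dt)
    i = int(np.argmin(np.abs(tm - foot_contact_time_s)))
    omega0 = np.sqrt(G_MPS2 / L)
    xcom_x = com_x[i] + vx[i] / omega0
    xcom_y = com_y[i] + vy[i] / omega0
    mos_ml = filt(f"{swing}_mt5_x_m")[i] - xcom_x
    if trial.meta.swing_side == "left":
        mos_ml = -mos_ml
    mos_ap = filt(f"{swing}_toe_y_m")[i] - xcom_y
    return StabilityMargins(
        com_xy_m=(float(com_x[i]), float(com_y[i])),
        com_vel_xy_mps=(float(vx[i]), float(vy[i])),
        xcom_xy_m=(float(xcom_x), float(xcom_y)),
        pendulum_length_m=L,
        mos_ml_mm=float(mos_ml) * 1000.0,
        mos_ap_mm=float(mos_ap) * 1000.0,
    )


def count_unstable(cohort: pd.DataFrame) -> pd.DataFrame:
    """Number of valid trials with MOS_ML strictly below zero, per
    participant and condition (exactly zero does not count)."""
    df = cohort.copy()
    df["unstable"] = df["mos_ml_mm"] < 0
    out = (
        df.groupby(["participant", "n_targets", "side"], as_index=False)["unstable"]
        .sum()
        .rename(columns={"unstable": "n_unstable"})
    )
    out["n_unstable"] = out["n_unstable"].astype(int)
    return out
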