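"""Signal conditioning: zero-phase filtering, global COP, velocities.

Plate channels are low-pass filtered at 20 Hz and marker channels at
4 Hz before any event detection.  "Fourth order" refers to the designed
Butterworth order before the forward-backward pass (the usual
biomechanics convention); the effective order doubles and the pass is
zero-phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .trial_io import TrialRecording, PLATE_RATE_HZ


class DegenerateLoadError(ValueError):
    """Total vertical force is non-positive somewhere: COP undefined."""


def lowpass(x: np.ndarray, cutoff_hz: float, fs_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Parameters
    ----------
    x : array
        Uniformly sampled signal (filtered along the first axis).
    cutoff_hz : float
        -3 dB cutoff of the one-way design; must be below Nyquist.
    fs_hz : float
        Sampling rate.
    order : int
        Designed order of the one-way filter; applied forward and
        backward (`sosfiltfilt`), so no phase lag is introduced.

    Edges are handled by reflect-padding up to 1 s of signal, which
    keeps constant inputs exactly constant.
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz >= fs_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz:g} Hz >= Nyquist {fs_hz / 2:g} Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    padlen = min(x.shape[0] - 1, int(round(fs_hz)))
    return sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def global_cop(
    fz1: np.ndarray, fz2: np.ndarray, cop1: np.ndarray, cop2: np.ndarray
) -> np.ndarray:
    """Force-weighted COP of two plates, per axis.

    cop_global = (fz1*cop1 + fz2*cop2) / (fz1 + fz2).  ``cop1``/``cop2``
    may be 1-D (single axis) or 2-D ``(n, axes)``; forces are 1-D.
    """
    fz1 = np.asarray(fz1, dtype=float)
    fz2 = np.asarray(fz2, dtype=float)
    cop1 = np.asarray(cop1, dtype=float)
    cop2 = np.asarray(cop2, dtype=float)
    total = fz1 + fz2
    if (total <= 0).any():
        raise DegenerateLoadError("fz1 + fz2 <= 0 at some sample; COP undefined")
    if cop1.ndim == 2:
        w1 = (fz1 / total)[:, None]
        w2 = (fz2 / total)[:, None]
    else:
        w1 = fz1 / total
        w2 = fz2 / total
    return w1 * cop1 + w2 * cop2


def central_velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """3-point central-difference derivative; one-sided at the ends.

    Interior: v[i] = (x[i+1] - x[i-1]) / (2 dt).  Exact for polynomials
    of degree <= 2.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for a central difference")
    return np.gradient(x, dt, axis=0, edge_order=1)


def body_weight(trial: TrialRecording, window_s: float = 0.5) -> float:
    """Body weight in newtons from the quiet-stance baseline.

    Mean of fz1 + fz2 over the ``window_s`` seconds preceding the go
    cue.  Raises when the recording holds less baseline than that.
    """
    go = trial.meta.go_time_s
    t = trial.plate["time_s"].to_numpy()
    if go - t[0] < window_s:
        raise ValueError(
            f"baseline before go cue is {go - t[0]:.3f} s, need >= {window_s:g} s"
        )
    mask = (t >= go - window_s) & (t < go)
    fz = trial.plate["fz1_N"].to_numpy()[mask] + trial.plate["fz2_N"].to_numpy()[mask]
    return float(fz.mean())


@dataclass
class CopTrace:
    """Filtered global COP and its velocity, on the plate time base."""

    time_s: np.ndarray
    cop_x_m: np.ndarray
    cop_y_m: np.ndarray
    vel_x_mps: np.ndarray
    vel_y_mps: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def index_at(self, time_s: float) -> int:
        """Index of the sample nearest to ``time_s``."""
        return int(np.argmin(np.abs(self.time_s - time_s)))


def cop_trace(
    trial: TrialRecording, cutoff_hz: float = 20.0, order: int = 4
) -> CopTrace:
    """Filter plate channels and build the global COP trace.

    All plate channels are filtered at ``cutoff_hz`` first, then the
    two plates are combined and differentiated.  For a left-side swing
    foot the mediolateral axis is mirrored so that +x always points
    toward the swing limb.
    """
    p = trial.plate
    fz1 = lowpass(p["fz1_N"].to_numpy(), cutoff_hz, PLATE_RATE_HZ, order)
    fz2 = lowpass(p["fz2_N"].to_numpy(), cutoff_hz, PLATE_RATE_HZ, order)
    # forces may dip microscopically below zero after filtering
    fz1 = np.clip(fz1, 0.0, None)
    fz2 = np.clip(fz2, 0.0, None)
    cop1 = lowpass(p[["cop1_x_m", "cop1_y_m"]].to_numpy(), cutoff_hz, PLATE_RATE_HZ, order)
    cop2 = lowpass(p[["cop2_x_m", "cop2_y_m"]].to_numpy(), cutoff_hz, PLATE_RATE_HZ, order)
    cop = global_cop(fz1, fz2, cop1, cop2)
    x = cop[:, 0]
    y = cop[:, 1]
    if trial.meta.swing_side == "left":
        x = -x
    t = p["time_s"].to_numpy(dtype=float)
    dt = float(t[1] - t[0])
    return CopTrace(
        time_s=t,
        cop_x_m=x,
        cop_y_m=y,
        vel_x_mps=central_velocity(x, dt),
        vel_y_mps=central_velocity(y, dt),
    )
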