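"""Synthetic stepping-trial generator with embedded ground truth.

Two levels of synthesis are provided:

* :func:`gen_cohort_summary` draws trial-level dependent variables
  directly from the hierarchical data-generating model (for testing the
  statistics and the Bayesian estimator at scale), and
* :func:`gen_timeseries_trial` renders one full dual-plate /
  marker recording (for testing the detection pipeline end to end).

The data-generating model mirrors the hierarchical weighting structure:
each participant k carries a latent logit weight ``alpha_k ~
Normal(group_alpha, sigma_alpha)``; ``theta_k = invlogit(alpha_k)``
weights that participant's single-medial versus single-lateral mean
lateral COP excursion, and dual-target trial values scatter around the
weighted mean with SD ``sigma_k``.

Time-series trials are built from minimum-jerk (quintic smoothstep)
position templates so that every detection rule has a single,
analytically unambiguous answer.  Ground-truth event times are derived
by applying the literal reference detectors (:mod:`apastep.reference`)
to the noise-free, filtered template, and are stored in the trial's
metadata sidecar under ``sim``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .preprocess import lowpass, global_cop, central_velocity
from .trial_io import (
    COHORT_COLUMNS,
    MARKER_RATE_HZ,
    PLATE_RATE_HZ,
    TrialMeta,
    TrialRecording,
    marker_columns,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def invlogit(a):
    from scipy.special import expit

    return expit(np.asarray(a, dtype=float))


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

#: failure mode -> QC rule expected to catch it
FAILURE_MODES = (
    "uneven_stance",
    "early_onset",
    "abnormal_initial_direction",
    "late_peak_reveal",
    "multiple_steps",
)
FAILURE_TO_RULE = {
    "uneven_stance": "uneven_stance",
    "early_onset": "early_onset",
    "abnormal_initial_direction": "abnormal_direction",
    "late_peak_reveal": "reveal_before_peak",
    "multiple_steps": "multiple_steps",
}


@dataclass
class GeneratorConfig:
    """Simulation truth for a cohort.

    Default group weight invlogit(group_alpha) = 0.85 encodes a
    medial-dominant cohort; single-condition lateral COP excursions
    default to 30 mm (lateral target) and 45 mm (medial target), with
    3 mm trial-to-trial noise.  The reveal latency reproduces the
    ~217 ms display lag of the acquisition setup being emulated.
    """

    n_participants: int = 13
    trials_per_condition: int = 24
    group_alpha: float = logit(0.85)
    sigma_alpha: float = 0.5
    mean_single_lateral_mm: float = 30.0
    mean_single_medial_mm: float = 45.0
    participant_sd_mm: float = 2.0
    sigma_k_mm: float = 3.0
    posterior_single_mm: float = 35.0
    posterior_dual_mm: float = 25.0
    posterior_sd_mm: float = 2.0
    reveal_latency_s: float = 0.217
    # time-series observation noise
    force_noise_n: float = 1.5
    cop_noise_m: float = 0.0003
    marker_noise_m: float = 0.00015
    swing_jitter_s: float = 0.02
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ConfigError("participant and trial counts must be >= 1")
        if self.sigma_k_mm <= 0:
            raise ConfigError("sigma_k_mm must be > 0")
        for name in (
            "sigma_alpha",
            "participant_sd_mm",
            "posterior_sd_mm",
            "force_noise_n",
            "cop_noise_m",
            "marker_noise_m",
            "swing_jitter_s",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.mean_single_medial_mm > self.mean_single_lateral_mm:
            raise ConfigError(
                "mean_single_medial_mm must exceed mean_single_lateral_mm "
                "(medial stepping requires the larger lateral COP shift)"
            )
        return self


@dataclass
class ParticipantTruth:
    """Latent per-participant parameters."""

    participant: str
    alpha_k: float
    theta_k: float
    mu_sl_mm: float
    mu_sm_mm: float
    sigma_k_mm: float
    body_weight_n: float


@dataclass
class GroundTruth:
    """Cohort-level simulation truth.

    ``participants`` holds one row per participant (alpha_k, theta_k,
    single-condition base means, sigma_k, body weight); ``trials``
    holds one row per generated trial with its condition, true value,
    validity flag, and failure mode.  Full time-series trials carry
    their event-level truth in ``TrialRecording.meta.sim``.
    """

    group_alpha: float
    sigma_alpha: float
    participants: pd.DataFrame
    trials: pd.DataFrame


# ---------------------------------------------------------------------------
# participant and summary-level synthesis
# ---------------------------------------------------------------------------


def gen_participants(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[ParticipantTruth]:
    out = []
    for k in range(config.n_participants):
        alpha_k = rng.normal(config.group_alpha, config.sigma_alpha)
        mu_sl = rng.normal(config.mean_single_lateral_mm, config.participant_sd_mm)
        mu_sm = rng.normal(config.mean_single_medial_mm, config.participant_sd_mm)
        # keep the defining ordering of the two single conditions
        mu_sm = max(mu_sm, mu_sl + 5.0)
        out.append(
            ParticipantTruth(
                participant=f"P{k + 1:02d}",
                alpha_k=float(alpha_k),
                theta_k=float(invlogit(alpha_k)),
                mu_sl_mm=float(mu_sl),
                mu_sm_mm=float(mu_sm),
                sigma_k_mm=config.sigma_k_mm,
                body_weight_n=float(np.clip(rng.normal(588.0, 100.0), 400.0, 900.0)),
            )
        )
    return out


def condition_mean_mm(truth: ParticipantTruth, condition: str) -> float:
    """Mean lateral COP excursion for a participant in a condition."""
    if condition == "single-lateral":
        return truth.mu_sl_mm
    if condition == "single-medial":
        return truth.mu_sm_mm
    if condition == "single-center":
        return 0.5 * (truth.mu_sl_mm + truth.mu_sm_mm)
    if condition in ("dual-lateral", "dual-medial"):
        return truth.theta_k * truth.mu_sm_mm + (1.0 - truth.theta_k) * truth.mu_sl_mm
    raise ConfigError(f"unknown condition {condition!r}")


_MOS_ML_BASE_MM = {"lateral": 280.0, "center": 180.0, "medial": 80.0}
_SWING_BASE_S = 0.45
_MT_SLOPE_S_PER_MM = 0.005
_POSTERIOR_REF_MM = 35.0
_RISE_S = 0.25
_POSTERIOR_PEAK_S = 0.28
_UNLOAD_S = 0.30


def _movement_time_s(posterior_mm: float, jitter_s: float = 0.0) -> float:
    """Movement time implied by the posterior excursion.

    Smaller posterior COP shifts decelerate the body less effectively,
    so the step takes longer; the negative coupling (-5 ms/mm) is what
    the trial-wise regression is meant to recover.
    """
    return (
        _RISE_S
        + _UNLOAD_S
        + _SWING_BASE_S
        + _MT_SLOPE_S_PER_MM * (_POSTERIOR_REF_MM - posterior_mm)
        + jitter_s
    )


def gen_cohort_summary(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort of trial-level dependent variables.

    Returns a cohort table (one row per valid trial, cohort-table
    columns) plus the ground truth.  Deterministic under a fixed
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants = gen_participants(config, rng)
    rows = []
    for truth in participants:
        for condition in (
            "single-lateral",
            "single-center",
            "single-medial",
            "dual-lateral",
            "dual-medial",
        ):
            n_targets, side = condition.split("-", 1)
            mean_mm = condition_mean_mm(truth, condition)
            post_mean = (
                config.posterior_dual_mm
                if n_targets == "dual"
                else config.posterior_single_mm
            )
            for i in range(config.trials_per_condition):
                lateral = rng.normal(mean_mm, truth.sigma_k_mm)
                posterior = rng.normal(post_mean, config.posterior_sd_mm)
                mos_ml = (
                    _MOS_ML_BASE_MM[side]
                    - (5.0 if n_targets == "dual" else 0.0)
                    + rng.normal(0.0, 10.0)
                )
                mos_ap = (
                    230.0
                    + (15.0 if side == "medial" else 0.0)
                    + (10.0 if n_targets == "dual" and side == "lateral" else 0.0)
                    + rng.normal(0.0, 10.0)
                )
                mt = _movement_time_s(posterior, rng.normal(0.0, config.swing_jitter_s))
                rows.append(
                    {
                        "participant": truth.participant,
                        "day": 1 + (i % 2),
                        "n_targets": n_targets,
                        "side": side,
                        "lateral_disp_mm": lateral,
                        "posterior_disp_mm": posterior,
                        "mos_ml_mm": mos_ml,
                        "mos_ap_mm": mos_ap,
                        "movement_time_s": mt,
                    }
                )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    trials = table.copy()
    trials["valid"] = True
    trials["failure_mode"] = None
    truth = GroundTruth(
        group_alpha=config.group_alpha,
        sigma_alpha=config.sigma_alpha,
        participants=pd.DataFrame([asdict(p) for p in participants]),
        trials=trials,
    )
    return table, truth


# ---------------------------------------------------------------------------
# time-series synthesis
# ---------------------------------------------------------------------------

_FIXATION_S = 1.0
_STANCE_HALF_M = 0.10  # foot centers at x = -0.10 (stance) and +0.10 (swing)
_SWING_HEIGHT_M = 0.06
_TAIL_S = 0.8
_TARGET_DISTANCE_M = 0.325
_TARGET_SPACING_M = 0.10

# marker offsets relative to the right foot center (x mirrored for left)
_FOOT_MARKERS = {
    "toe": (0.000, 0.130, 0.020),
    "mt1": (-0.035, 0.090, 0.020),
    "mt2": (0.000, 0.100, 0.020),
    "mt5": (0.045, 0.070, 0.020),
    "heel": (0.000, -0.070, 0.030),
}
_PELVIS_MARKERS = {
    "asis": (0.120, 0.100, 0.950),
    "psis": (0.050, -0.060, 0.970),
}


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile 0 -> 1 on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _bump(tau: np.ndarray) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 bump built from two smoothstep halves."""
    tau = np.clip(tau, 0.0, 1.0)
    return np.where(tau <= 0.5, _smoothstep(2 * tau), _smoothstep(2 * (1 - tau)))


def _segment(t, t_start, duration, y0, y1):
    """Minimum-jerk transition from y0 to y1 over [t_start, t_start+duration]."""
    return y0 + (y1 - y0) * _smoothstep((t - t_start) / duration)


@dataclass
class _TrialParams:
    """Fully resolved template parameters of one time-series trial."""

    go_time_s: float
    onset_time_s: float
    amp_lateral_m: float
    amp_posterior_m: float
    swing_s: float
    land_dx_m: float
    baseline_offset_x_m: float = 0.0
    reveal_latency_s: float = 0.217
    second_step: bool = False
    second_cop_bump_mm: float = 0.0

    @property
    def quiet(self) -> bool:
        """Degenerate quiet stance: no postural shift, no step."""
        return self.amp_lateral_m == 0.0

    @property
    def foot_off_nominal_s(self) -> float:
        return self.onset_time_s + _RISE_S + _UNLOAD_S

    @property
    def contact_nominal_s(self) -> float:
        return self.foot_off_nominal_s + self.swing_s

    @property
    def end_s(self) -> float:
        # both streams end on a common marker-period boundary
        raw = self.contact_nominal_s + _TAIL_S
        return float(np.ceil(raw * MARKER_RATE_HZ) / MARKER_RATE_HZ)


def _resolve_params(
    truth: ParticipantTruth,
    condition: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    failure: Optional[str],
) -> _TrialParams:
    interval = rng.uniform(1.0, 1.5)
    go = _FIXATION_S + interval
    reaction = float(np.clip(rng.normal(0.30, 0.03), 0.22, 0.40))
    amp_mm = rng.normal(condition_mean_mm(truth, condition), truth.sigma_k_mm)
    n_targets, side = condition.split("-", 1)
    post_mean = (
        config.posterior_dual_mm if n_targets == "dual" else config.posterior_single_mm
    )
    post_mm = max(rng.normal(post_mean, config.posterior_sd_mm), 5.0)
    swing = (
        _SWING_BASE_S
        + _MT_SLOPE_S_PER_MM * (_POSTERIOR_REF_MM - post_mm)
        + rng.normal(0.0, config.swing_jitter_s)
    )
    land_dx = {"lateral": _TARGET_SPACING_M, "center": 0.0, "medial": -_TARGET_SPACING_M}[
        side
    ]
    params = _TrialParams(
        go_time_s=go,
        onset_time_s=go + reaction,
        amp_lateral_m=max(amp_mm, 0.0) / 1000.0,
        amp_posterior_m=post_mm / 1000.0,
        swing_s=max(swing, 0.3),
        land_dx_m=land_dx,
        reveal_latency_s=config.reveal_latency_s,
    )
    if failure == "uneven_stance":
        params.baseline_offset_x_m = 0.02
    elif failure == "early_onset":
        # start just before the go cue: the onset rule still fires
        # pre-cue while the load split stays under 55% until after it,
        # so only the early-onset rule trips
        params.onset_time_s = go - 0.05
    elif failure == "abnormal_initial_direction":
        params.amp_lateral_m = -params.amp_lateral_m
    elif failure == "late_peak_reveal":
        params.reveal_latency_s = 0.0
    elif failure == "multiple_steps":
        params.second_step = True
    elif failure is not None:
        raise ConfigError(f"unknown failure mode {failure!r}")
    return params


def _cop_templates(t: np.ndarray, p: _TrialParams) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free global COP templates (meters) on time base ``t``."""
    if p.quiet:
        flat = np.full_like(t, p.baseline_offset_x_m)
        return flat, np.zeros_like(t)
    t0 = p.onset_time_s
    A = p.amp_lateral_m
    D = _STANCE_HALF_M
    t_peak = t0 + _RISE_S
    t_fo = p.foot_off_nominal_s
    x = np.zeros_like(t)
    x = np.where((t >= t0) & (t < t_peak), _segment(t, t0, _RISE_S, 0.0, A), x)
    x = np.where(
        (t >= t_peak) & (t < t_fo), _segment(t, t_peak, t_fo - t_peak, A, -D), x
    )
    x = np.where(t >= t_fo, -D, x)
    if p.second_cop_bump_mm:
        # optional extra lateral bump on the unloading limb of the curve,
        # larger than the initial peak, to exercise the initial-peak rule
        tb = t_peak + 0.08
        x = x + (p.second_cop_bump_mm / 1000.0) * _bump((t - tb) / 0.12)
    x = x + p.baseline_offset_x_m

    P = p.amp_posterior_m
    t_pp = t0 + _POSTERIOR_PEAK_S
    y = np.zeros_like(t)
    y = np.where((t >= t0) & (t < t_pp), _segment(t, t0, _POSTERIOR_PEAK_S, 0.0, -P), y)
    y = np.where(
        (t >= t_pp) & (t < t_fo), _segment(t, t_pp, t_fo - t_pp, -P, 0.015), y
    )
    y = np.where(t >= t_fo, 0.015, y)
    return x, y


def _marker_frames(tm: np.ndarray, p: _TrialParams, swing_side: str = "r"):
    """Noise-free marker trajectories (dict column -> array) at 100 Hz."""
    t_fo = p.foot_off_nominal_s
    t_fc = p.contact_nominal_s
    tau_sw = (tm - t_fo) / p.swing_s
    if p.quiet:
        tau_sw = np.full_like(tm, -1.0)  # foot never moves

    # swing-foot translation
    sx = p.land_dx_m * _smoothstep(tau_sw)
    sy = _TARGET_DISTANCE_M * _smoothstep(tau_sw)
    sz = _SWING_HEIGHT_M * _bump(tau_sw)
    if p.second_step:
        sz = sz + 0.04 * _bump((tm - (t_fc + 0.25)) / 0.30)

    # pelvis translation: lateral shift toward stance during the step,
    # forward progression bracketing the swing
    if p.quiet:
        px = np.zeros_like(tm)
        py = np.zeros_like(tm)
    else:
        px = _segment(tm, p.onset_time_s, t_fc - p.onset_time_s, 0.0, -0.04)
        py = _segment(tm, t_fo - 0.1, (t_fc + 0.2) - (t_fo - 0.1), 0.0, 0.16)

    cols: dict[str, np.ndarray] = {}
    for side in ("l", "r"):
        sgn = 1.0 if side == "r" else -1.0
        foot_x0 = sgn * _STANCE_HALF_M
        moving = side == swing_side
        for name, (ox, oy, oz) in _FOOT_MARKERS.items():
            base_x = foot_x0 + sgn * ox
            if moving:
                cols[f"{side}_{name}_x_m"] = base_x + sx
                cols[f"{side}_{name}_y_m"] = oy + sy
                cols[f"{side}_{name}_z_m"] = oz + sz
            else:
                cols[f"{side}_{name}_x_m"] = np.full_like(tm, base_x)
                cols[f"{side}_{name}_y_m"] = np.full_like(tm, oy)
                cols[f"{side}_{name}_z_m"] = np.full_like(tm, oz)
        for name, (ox, oy, oz) in _PELVIS_MARKERS.items():
            cols[f"{side}_{name}_x_m"] = sgn * ox + px
            cols[f"{side}_{name}_y_m"] = oy + py
            cols[f"{side}_{name}_z_m"] = np.full_like(tm, oz)
    return cols


def _derive_truth(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    fz1: np.ndarray,
    fz2: np.ndarray,
    tm: np.ndarray,
    mt2_z: np.ndarray,
    p: _TrialParams,
    body_weight_n: float,
    is_dual: bool,
) -> dict:
    """Apply the literal reference detectors to the noise-free trial."""
    dt = 1.0 / PLATE_RATE_HZ
    dtm = 1.0 / MARKER_RATE_HZ
    xf = lowpass(x, 20.0, PLATE_RATE_HZ)
    yf = lowpass(y, 20.0, PLATE_RATE_HZ)
    vx = central_velocity(xf, dt)
    zf = lowpass(mt2_z, 4.0, MARKER_RATE_HZ)
    vz = central_velocity(zf, dtm)

    truth: dict[str, object] = {
        "valid": True,
        "failure_mode": None,
        "reveal_time_s": None,
    }
    i_on = reference.scan_onset(list(vx), dt)
    if i_on is None:
        truth.update(
            valid=False,
            failure_mode="no_onset",
            onset_time_s=None,
            lateral_peak_time_s=None,
            posterior_peak_time_s=None,
            foot_off_time_s=None,
            foot_contact_time_s=None,
            lateral_disp_mm=None,
            posterior_disp_mm=None,
            movement_time_s=None,
        )
        return truth
    i_fo = reference.scan_sustained_above(list(vz), dtm, 0.02, 0.05)
    i_fc = reference.scan_foot_contact(list(vz), i_fo) if i_fo is not None else None
    t_on = float(t[i_on])
    truth["onset_time_s"] = t_on
    if i_fo is None or i_fc is None:
        truth.update(
            valid=False,
            failure_mode="no_step",
            lateral_peak_time_s=None,
            posterior_peak_time_s=None,
            foot_off_time_s=None,
            foot_contact_time_s=None,
            lateral_disp_mm=None,
            posterior_disp_mm=None,
            movement_time_s=None,
        )
        return truth
    t_fo = float(tm[i_fo])
    t_fc = float(tm[i_fc])
    i_fo_plate = int(np.searchsorted(t, t_fo))
    win_x = list(xf[i_on : i_fo_plate + 1])
    win_y = list(-yf[i_on : i_fo_plate + 1])
    i_lp = reference.scan_first_peak(win_x, 0.001)
    i_pp = reference.scan_first_peak(win_y, 0.001)
    truth.update(
        lateral_peak_time_s=float(t[i_on + i_lp]),
        posterior_peak_time_s=float(t[i_on + i_pp]),
        foot_off_time_s=t_fo,
        foot_contact_time_s=t_fc,
        lateral_disp_mm=abs(win_x[i_lp] - xf[i_on]) * 1000.0,
        posterior_disp_mm=abs(-win_y[i_pp] - yf[i_on]) * 1000.0,
        movement_time_s=t_fc - t_on,
    )
    if is_dual:
        cross = reference.scan_reveal_crossing(
            list(fz1), list(fz2), dt, p.go_time_s, float(t[0]), body_weight_n
        )
        truth["reveal_time_s"] = (
            None if cross is None else cross + p.reveal_latency_s
        )
    return truth


def gen_timeseries_trial(
    truth: ParticipantTruth,
    condition: str,
    seed,
    config: Optional[GeneratorConfig] = None,
    failure: Optional[str] = None,
    day: int = 1,
    amp_lateral_mm: Optional[float] = None,
    second_cop_bump_mm: float = 0.0,
) -> TrialRecording:
    """Render one synthetic trial as a full dual-plate/marker recording.

    ``seed`` fixes every output byte.  ``amp_lateral_mm`` overrides the
    drawn lateral excursion (useful for noise-free template checks);
    ``second_cop_bump_mm`` adds a late secondary lateral bump larger
    than the initial peak.  ``failure`` injects one of
    :data:`FAILURE_MODES`.
    """
    config = (config or GeneratorConfig()).validate()
    if condition not in (
        "single-lateral",
        "single-center",
        "single-medial",
        "dual-lateral",
        "dual-medial",
    ):
        raise ConfigError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    p = _resolve_params(truth, condition, config, rng, failure)
    if amp_lateral_mm is not None:
        p.amp_lateral_m = amp_lateral_mm / 1000.0
    p.second_cop_bump_mm = second_cop_bump_mm

    W = truth.body_weight_n
    n = int(round(p.end_s * PLATE_RATE_HZ)) + 1
    t = np.arange(n) / PLATE_RATE_HZ
    x, y = _cop_templates(t, p)
    D = _STANCE_HALF_M
    fz2 = W * np.clip(x + D, 0.0, 2 * D) / (2 * D)
    fz1 = W - fz2

    nm = int(round(p.end_s * MARKER_RATE_HZ)) + 1
    tm = np.arange(nm) / MARKER_RATE_HZ
    marker_cols = _marker_frames(tm, p)

    is_dual = condition.startswith("dual")
    truth_dict = _derive_truth(
        t, x, y, fz1, fz2, tm, marker_cols["r_mt2_z_m"], p, W, is_dual
    )
    truth_dict["amp_lateral_mm"] = p.amp_lateral_m * 1000.0
    truth_dict["amp_posterior_mm"] = p.amp_posterior_m * 1000.0
    if failure is not None:
        truth_dict["valid"] = False
        truth_dict["failure_mode"] = failure

    # observation noise
    fz1n = np.clip(fz1 + rng.normal(0.0, config.force_noise_n, n), 0.0, None)
    fz2n = np.clip(fz2 + rng.normal(0.0, config.force_noise_n, n), 0.0, None)
    plate = pd.DataFrame(
        {
            "time_s": t,
            "fz1_N": fz1n,
            "fz2_N": fz2n,
            "cop1_x_m": -D + rng.normal(0.0, config.cop_noise_m, n),
            "cop1_y_m": y + rng.normal(0.0, config.cop_noise_m, n),
            "cop2_x_m": D + rng.normal(0.0, config.cop_noise_m, n),
            "cop2_y_m": y + rng.normal(0.0, config.cop_noise_m, n),
        }
    )
    markers = pd.DataFrame({"time_s": tm})
    for col in marker_columns()[1:]:
        markers[col] = marker_cols[col] + rng.normal(0.0, config.marker_noise_m, nm)

    meta = TrialMeta(
        participant=truth.participant,
        day=day,
        condition=condition,
        cued_side=condition.split("-", 1)[1],
        go_time_s=p.go_time_s,
        target_onset_time_s=_FIXATION_S,
        body_weight_n=W,
        reveal_time_s=truth_dict.get("reveal_time_s"),
        swing_side="right",
        sim={
            "truth": truth_dict,
            "gen": {
                "participant_truth": asdict(truth),
                "condition": condition,
                "seed": int(np.random.SeedSequence(seed).entropy)
                if not isinstance(seed, (int, np.integer))
                else int(seed),
                "day": day,
                "config": asdict(config),
                "amp_lateral_mm": amp_lateral_mm,
                "second_cop_bump_mm": second_cop_bump_mm,
                "failure": failure,
            },
        },
    )
    return TrialRecording(plate=plate, markers=markers, meta=meta).validate()


def inject_failure(trial: TrialRecording, mode: str) -> TrialRecording:
    """Regenerate a synthetic trial with one failure mode injected.

    The returned trial must be caught by the QC rule named in
    :data:`FAILURE_TO_RULE`.  Only works on trials produced by
    :func:`gen_timeseries_trial` (their metadata carries the generator
    parameters)."""
    if mode not in FAILURE_MODES:
        raise ConfigError(f"unknown failure mode {mode!r}")
    if trial.meta.sim is None or "gen" not in trial.meta.sim:
        raise ConfigError("trial does not carry generator parameters")
    gen = trial.meta.sim["gen"]
    pt = gen["participant_truth"]
    truth = ParticipantTruth(**pt) if not isinstance(pt, ParticipantTruth) else pt
    cfg = gen["config"]
    config = GeneratorConfig(**cfg) if not isinstance(cfg, GeneratorConfig) else cfg
    return gen_timeseries_trial(
        truth,
        gen["condition"],
        gen["seed"],
        config=config,
        failure=mode,
        day=gen["day"],
        amp_lateral_mm=gen.get("amp_lateral_mm"),
        second_cop_bump_mm=gen.get("second_cop_bump_mm", 0.0),
    )
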