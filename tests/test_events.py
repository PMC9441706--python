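"""Event detectors, stability margins, and their invariants."""

import numpy as np
import pandas as pd
import pytest

import apastep as ap
from apastep.events import (
    NoStepError,
    count_unstable,
    detect_cop_onset,
    detect_events,
    detect_foot_events,
    find_initial_peaks,
    stability_margins,
)
from apastep.preprocess import CopTrace
from apastep.trial_io import TrialMeta, TrialRecording, marker_columns


def _trace_from_velocity(vx, dt=0.001):
    """Build a CopTrace with a prescribed mediolateral velocity."""
    vx = np.asarray(vx, dtype=float)
    t = np.arange(len(vx)) * dt
    x = np.concatenate([[0.0], np.cumsum(vx[:-1]) * dt])
    zeros = np.zeros_like(x)
    return CopTrace(time_s=t, cop_x_m=x, cop_y_m=zeros, vel_x_mps=vx, vel_y_mps=zeros)


def test_onset_on_sustained_velocity_step():
    vx = np.zeros(4000)
    vx[2000:2100] = 0.06  # 100 ms above threshold starting at t = 2.0 s
    onset = detect_cop_onset(_trace_from_velocity(vx))
    assert onset is not None
    assert onset.time_s == pytest.approx(2.0)
    assert onset.direction == "swing"


def test_onset_requires_sustained_interval():
    vx = np.zeros(4000)
    vx[2000:2030] = 0.06  # only 30 ms
    assert detect_cop_onset(_trace_from_velocity(vx)) is None


def test_onset_direction_toward_stance():
    vx = np.zeros(4000)
    vx[1000:1100] = -0.08
    onset = detect_cop_onset(_trace_from_velocity(vx))
    assert onset.direction == "stance"


def test_initial_peak_rule_prefers_first_bump(participants, noisefree_config):
    """With a later, larger secondary bump the first peak is kept."""
    trial = ap.gen_timeseries_trial(
        participants[0],
        "dual-medial",
        3,
        config=noisefree_config,
        amp_lateral_mm=40.0,
        second_cop_bump_mm=12.0,
    )
    ev = detect_events(trial)
    assert ev.lateral_disp_mm == pytest.approx(40.0, abs=0.7)
    # and the generator's own truth uses the same initial-peak rule
    assert ev.lateral_peak_time_s == pytest.approx(
        trial.meta.sim["truth"]["lateral_peak_time_s"], abs=1e-9
    )


def test_monotone_drift_peak_falls_back_to_window_end():
    n = 3000
    t = np.arange(n) * 0.001
    x = 0.02 * t  # monotone rise, no interior peak
    trace = CopTrace(
        time_s=t,
        cop_x_m=x,
        cop_y_m=np.zeros(n),
        vel_x_mps=np.full(n, 0.02),
        vel_y_mps=np.zeros(n),
    )
    onset = ap.events.OnsetResult(time_s=0.5, index=500, direction="swing")
    t_lat, _, d_lat, _ = find_initial_peaks(trace, onset, foot_off_time_s=2.0)
    assert t_lat == pytest.approx(2.0)
    assert d_lat == pytest.approx((x[2000] - x[500]) * 1000.0)


def test_foot_events_match_truth_within_one_marker_sample(
    participants, noisefree_config
):
    for s in range(3):
        trial = ap.gen_timeseries_trial(
            participants[s], "single-lateral", 600 + s, config=noisefree_config
        )
        fe = detect_foot_events(trial)
        tr = trial.meta.sim["truth"]
        assert fe.foot_off_time_s == pytest.approx(tr["foot_off_time_s"], abs=0.0101)
        assert fe.foot_contact_time_s == pytest.approx(
            tr["foot_contact_time_s"], abs=0.0101
        )
        assert not fe.multiple_steps


def test_flat_marker_trajectory_is_no_step(clean_trial):
    flat = clean_trial.markers.copy()
    for col in flat.columns:
        if col.endswith("_z_m"):
            flat[col] = flat[col].iloc[0]
        elif col != "time_s":
            flat[col] = flat[col].iloc[0]
    trial = TrialRecording(plate=clean_trial.plate, markers=flat, meta=clean_trial.meta)
    with pytest.raises(NoStepError):
        detect_foot_events(trial)


def _margin_trial(com_speed_mps=0.0, pelvis_z=1.0, contact_s=2.0):
    """Handcrafted trial: pelvis gliding at constant velocity, all feet
    flat, pendulum length exactly pelvis_z (heels at z = 0)."""
    n = 300
    t = np.arange(n) / 100.0
    cols = {"time_s": t}
    for col in marker_columns()[1:]:
        if col.endswith("_z_m"):
            cols[col] = np.full(n, pelvis_z if ("asis" in col or "psis" in col) else 0.0)
        elif "_y_m" in col and ("asis" in col or "psis" in col):
            cols[col] = com_speed_mps * t
        elif col == "r_toe_y_m":
            cols[col] = np.full(n, 0.445)
        elif col == "r_mt5_x_m":
            cols[col] = np.full(n, 0.145)
        else:
            cols[col] = np.zeros(n)
    markers = pd.DataFrame(cols)
    plate = pd.DataFrame(
        {
            "time_s": np.arange(3000) / 1000.0,
            "fz1_N": 294.0,
            "fz2_N": 294.0,
            "cop1_x_m": -0.1,
            "cop1_y_m": 0.0,
            "cop2_x_m": 0.1,
            "cop2_y_m": 0.0,
        }
    )
    meta = TrialMeta(
        participant="PX",
        day=1,
        condition="single-center",
        cued_side="center",
        go_time_s=1.0,
        target_onset_time_s=0.2,
        body_weight_n=588.0,
    )
    return TrialRecording(plate=plate, markers=markers, meta=meta), contact_s


def test_xcom_equals_com_at_zero_velocity():
    trial, tc = _margin_trial(com_speed_mps=0.0)
    m = stability_margins(trial, tc)
    assert m.xcom_xy_m[0] == pytest.approx(m.com_xy_m[0], abs=1e-6)
    assert m.xcom_xy_m[1] == pytest.approx(m.com_xy_m[1], abs=1e-6)


def test_xcom_offset_hand_computed():
    """v = 0.3131 m/s with L = 1 m shifts the XCOM by
    0.3131 * sqrt(1 / 9.81) = 0.100 m ahead of the COM."""
    trial, tc = _margin_trial(com_speed_mps=0.3131, pelvis_z=1.0)
    m = stability_margins(trial, tc)
    assert m.pendulum_length_m == pytest.approx(1.0, abs=1e-6)
    offset = m.xcom_xy_m[1] - m.com_xy_m[1]
    assert offset == pytest.approx(0.100, abs=0.001)


def test_mos_zero_at_boundary():
    trial, tc = _margin_trial(com_speed_mps=0.0)
    # place the fifth-metatarsal marker exactly on the XCOM lateral line
    trial.markers["r_mt5_x_m"] = 0.0  # XCOM_x = COM_x = 0 here
    m = stability_margins(trial, tc)
    assert m.mos_ml_mm == pytest.approx(0.0, abs=1e-6)
    assert not m.unstable


def test_missing_pelvis_marker_rejected():
    trial, tc = _margin_trial()
    trial.markers.drop(columns=["l_asis_x_m"], inplace=True)
    with pytest.raises(ValueError, match="l_asis_x_m"):
        stability_margins(trial, tc)


def test_detected_lateral_disp_increases_with_amplitude(
    participants, noisefree_config
):
    disps = []
    for amp in (30.0, 35.0, 40.0, 45.0):
        trial = ap.gen_timeseries_trial(
            participants[0],
            "single-center",
            77,
            config=noisefree_config,
            amp_lateral_mm=amp,
        )
        disps.append(detect_events(trial).lateral_disp_mm)
    assert all(b > a for a, b in zip(disps, disps[1:]))


def test_mos_ml_decreases_for_medial_landing(participants, noisefree_config):
    values = {}
    for cond in ("single-lateral", "single-center", "single-medial"):
        trial = ap.gen_timeseries_trial(
            participants[0], cond, 55, config=noisefree_config
        )
        ev = detect_events(trial)
        m = stability_margins(trial, ev.foot_contact_time_s)
        values[cond] = m.mos_ml_mm
    assert values["single-medial"] < values["single-center"] < values["single-lateral"]


def test_count_unstable_strict_inequality():
    df = pd.DataFrame(
        {
            "participant": ["P1"] * 3,
            "n_targets": ["single"] * 3,
            "side": ["medial"] * 3,
            "mos_ml_mm": [5.0, 0.0, -2.0],
        }
    )
    out = count_unstable(df)
    assert out["n_unstable"].iloc[0] == 1  # exactly zero does not count


def test_movement_time_is_contact_minus_onset(clean_trial):
    ev = detect_events(clean_trial)
    assert ev.movement_time_s == pytest.approx(
        ev.foot_contact_time_s - ev.onset_time_s
    )
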