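"""Repeated-measures ANOVA, effect sizes, normalization, power,
trial-wise regression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as ss

from apastep.stats import (
    DegenerateDataError,
    normalize_dual,
    one_sample_t,
    partial_eta_sq,
    rm_anova,
    simple_main_effects,
    t_power,
    trialwise_regression,
)


def _random_table(seed, n=13):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n):
        base = rng.normal(40, 4)
        for nt in ("single", "dual"):
            for side in ("lateral", "medial"):
                rows.append(
                    {
                        "participant": f"P{p:02d}",
                        "n_targets": nt,
                        "side": side,
                        "y": base
                        + (3 if nt == "dual" else 0)
                        + (6 if side == "medial" else 0)
                        + rng.normal(0, 2),
                    }
                )
    return pd.DataFrame(rows)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_two_level_factor_f_equals_squared_paired_t(seed):
    df = _random_table(seed)
    aov = rm_anova(df, "y", ["n_targets", "side"])
    cells = df.groupby(["participant", "n_targets"])["y"].mean().unstack()
    t, _ = ss.ttest_rel(cells["single"], cells["dual"])
    F = aov.loc[aov["effect"] == "n_targets", "F"].iloc[0]
    assert F == pytest.approx(t**2, abs=1e-9)
    # interaction contrast oracle
    wide = df.set_index(["participant", "n_targets", "side"])["y"].unstack(
        ["n_targets", "side"]
    )
    inter = (
        wide[("single", "lateral")]
        - wide[("single", "medial")]
        - wide[("dual", "lateral")]
        + wide[("dual", "medial")]
    )
    t_i = inter.mean() / (inter.std(ddof=1) / np.sqrt(len(inter)))
    F_i = aov.loc[aov["effect"] == "n_targets:side", "F"].iloc[0]
    assert F_i == pytest.approx(t_i**2, abs=1e-9)


def test_permuting_participant_labels_leaves_f_unchanged():
    df = _random_table(5)
    aov1 = rm_anova(df, "y", ["n_targets", "side"])
    relabel = {f"P{p:02d}": f"Q{12 - p:02d}" for p in range(13)}
    df2 = df.assign(participant=df["participant"].map(relabel))
    aov2 = rm_anova(df2, "y", ["n_targets", "side"])
    np.testing.assert_allclose(aov1["F"], aov2["F"], atol=1e-9)


def test_constant_nonzero_differences_give_infinite_f():
    rows = []
    for p in range(6):
        base = 30 + p
        rows.append({"participant": p, "n_targets": "single", "side": "x", "y": base})
        rows.append({"participant": p, "n_targets": "dual", "side": "x", "y": base + 5})
    df = pd.DataFrame(rows)
    aov = rm_anova(df, "y", ["n_targets"])
    row = aov.iloc[0]
    assert math.isinf(row["F"]) and row["degenerate"]
    assert row["eta_p2"] == 1.0


def test_missing_cells_rejected():
    df = _random_table(0)
    df = df[~((df["participant"] == "P00") & (df["side"] == "medial"))]
    with pytest.raises(DegenerateDataError, match="P00"):
        rm_anova(df, "y", ["n_targets", "side"])


def test_three_way_anova_runs_with_day_factor():
    rng = np.random.default_rng(8)
    rows = []
    for p in range(8):
        for day in (1, 2):
            for nt in ("single", "dual"):
                for side in ("lateral", "medial"):
                    rows.append(
                        {
                            "participant": p,
                            "day": day,
                            "n_targets": nt,
                            "side": side,
                            "y": rng.normal(40, 3),
                        }
                    )
    aov = rm_anova(pd.DataFrame(rows), "y", ["day", "n_targets", "side"])
    assert len(aov) == 7  # 3 mains + 3 two-way + 1 three-way
    assert (aov["df2"] == 7).all()
    assert (aov["gg_epsilon"] == 1.0).all()


def test_simple_main_effects_equal_stratum_paired_t():
    df = _random_table(3)
    sme = simple_main_effects(df, "y", "n_targets", {"side": "medial"})
    cells = (
        df[df["side"] == "medial"]
        .groupby(["participant", "n_targets"])["y"]
        .mean()
        .unstack()
    )
    t, _ = ss.ttest_rel(cells["dual"], cells["single"])
    assert sme["F"].iloc[0] == pytest.approx(t**2, abs=1e-9)


def test_partial_eta_sq_identity_and_limits():
    assert partial_eta_sq(0.0, 1, 12) == 0.0
    f = 26.33
    eta = partial_eta_sq(f, 1, 12)
    assert eta == pytest.approx(f / (f + 12))
    assert partial_eta_sq(math.inf, 1, 12) == 1.0


@given(st.floats(0.0, 1e4), st.integers(1, 5), st.integers(2, 100))
def test_partial_eta_sq_bounded(F, df1, df2):
    eta = partial_eta_sq(F, df1, df2)
    assert 0.0 <= eta <= 1.0


def _norm_table():
    rows = []
    for p, (msl, msm) in enumerate([(30.0, 45.0), (28.0, 44.0)]):
        for v in (msl, msl):
            rows.append(
                {"participant": p, "n_targets": "single", "side": "lateral",
                 "lateral_disp_mm": v}
            )
        for v in (msm, msm):
            rows.append(
                {"participant": p, "n_targets": "single", "side": "medial",
                 "lateral_disp_mm": v}
            )
        mid = (msl + msm) / 2
        for v in (msm, mid, msl):
            rows.append(
                {"participant": p, "n_targets": "dual", "side": "medial",
                 "lateral_disp_mm": v}
            )
    return pd.DataFrame(rows)


def test_normalization_anchors():
    """m_SM -> +1, midpoint -> 0, m_SL -> -1; their mean is 0."""
    out = normalize_dual(_norm_table())
    np.testing.assert_allclose(out["norm_mean"], 0.0, atol=1e-12)
    one = _norm_table()
    one = one[~((one["n_targets"] == "dual") & (one["lateral_disp_mm"] < 40))]
    out_m = normalize_dual(one)  # only the m_SM dual trials remain
    np.testing.assert_allclose(out_m["norm_mean"], 1.0, atol=1e-12)


def test_normalization_unit_invariance():
    df = _random_table(11).rename(columns={"y": "lateral_disp_mm"})
    a = normalize_dual(df)
    df_m = df.assign(lateral_disp_mm=df["lateral_disp_mm"] / 1000.0)  # mm -> m
    b = normalize_dual(df_m)
    np.testing.assert_allclose(a["norm_mean"], b["norm_mean"], atol=1e-12)


def test_normalization_zero_denominator_rejected():
    df = _norm_table()
    df.loc[df["side"] == "medial", "lateral_disp_mm"] = 30.0
    df.loc[df["n_targets"] == "single", "lateral_disp_mm"] = 30.0
    with pytest.raises(DegenerateDataError):
        normalize_dual(df)


def test_one_sample_t_symmetric_values():
    res = one_sample_t([1.0, -1.0, 2.0, -2.0], 0.0)
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_one_sample_t_hand_formula():
    x = np.array([0.8, 1.1, 0.9, 1.3, 0.7])
    res = one_sample_t(x, 0.0)
    sd = x.std(ddof=1)
    assert res.t == pytest.approx(x.mean() / (sd / np.sqrt(5)))
    assert res.df == 4
    assert res.d == pytest.approx(abs(res.t) / np.sqrt(5))


def test_one_sample_t_zero_variance_rejected():
    with pytest.raises(DegenerateDataError):
        one_sample_t([2.0, 2.0, 2.0], 0.0)


def test_power_at_zero_effect_equals_alpha():
    assert t_power(0.0, 13, 0.05) == pytest.approx(0.05, abs=1e-6)


def test_power_monotone_in_effect_and_sample_size():
    ds = [0.2, 0.4, 0.8, 1.2]
    powers = [t_power(d, 13) for d in ds]
    assert all(b > a for a, b in zip(powers, powers[1:]))
    ns = [5, 10, 20, 40]
    powers_n = [t_power(0.5, n) for n in ns]
    assert all(b > a for a, b in zip(powers_n, powers_n[1:]))


def test_regression_exact_line():
    rows = []
    for x in (10.0, 20.0, 30.0, 40.0):
        rows.append(
            {"participant": "P1", "posterior_disp_mm": x,
             "movement_time_s": -0.005 * x + 1.2}
        )
    out = trialwise_regression(pd.DataFrame(rows))
    assert out["slope"].iloc[0] == pytest.approx(-0.005)
    assert out["intercept"].iloc[0] == pytest.approx(1.2)
    assert out["r2"].iloc[0] == pytest.approx(1.0)


def test_regression_recovers_slope_on_noisy_trials():
    rng = np.random.default_rng(2)
    rows = []
    for p in range(5):
        for _ in range(60):
            x = rng.normal(30, 5)
            rows.append(
                {"participant": p, "posterior_disp_mm": x,
                 "movement_time_s": 1.2 - 0.005 * x + rng.normal(0, 0.02)}
            )
    out = trialwise_regression(pd.DataFrame(rows))
    se = 0.02 / (5 * np.sqrt(60))
    assert np.all(np.abs(out["slope"] + 0.005) < 4 * se * 10)
    assert (out["slope"] < 0).all()


def test_regression_constant_predictor_rejected():
    rows = [
        {"participant": "P1", "posterior_disp_mm": 20.0, "movement_time_s": v}
        for v in (1.0, 1.1, 1.2)
    ]
    with pytest.raises(DegenerateDataError, match="constant"):
        trialwise_regression(pd.DataFrame(rows))
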