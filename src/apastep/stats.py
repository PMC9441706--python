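"""Frequentist analyses of the cohort table.

Repeated-measures ANOVA (all within-subject factors here have two
levels, where the Greenhouse-Geisser epsilon is identically 1 and
sphericity is vacuous), partial eta-squared effect sizes, simple main
effects with stratum-specific error terms, the dual-condition
normalization transform, one-sample t-tests with Cohen's d and
noncentral-t power, and the per-participant trial-wise regression of
movement time on posterior COP displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.anova import AnovaRM


class DegenerateDataError(ValueError):
    pass


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta-squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    if math.isinf(F):
        return 1.0
    return F * df1 / (F * df1 + df2)


def _cell_means(
    table: pd.DataFrame, dv: str, within: list[str], subject: str
) -> pd.DataFrame:
    """Average trials to one value per subject x cell; check balance."""
    cells = table.groupby([subject] + within, as_index=False)[dv].mean()
    n_levels = int(np.prod([cells[f].nunique() for f in within]))
    counts = cells.groupby(subject).size()
    if (counts != n_levels).any():
        bad = counts[counts != n_levels].index.tolist()
        raise DegenerateDataError(f"missing cells for subject(s) {bad}")
    return cells


def _effect_contrast(
    cells: pd.DataFrame, dv: str, effect: tuple[str, ...], within: list[str], subject: str
) -> np.ndarray:
    """Per-subject contrast scores for a (possibly interaction) effect
    in an all-two-level within design; used to flag zero-error strata."""
    df = cells.copy()
    sign = np.ones(len(df))
    for f in effect:
        levels = sorted(df[f].unique())
        sign *= np.where(df[f] == levels[0], 1.0, -1.0)
    df["_signed"] = df[dv] * sign
    return df.groupby(subject)["_signed"].mean().to_numpy()


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """Fully within-subject repeated-measures ANOVA on cell means.

    Trials are averaged within subject x cell first.  Returns one row
    per effect with F, dfs, p, partial eta-squared, and the (trivial)
    Greenhouse-Geisser epsilon.  A zero-variance contrast (all
    subjects show the identical nonzero difference) yields an infinite
    F with the ``degenerate`` flag instead of an error.
    """
    cells = _cell_means(table, dv, within, subject)
    effects: list[tuple[str, ...]] = []
    for r in range(1, len(within) + 1):
        from itertools import combinations

        effects.extend(combinations(within, r))

    degenerate = {}
    n = cells[subject].nunique()
    for eff in effects:
        c = _effect_contrast(cells, dv, eff, within, subject)
        if np.var(c, ddof=1) < 1e-24 * max(1.0, np.mean(np.abs(c)) ** 2):
            degenerate[eff] = float(np.mean(c))

    rows = []
    if len(degenerate) < len(effects):
        res = AnovaRM(
            data=cells, depvar=dv, subject=subject, within=list(within)
        ).fit()
        aov = res.anova_table
    else:
        aov = None
    for eff in effects:
        name = ":".join(eff)
        if eff in degenerate:
            mean_c = degenerate[eff]
            F = math.inf if abs(mean_c) > 0 else 0.0
            df1, df2 = 1.0, float(n - 1)
            p = 0.0 if math.isinf(F) else 1.0
            flag = True
        else:
            key = name if name in aov.index else ":".join(reversed(eff))
            row = aov.loc[key]
            F = float(row["F Value"])
            df1 = float(row["Num DF"])
            df2 = float(row["Den DF"])
            p = float(row["Pr > F"])
            flag = False
        rows.append(
            {
                "effect": name,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "eta_p2": partial_eta_sq(F, df1, df2),
                "gg_epsilon": 1.0,
                "degenerate": flag,
            }
        )
    return pd.DataFrame(rows)


def simple_main_effects(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    at: dict[str, object],
    subject: str = "participant",
) -> pd.DataFrame:
    """One-factor within-subject ANOVA of ``factor`` at fixed levels of
    the other factor(s), using each stratum's own error term."""
    sub = table.copy()
    label = {}
    for col, level in at.items():
        sub = sub[sub[col] == level]
        label[col] = level
    if sub.empty:
        raise DegenerateDataError(f"no rows at {at}")
    out = rm_anova(sub, dv, [factor], subject)
    out.insert(0, "at", [";".join(f"{k}={v}" for k, v in label.items())] * len(out))
    return out


def normalize_dual(
    table: pd.DataFrame,
    dv: str = "lateral_disp_mm",
    subject: str = "participant",
) -> pd.DataFrame:
    """Normalize pooled dual-condition values per participant.

    With m_SL and m_SM the participant's single-lateral and
    single-medial condition means and mid = (m_SL + m_SM)/2, each
    pooled dual value x maps to (x - mid) / (m_SM - mid), so the scale
    anchors m_SL -> -1, mid -> 0, m_SM -> +1.  Returns one row per
    participant with the mean normalized value.  The transform is
    invariant to affine rescaling of the displacement unit.
    """
    rows = []
    for pid, grp in table.groupby(subject):
        m_sl = grp.loc[
            (grp["n_targets"] == "single") & (grp["side"] == "lateral"), dv
        ].mean()
        m_sm = grp.loc[
            (grp["n_targets"] == "single") & (grp["side"] == "medial"), dv
        ].mean()
        dual = grp.loc[grp["n_targets"] == "dual", dv].to_numpy()
        if np.isnan(m_sl) or np.isnan(m_sm) or dual.size == 0:
            raise DegenerateDataError(f"participant {pid}: missing condition data")
        mid = 0.5 * (m_sl + m_sm)
        denom = m_sm - mid
        if denom == 0:
            raise DegenerateDataError(
                f"participant {pid}: single-condition means coincide"
            )
        rows.append({subject: pid, "norm_mean": float(((dual - mid) / denom).mean())})
    return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    power: float


def t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided one-sample power at effect size ``d`` via the
    noncentral t distribution (noncentrality d*sqrt(n), df n-1)."""
    if n < 2 or d < 0:
        raise ValueError("need n >= 2 and d >= 0")
    df = n - 1
    nc = d * math.sqrt(n)
    tc = sstats.t.ppf(1 - alpha / 2, df)
    # the far lower tail underflows to nan at large noncentrality,
    # where its true value is negligible
    upper = np.nan_to_num(sstats.nct.sf(tc, df, nc), nan=0.0)
    lower = np.nan_to_num(sstats.nct.cdf(-tc, df, nc), nan=0.0)
    return float(upper + lower)


def one_sample_t(values, mu0: float, alpha: float = 0.05) -> TTestResult:
    """Two-sided one-sample t-test with Cohen's d (= |t|/sqrt(n)) and
    post-hoc power at the observed d."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance")
    res = sstats.ttest_1samp(x, mu0)
    d = abs(x.mean() - mu0) / sd
    return TTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        d=float(d),
        power=t_power(d, n, alpha),
    )


def trialwise_regression(
    table: pd.DataFrame,
    x: str = "posterior_disp_mm",
    y: str = "movement_time_s",
    subject: str = "participant",
) -> pd.DataFrame:
    """Per-participant OLS of ``y`` on ``x`` over trials.

    Returns slope, intercept, two-sided p for the slope, and R^2, plus
    a cohort-wide summary of slope signs is left to the caller.
    Raises on a constant predictor."""
    rows = []
    for pid, grp in table.groupby(subject):
        xv = grp[x].to_numpy(dtype=float)
        yv = grp[y].to_numpy(dtype=float)
        if xv.size < 3:
            raise DegenerateDataError(f"participant {pid}: fewer than 3 trials")
        if np.ptp(xv) == 0:
            raise DegenerateDataError(f"participant {pid}: constant predictor")
        res = sstats.linregress(xv, yv)
        rows.append(
            {
                subject: pid,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "p": float(res.pvalue),
                "r2": float(res.rvalue**2),
                "n": int(xv.size),
            }
        )
    return pd.DataFrame(rows)
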