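"""End-to-end orchestration: generate -> preprocess -> events -> qc ->
stats -> bayes, with a structured, machine-readable report.

Every stage threshold lives in :class:`PipelineConfig` with the
analysis defaults; the report bundles QC counts, per-condition means
with standard errors for all five dependent variables, ANOVA tables,
the dual-condition normalization t-tests with power, per-participant
regression slopes, and the hierarchical posterior with strategy
labels.  A fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import bayes, events, qc, stats
from .synthetic import GeneratorConfig, gen_participants, gen_timeseries_trial
from .preprocess import cop_trace
from .trial_io import COHORT_COLUMNS, TrialRecording, write_cohort

log = logging.getLogger("apastep")


@dataclass
class PipelineConfig:
    """All module thresholds plus generator settings and the seed."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    plate_cutoff_hz: float = 20.0
    marker_cutoff_hz: float = 4.0
    filter_order: int = 4
    onset_threshold_mps: float = 0.05
    sustain_s: float = 0.05
    contact_threshold_mps: float = 0.02
    peak_prominence_m: float = 0.001
    trigger_frac: float = 0.10
    uneven_load_frac: float = 0.55
    reveal_latency_s: float = 0.217
    alpha_level: float = 0.05
    chains: int = 4
    mcmc_iterations: int = 3_500
    mcmc_warmup: int = 1_000
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.generator.validate()
        for name in (
            "plate_cutoff_hz",
            "marker_cutoff_hz",
            "onset_threshold_mps",
            "sustain_s",
            "contact_threshold_mps",
            "peak_prominence_m",
            "trigger_frac",
            "uneven_load_frac",
            "reveal_latency_s",
            "alpha_level",
        ):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and trial id."""

    def __init__(self, stage: str, trial_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on trial {trial_id!r}: {cause}")
        self.stage = stage
        self.trial_id = trial_id


def process_trial(
    trial: TrialRecording, config: PipelineConfig
) -> tuple[Optional[events.CopEvents], qc.TrialVerdict, Optional[events.StabilityMargins]]:
    """Preprocess, detect and judge one trial."""
    thresholds = qc.QcThresholds(
        uneven_load_frac=config.uneven_load_frac,
        trigger_frac=config.trigger_frac,
        reveal_latency_s=config.reveal_latency_s,
        direction_window_s=config.sustain_s,
    )
    trace = cop_trace(trial, config.plate_cutoff_hz, config.filter_order)
    try:
        ev = events.detect_events(
            trial,
            trace,
            onset_threshold_mps=config.onset_threshold_mps,
            sustain_s=config.sustain_s,
            contact_threshold_mps=config.contact_threshold_mps,
            prominence_m=config.peak_prominence_m,
        )
    except events.NoStepError:
        verdict = qc.TrialVerdict(failed_rules=["no_step"])
        return None, verdict, None
    reveal = None
    if trial.meta.n_targets == "dual" and trial.meta.reveal_time_s is None:
        reveal = qc.reveal_time(trial, trial.meta.body_weight_n, thresholds)
    verdict = qc.judge_trial(trial, ev, reveal, trace, thresholds)
    margins = None
    if ev is not None and verdict.valid:
        margins = events.stability_margins(
            trial, ev.foot_contact_time_s, config.marker_cutoff_hz
        )
    return ev, verdict, margins


def build_cohort(
    trials: list[TrialRecording], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run detection and QC over trials; return (cohort table of valid
    trials, QC ledger with one row per trial)."""
    rows, ledger = [], []
    for i, trial in enumerate(trials):
        trial_id = f"{trial.meta.participant}/{trial.meta.condition}/{i}"
        try:
            ev, verdict, margins = process_trial(trial, config)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("process", trial_id, exc) from exc
        ledger.append(
            {
                "trial": trial_id,
                "participant": trial.meta.participant,
                "condition": trial.meta.condition,
                "valid": verdict.valid,
                "failed_rules": ",".join(verdict.failed_rules),
            }
        )
        if verdict.valid and ev is not None and margins is not None:
            rows.append(
                {
                    "participant": trial.meta.participant,
                    "day": trial.meta.day,
                    "n_targets": trial.meta.n_targets,
                    "side": trial.meta.side,
                    "lateral_disp_mm": ev.lateral_disp_mm,
                    "posterior_disp_mm": ev.posterior_disp_mm,
                    "mos_ml_mm": margins.mos_ml_mm,
                    "mos_ap_mm": margins.mos_ap_mm,
                    "movement_time_s": ev.movement_time_s,
                }
            )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return cohort, pd.DataFrame(ledger)


def generate_cohort_trials(config: PipelineConfig) -> list[TrialRecording]:
    """Render the full synthetic cohort as time-series recordings."""
    gen = config.generator
    rng = np.random.default_rng(gen.seed)
    participants = gen_participants(gen, rng)
    ss = np.random.SeedSequence(config.seed)
    conditions = (
        "single-lateral",
        "single-center",
        "single-medial",
        "dual-lateral",
        "dual-medial",
    )
    n_seeds = len(participants) * len(conditions) * gen.trials_per_condition
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_seeds)]
    trials = []
    i = 0
    for truth in participants:
        for condition in conditions:
            for j in range(gen.trials_per_condition):
                trials.append(
                    gen_timeseries_trial(
                        truth,
                        condition,
                        child_seeds[i],
                        config=gen,
                        day=1 + (j % 2),
                    )
                )
                i += 1
    return trials


def _anova_section(cohort: pd.DataFrame, dv: str) -> dict:
    """Two-way (number of targets x stepping side) RM-ANOVA on the
    lateral/medial cells, plus simple main effects of the interaction."""
    two = cohort[cohort["side"].isin(["lateral", "medial"])]
    aov = stats.rm_anova(two, dv, ["n_targets", "side"])
    section = {"anova": aov.to_dict(orient="records"), "simple_main_effects": []}
    for col, other in (("n_targets", "side"), ("side", "n_targets")):
        for level in sorted(two[col].unique()):
            sme = stats.simple_main_effects(two, dv, other, {col: level})
            section["simple_main_effects"].extend(sme.to_dict(orient="records"))
    return section


def _condition_means(cohort: pd.DataFrame) -> list[dict]:
    out = []
    dvs = [
        "lateral_disp_mm",
        "posterior_disp_mm",
        "mos_ml_mm",
        "mos_ap_mm",
        "movement_time_s",
    ]
    per_subj = cohort.groupby(["participant", "n_targets", "side"], as_index=False)[
        dvs
    ].mean()
    for (n_targets, side), grp in per_subj.groupby(["n_targets", "side"]):
        row = {"n_targets": n_targets, "side": side, "n_participants": len(grp)}
        for dv in dvs:
            row[f"{dv}_mean"] = float(grp[dv].mean())
            row[f"{dv}_se"] = float(grp[dv].std(ddof=1) / np.sqrt(len(grp)))
        out.append(row)
    return out


def run(
    config: PipelineConfig,
    trials: Optional[list[TrialRecording]] = None,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run the full analysis and return the report bundle.

    ``trials`` defaults to a freshly generated synthetic cohort.  When
    ``out_dir`` is given, ``report.json``, ``report.md``, ``cohort.tsv``
    and ``qc.tsv`` are written there.
    """
    config.validate()
    if trials is None:
        log.info("generating synthetic cohort (%d participants)",
                 config.generator.n_participants)
        trials = generate_cohort_trials(config)
    log.info("processing %d trials", len(trials))
    cohort, ledger = build_cohort(trials, config)
    if cohort.empty:
        raise StageError("cohort", "-", ValueError("no valid trials"))

    qc_counts = (
        ledger.groupby(["condition", "valid"]).size().unstack(fill_value=0)
    )
    report: dict = {
        "config": asdict(config),
        "qc": {
            "n_trials": int(len(ledger)),
            "n_valid": int(ledger["valid"].sum()),
            "per_condition": {
                cond: {
                    "valid": int(qc_counts.loc[cond].get(True, 0)),
                    "excluded": int(qc_counts.loc[cond].get(False, 0)),
                }
                for cond in qc_counts.index
            },
        },
        "condition_means": _condition_means(cohort),
        "anova": {},
    }
    for dv in (
        "lateral_disp_mm",
        "posterior_disp_mm",
        "mos_ml_mm",
        "mos_ap_mm",
        "movement_time_s",
    ):
        log.info("ANOVA: %s", dv)
        report["anova"][dv] = _anova_section(cohort, dv)

    log.info("normalization t-tests")
    norm = stats.normalize_dual(cohort)
    t_vs_mid = stats.one_sample_t(norm["norm_mean"], 0.0, config.alpha_level)
    t_vs_medial = stats.one_sample_t(norm["norm_mean"], 1.0, config.alpha_level)
    report["normalization"] = {
        "per_participant": norm.to_dict(orient="records"),
        "vs_intermediate": asdict(t_vs_mid),
        "vs_single_medial": asdict(t_vs_medial),
    }

    log.info("trial-wise regression")
    reg_pool = cohort[cohort["side"].isin(["lateral", "medial"])]
    reg = stats.trialwise_regression(reg_pool)
    report["regression"] = {
        "per_participant": reg.to_dict(orient="records"),
        "n_negative_slopes": int((reg["slope"] < 0).sum()),
        "n_significant": int(((reg["p"] < config.alpha_level) & (reg["slope"] < 0)).sum()),
    }

    log.info("unstable-trial counts")
    unstable = events.count_unstable(cohort)
    report["unstable_counts"] = unstable.to_dict(orient="records")

    log.info("hierarchical Bayesian fit")
    model = bayes.HierarchicalModel.from_cohort(cohort)
    posterior = bayes.fit(
        model,
        chains=config.chains,
        iterations=config.mcmc_iterations,
        warmup=config.mcmc_warmup,
        seed=config.seed,
    )
    labels = bayes.classify_strategy(posterior)
    group_theta = posterior.draws["theta_group"].reshape(-1)
    group_mean = float(group_theta.mean())
    report["bayes"] = {
        "converged": posterior.converged,
        "max_rhat": posterior.max_rhat,
        "group_theta": {
            "mean": group_mean,
            "median": float(np.median(group_theta)),
            "ci_low": float(np.percentile(group_theta, 2.5)),
            "ci_high": float(np.percentile(group_theta, 97.5)),
        },
        "group_label": (
            "medial"
            if group_mean >= 2 / 3
            else "lateral" if group_mean <= 1 / 3 else "intermediate"
        ),
        "participants": labels.to_dict(orient="records"),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out_dir / "cohort.tsv")
        ledger.to_csv(out_dir / "qc.tsv", sep="\t", index=False)
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        (out_dir / "report.md").write_text(render_markdown(report), encoding="utf-8")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def render_markdown(report: dict) -> str:
    """Human-readable digest of the report bundle."""
    lines = ["# Stepping-cohort analysis report", ""]
    qc_sec = report["qc"]
    lines.append(
        f"Trials: {qc_sec['n_trials']} total, {qc_sec['n_valid']} valid after QC."
    )
    lines.append("")
    lines.append("## Condition means (participant-level mean +/- SE)")
    for row in report["condition_means"]:
        lines.append(
            f"- {row['n_targets']}-{row['side']}: lateral COP "
            f"{row['lateral_disp_mm_mean']:.1f} +/- {row['lateral_disp_mm_se']:.1f} mm, "
            f"posterior {row['posterior_disp_mm_mean']:.1f} mm, "
            f"movement time {row['movement_time_s_mean']:.3f} s"
        )
    lines.append("")
    lines.append("## Dual-condition normalization")
    vi = report["normalization"]["vs_intermediate"]
    vm = report["normalization"]["vs_single_medial"]
    lines.append(
        f"- vs intermediate (mu0=0): t({vi['df']}) = {vi['t']:.2f}, p = {vi['p']:.3g}, "
        f"d = {vi['d']:.2f}, power = {vi['power']:.2f}"
    )
    lines.append(
        f"- vs single-medial (mu0=1): t({vm['df']}) = {vm['t']:.2f}, p = {vm['p']:.3g}, "
        f"d = {vm['d']:.2f}, power = {vm['power']:.2f}"
    )
    lines.append("")
    b = report["bayes"]
    lines.append("## Hierarchical weighting estimates")
    lines.append(
        f"- group theta: mean {b['group_theta']['mean']:.3f} "
        f"[{b['group_theta']['ci_low']:.3f}, {b['group_theta']['ci_high']:.3f}], "
        f"label: {b['group_label']}, max split R-hat {b['max_rhat']:.3f}"
    )
    n_med = sum(1 for p in b["participants"] if p["label"] == "medial")
    lines.append(
        f"- participants: {n_med}/{len(b['participants'])} medial weighting"
    )
    lines.append("")
    return "\n".join(lines)
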