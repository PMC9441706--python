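"""On-disk trial format, schema validation, and stream synchronization.

A recorded stepping trial is stored as a plain-text triplet:

``<stem>.plate.tsv``
    Force-plate stream at 1,000 Hz: ``time_s``, per-plate vertical force
    (``fz1_N`` = stance/left plate, ``fz2_N`` = swing/right plate) and
    per-plate center of pressure in meters.
``<stem>.markers.tsv``
    Motion-capture stream at 100 Hz: ``time_s`` plus 14 lower-body
    markers x 3 axes (second-toe top, first/second/fifth metatarsal,
    heel, ASIS, PSIS; bilateral), all in meters.
``<stem>.meta.json``
    Trial metadata (participant, day, condition, cue times, body weight).

Coordinate convention: +x toward the participant's right (the swing-foot
side), +y anterior, +z up; origin at the midpoint between the feet at
trial start.  Meters internally, millimeters in reports.  Time is seconds
from recording start; intervals are half-open ``[start, end)``.

The format is deliberately vendor-free (no C3D): tab-separated, header
row, decimal point, UTF-8, so trials stay diffable and text-only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

PLATE_RATE_HZ = 1000.0
MARKER_RATE_HZ = 100.0

#: marker short names; bilateral ("l_"/"r_" prefixes) in files
MARKER_NAMES = ("toe", "mt1", "mt2", "mt5", "heel", "asis", "psis")
MARKER_SIDES = ("l", "r")

PLATE_COLUMNS = [
    "time_s",
    "fz1_N",
    "fz2_N",
    "cop1_x_m",
    "cop1_y_m",
    "cop2_x_m",
    "cop2_y_m",
]

CONDITIONS = (
    "single-lateral",
    "single-center",
    "single-medial",
    "dual-lateral",
    "dual-medial",
)

#: columns of the cohort-level table of per-trial dependent variables
COHORT_COLUMNS = [
    "participant",
    "day",
    "n_targets",
    "side",
    "lateral_disp_mm",
    "posterior_disp_mm",
    "mos_ml_mm",
    "mos_ap_mm",
    "movement_time_s",
]


def marker_columns() -> list[str]:
    """Column order of the marker TSV: time plus side_marker_axis_m."""
    cols = ["time_s"]
    for side in MARKER_SIDES:
        for name in MARKER_NAMES:
            for axis in ("x", "y", "z"):
                cols.append(f"{side}_{name}_{axis}_m")
    return cols


class SchemaError(ValueError):
    """A trial file violates the documented schema."""


class NoOverlapError(ValueError):
    """Plate and marker streams share no common time window."""


@dataclass
class TrialMeta:
    """Metadata sidecar for one trial.

    ``reveal_time_s`` is the time the true target appeared on screen
    (dual-target trials only; ``None`` for single-target trials).
    ``sim`` carries generator parameters and ground truth for synthetic
    trials and is absent for real recordings.
    """

    participant: str
    day: int
    condition: str
    cued_side: str
    go_time_s: float
    target_onset_time_s: float
    body_weight_n: float
    reveal_time_s: Optional[float] = None
    swing_side: str = "right"
    sim: Optional[dict] = None

    @property
    def n_targets(self) -> str:
        return "dual" if self.condition.startswith("dual") else "single"

    @property
    def side(self) -> str:
        return self.condition.split("-", 1)[1]


@dataclass
class TrialRecording:
    """Synchronized force-plate and marker streams plus metadata."""

    plate: pd.DataFrame
    markers: pd.DataFrame
    meta: TrialMeta

    def validate(self) -> "TrialRecording":
        _check_stream(self.plate, PLATE_COLUMNS, PLATE_RATE_HZ, "plate")
        _check_stream(self.markers, marker_columns(), MARKER_RATE_HZ, "markers")
        for col in ("fz1_N", "fz2_N"):
            if (self.plate[col].to_numpy() < -1e-6).any():
                raise SchemaError(f"plate: negative vertical force in {col}")
        if self.meta.condition not in CONDITIONS:
            raise SchemaError(f"meta: unknown condition {self.meta.condition!r}")
        t0 = max(self.plate["time_s"].iloc[0], self.markers["time_s"].iloc[0])
        t1 = min(self.plate["time_s"].iloc[-1], self.markers["time_s"].iloc[-1])
        if t0 >= t1:
            raise NoOverlapError("plate and marker streams do not overlap in time")
        return self


def _check_stream(df: pd.DataFrame, required: list[str], rate_hz: float, label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label}: missing column(s) {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 3:
        raise SchemaError(f"{label}: stream too short ({len(t)} samples)")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise SchemaError(f"{label}: time_s not strictly increasing")
    nominal = 1.0 / rate_hz
    if np.abs(dt - nominal).max() > 1e-6:
        raise SchemaError(
            f"{label}: non-uniform sampling (expected {rate_hz:g} Hz, "
            f"dt range [{dt.min():.6g}, {dt.max():.6g}] s)"
        )


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def write_trial(trial: TrialRecording, stem: str | Path) -> None:
    """Write the ``.plate.tsv`` / ``.markers.tsv`` / ``.meta.json`` triplet."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    trial.plate.to_csv(
        stem.with_suffix(".plate.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    trial.markers.to_csv(
        stem.with_suffix(".markers.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    meta = asdict(trial.meta)
    with open(stem.with_suffix(".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_trial(stem: str | Path) -> TrialRecording:
    """Read a trial triplet and validate it.

    Raises :class:`SchemaError` with a field-level message on any
    missing channel, non-uniform sampling, or metadata mismatch.
    """
    stem = Path(stem)
    plate_path = stem.with_suffix(".plate.tsv")
    markers_path = stem.with_suffix(".markers.tsv")
    meta_path = stem.with_suffix(".meta.json")
    for p in (plate_path, markers_path, meta_path):
        if not p.exists():
            raise SchemaError(f"missing file {p.name}")
    plate = pd.read_csv(plate_path, sep="\t")
    markers = pd.read_csv(markers_path, sep="\t")
    with open(meta_path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        meta = TrialMeta(**raw)
    except TypeError as exc:
        raise SchemaError(f"meta: {exc}") from None
    if not isinstance(meta.body_weight_n, (int, float)) or not math.isfinite(
        meta.body_weight_n
    ):
        raise SchemaError("meta: body_weight_n must be a finite number")
    trial = TrialRecording(plate=plate, markers=markers, meta=meta)
    return trial.validate()


# ---------------------------------------------------------------------------
# stream synchronization
# ---------------------------------------------------------------------------


def align_streams(trial: TrialRecording) -> TrialRecording:
    """Crop both streams to their common time window.

    Event times derived from the plate stream are reported in seconds,
    so the two native rates (1,000 and 100 Hz) never need resampling.
    Raises :class:`NoOverlapError` when the windows are disjoint.
    """
    t0 = max(trial.plate["time_s"].iloc[0], trial.markers["time_s"].iloc[0])
    t1 = min(trial.plate["time_s"].iloc[-1], trial.markers["time_s"].iloc[-1])
    if t0 >= t1:
        raise NoOverlapError(
            f"streams do not overlap (plate [{trial.plate['time_s'].iloc[0]:g}, "
            f"{trial.plate['time_s'].iloc[-1]:g}], markers "
            f"[{trial.markers['time_s'].iloc[0]:g}, {trial.markers['time_s'].iloc[-1]:g}])"
        )
    eps = 1e-9
    plate = trial.plate[
        (trial.plate["time_s"] >= t0 - eps) & (trial.plate["time_s"] <= t1 + eps)
    ].reset_index(drop=True)
    markers = trial.markers[
        (trial.markers["time_s"] >= t0 - eps) & (trial.markers["time_s"] <= t1 + eps)
    ].reset_index(drop=True)
    return TrialRecording(plate=plate, markers=markers, meta=trial.meta)


def decimated_plate(trial: TrialRecording, factor: int = 10) -> pd.DataFrame:
    """Every ``factor``-th plate sample, for joint plotting with markers."""
    return trial.plate.iloc[::factor].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort: missing column(s) {', '.join(missing)}")
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort: missing column(s) {', '.join(missing)}")
    return table
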