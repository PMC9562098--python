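"""Exam records and grader labels.

One :class:`ExamRecord` is one eye-session: identity (patient, eye, session),
postmenstrual age, the two masked graders' stage labels, the adjudicated
ordinal stage, the measured maximum ridge thickness, and treatment status.
Stage labels come in two forms: ordinal (integers 0-3, the classical ICROP
stage) and continuous (0.1-increment values in [0, 3], reflecting that
staging is a spectrum). The two graders' continuous labels are averaged into
``mean_continuous``; ordinal disagreements are adjudicated by rounding that
average to the nearest integer (half rounds up).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import pandas as pd

STAGE_MIN = 0
STAGE_MAX = 3


def quantize_continuous(value: float) -> float:
    """Snap a continuous stage label to the 0.1 grid, clipped to [0, 3]."""
    v = min(max(value, float(STAGE_MIN)), float(STAGE_MAX))
    return round(int(v * 10 + 0.5) / 10.0, 1) if v >= 0 else 0.0


def round_half_up(value: float) -> int:
    """Round to the nearest integer with .5 rounding up (1.5 -> 2).

    Works on the 0.01 grid to dodge float representation of values such as
    2.45 (the finest grid a two-grader continuous-label average can hit).
    """
    hundredths = int(round(value * 100))
    return (hundredths + 50) // 100


@dataclass(frozen=True)
class GraderLabels:
    """Ordinal and continuous stage labels from two masked graders."""

    grader_a_ordinal: int
    grader_b_ordinal: int
    grader_a_continuous: float
    grader_b_continuous: float

    def __post_init__(self) -> None:
        for name in ("grader_a_ordinal", "grader_b_ordinal"):
            v = getattr(self, name)
            if not (STAGE_MIN <= v <= STAGE_MAX):
                raise ValueError(f"{name}={v} outside [{STAGE_MIN}, {STAGE_MAX}]")
        for oname, cname in (
            ("grader_a_ordinal", "grader_a_continuous"),
            ("grader_b_ordinal", "grader_b_continuous"),
        ):
            c = getattr(self, cname)
            if not (STAGE_MIN <= c <= STAGE_MAX):
                raise ValueError(f"{cname}={c} outside [{STAGE_MIN}, {STAGE_MAX}]")
            if abs(c * 10 - round(c * 10)) > 1e-6:
                raise ValueError(f"{cname}={c} is not on the 0.1 grid")
            if getattr(self, oname) != round_half_up(c):
                raise ValueError(
                    f"{oname}={getattr(self, oname)} inconsistent with {cname}={c}"
                )

    @classmethod
    def from_continuous(cls, a: float, b: float) -> "GraderLabels":
        """Build labels from two raw continuous values (quantized, clipped)."""
        ca, cb = quantize_continuous(a), quantize_continuous(b)
        return cls(
            grader_a_ordinal=round_half_up(ca),
            grader_b_ordinal=round_half_up(cb),
            grader_a_continuous=ca,
            grader_b_continuous=cb,
        )


@dataclass
class ExamRecord:
    """One eye-session with labels, measurement, and treatment status."""

    patient_id: str
    eye: str  # "OD" | "OS"
    session_id: str
    postmenstrual_week: float
    labels: GraderLabels
    adjudicated_ordinal: int
    mean_continuous: float
    max_thickness_um: float
    treated: bool = False
    weeks_from_treatment: float | None = None
    # generator-side ground truth; NaN/None for real data
    stage_true: int | None = None
    true_thickness_um: float | None = None
    capture: int = 0  # repeat-capture index within a session

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS'; got {self.eye!r}")
        if self.max_thickness_um < 0:
            raise ValueError("max_thickness_um must be >= 0")


_COLUMNS = [
    "patient_id",
    "eye",
    "session_id",
    "capture",
    "postmenstrual_week",
    "grader_a_ordinal",
    "grader_b_ordinal",
    "grader_a_continuous",
    "grader_b_continuous",
    "adjudicated_ordinal",
    "mean_continuous",
    "max_thickness_um",
    "treated",
    "weeks_from_treatment",
    "stage_true",
    "true_thickness_um",
]


def records_to_frame(records: Iterable[ExamRecord]) -> pd.DataFrame:
    """Flatten exam records into the documented cohort table (one row per exam)."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "eye": r.eye,
                "session_id": r.session_id,
                "capture": r.capture,
                "postmenstrual_week": r.postmenstrual_week,
                "grader_a_ordinal": r.labels.grader_a_ordinal,
                "grader_b_ordinal": r.labels.grader_b_ordinal,
                "grader_a_continuous": r.labels.grader_a_continuous,
                "grader_b_continuous": r.labels.grader_b_continuous,
                "adjudicated_ordinal": r.adjudicated_ordinal,
                "mean_continuous": r.mean_continuous,
                "max_thickness_um": r.max_thickness_um,
                "treated": r.treated,
                "weeks_from_treatment": r.weeks_from_treatment,
                "stage_true": r.stage_true,
                "true_thickness_um": r.true_thickness_um,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ExamRecord]:
    """Inverse of :func:`records_to_frame` for cohort CSVs."""
    out: list[ExamRecord] = []
    for _, row in frame.iterrows():
        labels = GraderLabels(
            grader_a_ordinal=int(row["grader_a_ordinal"]),
            grader_b_ordinal=int(row["grader_b_ordinal"]),
            grader_a_continuous=float(row["grader_a_continuous"]),
            grader_b_continuous=float(row["grader_b_continuous"]),
        )
        wft = row.get("weeks_from_treatment")
        wft = None if pd.isna(wft) else float(wft)
        stage_true = row.get("stage_true")
        stage_true = None if pd.isna(stage_true) else int(stage_true)
        true_um = row.get("true_thickness_um")
        true_um = None if pd.isna(true_um) else float(true_um)
        out.append(
            ExamRecord(
                patient_id=str(row["patient_id"]),
                eye=str(row["eye"]),
                session_id=str(row["session_id"]),
                capture=int(row.get("capture", 0)),
                postmenstrual_week=float(row["postmenstrual_week"]),
                labels=labels,
                adjudicated_ordinal=int(row["adjudicated_ordinal"]),
                mean_continuous=float(row["mean_continuous"]),
                max_thickness_um=float(row["max_thickness_um"]),
                treated=bool(row["treated"]),
                weeks_from_treatment=wft,
                stage_true=stage_true,
                true_thickness_um=true_um,
            )
        )
    return out
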