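"""Patient records, cutoff rules and the STOP score itself.

The STOP (Sepsis as Trauma Outcome Prediction) score is a 0–6 additive
risk score for sepsis development in severely injured multiple-trauma
patients (inclusion ISS >= 16).  Four variables measurable within 24 h of
admission each contribute points when they cross a directional cutoff:

====================================  =========  =========  ======
variable                              direction  threshold  weight
====================================  =========  =========  ======
small (<200 nm) EPs (particles/μL)    at_most    12,639     2
leukocyte count day 1 (10³ cells/μL)  at_most    8.5        2
Injury Severity Score                 at_least   25         1
PRBC units transfused within 24 h     at_least   1          1
====================================  =========  =========  ======

All comparisons are inclusive at the boundary.  A total above 3 (i.e.
>= 4) flags a patient as high risk.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Direction",
    "Outcome",
    "PatientRecord",
    "CutoffRule",
    "ScoreDefinition",
    "ScoreResult",
    "MissingVariable",
    "InvalidRecord",
    "canonical_stop_definition",
    "stop_score",
    "classify_high_risk",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
    "COHORT_COLUMNS",
]


class Direction(str, enum.Enum):
    """Risk direction of a cutoff: test-positive at or below / at or above."""

    AT_MOST = "at_most"
    AT_LEAST = "at_least"


class Outcome(str, enum.Enum):
    NO_COMPLICATION = "no_complication"
    PNEUMONIA = "pneumonia"
    SEPSIS = "sepsis"


class InvalidRecord(ValueError):
    """A patient record violates a field invariant."""


class MissingVariable(KeyError):
    """Scoring was attempted on a record lacking a score variable.

    Scoring with imputation is refused by design: records with incomplete
    predictor data are excluded, never filled in.
    """

    def __init__(self, variables: Sequence[str]):
        self.variables = tuple(variables)
        super().__init__(f"missing score variable(s): {', '.join(self.variables)}")


# Numeric score variables of a PatientRecord, in canonical order.
SCORE_VARIABLES = ("ep_small_per_ul", "leukocytes_day1", "iss", "prbc_units_24h")


def _check_nonneg_finite(name: str, value: float | None) -> None:
    if value is None:
        return
    if not math.isfinite(value) or value < 0:
        raise InvalidRecord(f"{name} must be finite and >= 0, got {value!r}")


@dataclass
class PatientRecord:
    """One patient's score-relevant measurements and outcome label.

    Units: ``ep_small_per_ul`` in particles/μL, ``leukocytes_day1`` in
    10³ cells/μL (printed clinically as "U/nL"), ``iss`` an integer in
    [0, 75], ``prbc_units_24h`` in transfusion units.  Any field may be
    missing (``None``); missing score variables abort scoring.
    """

    patient_id: str
    ep_small_per_ul: float | None = None
    leukocytes_day1: float | None = None
    iss: int | None = None
    prbc_units_24h: float | None = None
    outcome: Outcome | None = None

    def __post_init__(self) -> None:
        for name in ("ep_small_per_ul", "leukocytes_day1", "prbc_units_24h"):
            _check_nonneg_finite(name, getattr(self, name))
        if self.iss is not None:
            if not float(self.iss).is_integer() or not 0 <= self.iss <= 75:
                raise InvalidRecord(f"iss must be an integer in [0, 75], got {self.iss!r}")
            self.iss = int(self.iss)
        if self.outcome is not None and not isinstance(self.outcome, Outcome):
            self.outcome = Outcome(self.outcome)

    def validate_inclusion(self) -> None:
        """Raise unless the record meets the study inclusion criterion ISS >= 16."""
        if self.iss is None or self.iss < 16:
            raise InvalidRecord(
                f"patient {self.patient_id}: inclusion requires ISS >= 16, got {self.iss!r}"
            )


@dataclass(frozen=True)
class CutoffRule:
    """A directional threshold on one record variable with an integer weight."""

    variable: str
    direction: Direction
    threshold: float
    weight: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold!r}")
        if self.weight < 1 or int(self.weight) != self.weight:
            raise ValueError(f"weight must be a positive integer, got {self.weight!r}")
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "weight", int(self.weight))

    def is_met(self, value: float) -> bool:
        """Inclusive comparison, exactly as the printed operators (≤ / ≥)."""
        if self.direction is Direction.AT_MOST:
            return value <= self.threshold
        return value >= self.threshold


@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered set of cutoff rules; the score is the sum of met weights."""

    name: str
    rules: tuple[CutoffRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        names = [r.variable for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate rule variables in definition {self.name!r}")

    @property
    def max_score(self) -> int:
        return sum(r.weight for r in self.rules)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(r.variable for r in self.rules)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "rules": [
                {
                    "variable": r.variable,
                    "direction": r.direction.value,
                    "threshold": r.threshold,
                    "weight": r.weight,
                }
                for r in self.rules
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreDefinition":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        rules = tuple(
            CutoffRule(
                variable=r["variable"],
                direction=Direction(r["direction"]),
                threshold=float(r["threshold"]),
                weight=int(r["weight"]),
            )
            for r in payload["rules"]
        )
        return cls(name=payload["name"], rules=rules)


@dataclass(frozen=True)
class ScoreResult:
    total: int
    breakdown: Mapping[str, bool]


def canonical_stop_definition() -> ScoreDefinition:
    """The published STOP score definition (max score 6).

    Two points each for small-EP concentration <= 12,639 particles/μL at
    admission and leukocytes <= 8.5 (10³ cells/μL) on day 1; one point
    each for ISS >= 25 and >= 1 PRBC unit within 24 h.
    """
    return ScoreDefinition(
        name="STOP",
        rules=(
            CutoffRule("ep_small_per_ul", Direction.AT_MOST, 12639.0, weight=2),
            CutoffRule("leukocytes_day1", Direction.AT_MOST, 8.5, weight=2),
            CutoffRule("iss", Direction.AT_LEAST, 25.0, weight=1),
            CutoffRule("prbc_units_24h", Direction.AT_LEAST, 1.0, weight=1),
        ),
    )


def stop_score(record: PatientRecord, definition: ScoreDefinition | None = None) -> ScoreResult:
    """Score one patient: sum of rule weights over satisfied cutoffs.

    Raises :class:`MissingVariable` (naming every absent field) if any
    rule variable is missing — no imputation.
    """
    if definition is None:
        definition = canonical_stop_definition()
    missing = [r.variable for r in definition.rules if getattr(record, r.variable) is None]
    if missing:
        raise MissingVariable(missing)
    breakdown = {r.variable: r.is_met(float(getattr(record, r.variable))) for r in definition.rules}
    total = sum(r.weight for r in definition.rules if breakdown[r.variable])
    return ScoreResult(total=total, breakdown=breakdown)


def classify_high_risk(total: int, threshold: int = 3) -> bool:
    """High-risk iff the score strictly exceeds ``threshold`` (default >3, i.e. >=4)."""
    return total > threshold


def score_frame(
    frame: pd.DataFrame,
    definition: ScoreDefinition | None = None,
    threshold: int = 3,
) -> pd.DataFrame:
    """Score every row of a cohort frame.

    Adds ``stop_score`` (nullable integer), ``high_risk`` and
    ``score_missing`` columns; rows lacking a score variable are flagged
    via ``score_missing`` rather than dropped or imputed.
    """
    if definition is None:
        definition = canonical_stop_definition()
    out = frame.copy()
    totals: list[int | None] = []
    missing_flags: list[bool] = []
    for rec in frame_to_records(frame):
        try:
            totals.append(stop_score(rec, definition).total)
            missing_flags.append(False)
        except MissingVariable:
            totals.append(None)
            missing_flags.append(True)
    out["stop_score"] = pd.array(totals, dtype="Int64")
    out["high_risk"] = [
        classify_high_risk(t, threshold) if t is not None else None for t in totals
    ]
    out["score_missing"] = missing_flags
    return out


# ---------------------------------------------------------------------------
# CSV / DataFrame interchange
#
# CSV schema (header required, UTF-8, '.' decimal separator):
#   patient_id, ep_small_per_ul, leukocytes_day1, iss, prbc_24h, outcome
# Empty cell = missing.  The CSV column "prbc_24h" maps to the record
# field "prbc_units_24h".

COHORT_COLUMNS = ["patient_id", "ep_small_per_ul", "leukocytes_day1", "iss", "prbc_24h", "outcome"]
_CSV_TO_FIELD = {"prbc_24h": "prbc_units_24h"}
_FIELD_TO_CSV = {v: k for k, v in _CSV_TO_FIELD.items()}


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate records with field-named columns (internal representation)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "ep_small_per_ul": rec.ep_small_per_ul,
                "leukocytes_day1": rec.leukocytes_day1,
                "iss": rec.iss,
                "prbc_units_24h": rec.prbc_units_24h,
                "outcome": rec.outcome.value if rec.outcome is not None else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "ep_small_per_ul", "leukocytes_day1", "iss", "prbc_units_24h", "outcome"],
    )


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in frame.iterrows():
        def _get(col):
            val = row.get(col)
            return None if val is None or (isinstance(val, float) and math.isnan(val)) else val

        outcome = _get("outcome")
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                ep_small_per_ul=_get("ep_small_per_ul"),
                leukocytes_day1=_get("leukocytes_day1"),
                iss=None if _get("iss") is None else int(row["iss"]),
                prbc_units_24h=_get("prbc_units_24h"),
                outcome=Outcome(outcome) if outcome else None,
            )
        )
    return records


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a patient cohort CSV into the internal (field-named) frame.

    Raises ``ValueError`` with the offending column names on schema
    mismatch; row-level value errors carry 1-based data row numbers.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    frame = frame.rename(columns=_CSV_TO_FIELD)
    valid_outcomes = {o.value for o in Outcome}
    for i, val in enumerate(frame["outcome"], start=1):
        if isinstance(val, str) and val and val not in valid_outcomes:
            raise ValueError(f"{path}: row {i}: unknown outcome {val!r}")
    return frame


def write_cohort_csv(frame_or_records, path: str | Path) -> None:
    """Write a cohort to CSV in the external schema (sorted, stable floats)."""
    if isinstance(frame_or_records, pd.DataFrame):
        frame = frame_or_records.copy()
    else:
        frame = records_to_frame(frame_or_records)
    frame = frame.rename(columns=_FIELD_TO_CSV)
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    frame = frame[COHORT_COLUMNS + extra]
    frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
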