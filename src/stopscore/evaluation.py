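"""Stratified predictive-value tables and threshold metrics for a scored cohort.

``ppv_by_level`` produces the per-score-level stratification (one row per
score level, with everything below an aggregation point pooled into a
"<k" stratum), and ``metrics_at_threshold`` the dichotomised
sensitivity/specificity/PPV/NPV/F1 block with exact binomial CIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import BinomialCI, Confusion2x2, DegenerateInput, clopper_pearson

__all__ = [
    "ScoreLevelRow",
    "ThresholdMetrics",
    "EmptyCohort",
    "ppv_by_level",
    "metrics_at_threshold",
    "levels_to_frame",
    "metrics_to_frame",
]


class EmptyCohort(ValueError):
    pass


@dataclass(frozen=True)
class ScoreLevelRow:
    """One score stratum: patient count, event count, PPV, cohort share."""

    level: str  # "6", "5", ... or an aggregate label like "<3"
    n_patients: int
    n_events: int
    ppv: float
    pct_of_cohort: float


@dataclass(frozen=True)
class ThresholdMetrics:
    """Metrics for the dichotomy score > threshold, with exact CIs."""

    threshold: int
    confusion: Confusion2x2
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    sensitivity_ci: BinomialCI
    specificity_ci: BinomialCI
    ppv_ci: BinomialCI | None
    npv_ci: BinomialCI | None


def _as_arrays(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(list(scores), dtype=int)
    y = np.asarray(list(outcomes), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    return s, y


def ppv_by_level(
    scores: Sequence[int],
    outcomes: Sequence[int],
    aggregate_below: int = 3,
    detail_below: bool = False,
) -> list[ScoreLevelRow]:
    """Per-score-level event counts and PPVs, sorted descending by level.

    Levels below ``aggregate_below`` are pooled into a single "<k" row
    (set ``detail_below=True`` for per-level rows instead).  The rows
    partition the cohort: patient counts sum to the cohort size and
    event counts to the total events.
    """
    s, y = _as_arrays(scores, outcomes)
    if s.size == 0:
        raise EmptyCohort("no scored patients")
    total = s.size
    rows: list[ScoreLevelRow] = []

    def row(label: str, mask: np.ndarray) -> ScoreLevelRow:
        n = int(mask.sum())
        k = int(y[mask].sum())
        return ScoreLevelRow(
            level=label,
            n_patients=n,
            n_events=k,
            ppv=(k / n) if n else 0.0,
            pct_of_cohort=n / total,
        )

    for lvl in sorted({int(v) for v in s if v >= aggregate_below}, reverse=True):
        rows.append(row(str(lvl), s == lvl))
    if detail_below:
        for lvl in sorted({int(v) for v in s if v < aggregate_below}, reverse=True):
            rows.append(row(str(lvl), s == lvl))
    elif np.any(s < aggregate_below):
        rows.append(row(f"<{aggregate_below}", s < aggregate_below))
    return rows


def metrics_at_threshold(
    scores: Sequence[int],
    outcomes: Sequence[int],
    threshold: int = 3,
    level: float = 0.95,
) -> ThresholdMetrics:
    """Dichotomised metrics: test-positive iff score > threshold.

    Clopper–Pearson CIs are attached to sensitivity, specificity, PPV
    and NPV (the latter two only when their denominators are non-zero);
    F1 = 2·PPV·sens / (PPV + sens).
    """
    s, y = _as_arrays(scores, outcomes)
    if not np.any(y == 1) or not np.any(y == 0):
        raise DegenerateInput("both outcome classes must be present")
    pos = s > threshold
    cm = Confusion2x2(
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
        tn=int(np.sum(~pos & (y == 0))),
    )
    sens, spec = cm.sensitivity, cm.specificity
    n_pos, n_neg = cm.tp + cm.fp, cm.tn + cm.fn
    ppv = cm.ppv if n_pos else 0.0
    npv = cm.npv if n_neg else 0.0
    f1 = (2 * ppv * sens / (ppv + sens)) if (ppv + sens) > 0 else 0.0
    return ThresholdMetrics(
        threshold=threshold,
        confusion=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f1=f1,
        sensitivity_ci=clopper_pearson(cm.tp, cm.tp + cm.fn, level),
        specificity_ci=clopper_pearson(cm.tn, cm.tn + cm.fp, level),
        ppv_ci=clopper_pearson(cm.tp, n_pos, level) if n_pos else None,
        npv_ci=clopper_pearson(cm.tn, n_neg, level) if n_neg else None,
    )


def levels_to_frame(rows: Sequence[ScoreLevelRow]) -> pd.DataFrame:
    """Render stratification rows as a CSV-ready table (percentages, 2 dp)."""
    return pd.DataFrame(
        [
            {
                "score": r.level,
                "n_patients": r.n_patients,
                "n_events": r.n_events,
                "ppv_pct": round(100 * r.ppv, 2),
                "pct_of_cohort": round(100 * r.pct_of_cohort, 2),
            }
            for r in rows
        ]
    )


def metrics_to_frame(m: ThresholdMetrics) -> pd.DataFrame:
    def fmt(value: float, ci: BinomialCI | None) -> dict:
        out = {"value_pct": round(100 * value, 2)}
        if ci is not None:
            out.update(
                ci_lower_pct=round(100 * ci.lower, 2), ci_upper_pct=round(100 * ci.upper, 2)
            )
        return out

    rows = {
        "sensitivity": fmt(m.sensitivity, m.sensitivity_ci),
        "specificity": fmt(m.specificity, m.specificity_ci),
        "ppv": fmt(m.ppv, m.ppv_ci),
        "npv": fmt(m.npv, m.npv_ci),
        "f1": fmt(m.f1, None),
    }
    frame = pd.DataFrame.from_dict(rows, orient="index").reset_index(names="metric")
    frame.insert(0, "threshold", m.threshold)
    return frame
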