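"""Diagnostic-accuracy statistics: ROC curves, exact binomial CIs,
likelihood ratios, 2×2 tables, cutoff selection, and the two screening
tests (Mann–Whitney U, chi-square on proportions).

Conventions: test-positive is defined by an *inclusive* directional
comparison (value <= t for ``at_most`` cutoffs, value >= t for
``at_least``), matching the printed cutoff operators.  Proportions are
handled internally in [0, 1]; report helpers render percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CutoffRule, Direction

__all__ = [
    "RocCurve",
    "RocPoint",
    "BinomialCI",
    "Confusion2x2",
    "DegenerateInput",
    "UndefinedRatio",
    "NoFeasibleCutoff",
    "EmptySample",
    "DegenerateTable",
    "roc_curve",
    "clopper_pearson",
    "positive_likelihood_ratio",
    "confusion_at_cutoff",
    "select_cutoff",
    "mann_whitney_u",
    "chi_square_proportions",
    "table_row",
]


class DegenerateInput(ValueError):
    """A class is empty (after missing-value removal) where both are required."""


class UndefinedRatio(ZeroDivisionError):
    """Positive likelihood ratio is undefined at specificity 1."""


class NoFeasibleCutoff(ValueError):
    """No ROC point satisfies the sensitivity floor."""


class EmptySample(ValueError):
    pass


class DegenerateTable(ValueError):
    """A contingency table has a zero margin."""


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocCurve:
    """Threshold-indexed (sensitivity, specificity) pairs with trapezoidal AUC.

    One point per distinct observed value plus the degenerate
    all-negative / all-positive endpoints (threshold ±inf); points are
    sorted by threshold.  The AUC equals the tie-corrected concordance
    probability (concordant + ½·tied) / (n₁·n₂).
    """

    direction: Direction
    points: tuple[RocPoint, ...]
    auc: float

    @property
    def finite_points(self) -> tuple[RocPoint, ...]:
        return tuple(p for p in self.points if math.isfinite(p.threshold))


@dataclass(frozen=True)
class BinomialCI:
    """Exact (Clopper–Pearson) binomial confidence interval."""

    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class Confusion2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)


def _clean(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(
        [np.nan if x is None else float(x) for x in values], dtype=float
    )
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    if not np.any(y == 1) or not np.any(y == 0):
        raise DegenerateInput("need at least one record in each class after missing-value removal")
    return v, y


def _positive_mask(values: np.ndarray, threshold: float, direction: Direction) -> np.ndarray:
    if Direction(direction) is Direction.AT_MOST:
        return values <= threshold
    return values >= threshold


def roc_curve(values: Sequence[float], labels: Sequence[int], direction: Direction) -> RocCurve:
    """ROC over all distinct observed thresholds with inclusive comparisons.

    ``labels`` are binary (1 = event).  Missing values (None/NaN) are
    dropped first; both classes must remain non-empty.
    """
    v, y = _clean(values, labels)
    direction = Direction(direction)
    thresholds = np.concatenate(([-np.inf], np.unique(v), [np.inf]))
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    points = []
    for t in thresholds:
        # ±inf endpoints give the all-negative / all-positive corners
        pos = _positive_mask(v, t, direction)
        sens = float(np.sum(pos & (y == 1))) / n1
        spec = float(np.sum(~pos & (y == 0))) / n0
        points.append(RocPoint(float(t), sens, spec))
    # trapezoid over (1 - specificity, sensitivity), sorted along the curve
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(direction=direction, points=tuple(points), auc=auc)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial CI by inverting the binomial tail probabilities.

    ``lower`` solves P[X >= k | p] = (1 - level)/2 (0 when k = 0) and
    ``upper`` solves P[X <= k | p] = (1 - level)/2 (1 when k = n); the
    standard beta-quantile closed form of that inversion is used.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialCI(successes=k, trials=n, level=level, lower=lower, upper=upper)


def positive_likelihood_ratio(sensitivity: float, specificity: float) -> float:
    """LR+ = sensitivity / (1 - specificity)."""
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if specificity == 1:
        raise UndefinedRatio("positive likelihood ratio undefined at specificity 1")
    return sensitivity / (1.0 - specificity)


def confusion_at_cutoff(values, labels, rule: CutoffRule) -> Confusion2x2:
    """2×2 table at a cutoff rule; test-positive iff the rule comparison holds."""
    v, y = _clean(values, labels)
    pos = _positive_mask(v, rule.threshold, rule.direction)
    return Confusion2x2(
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
        tn=int(np.sum(~pos & (y == 0))),
    )


def select_cutoff(
    curve: RocCurve,
    policy: str = "sensitivity_floor",
    min_sensitivity: float = 0.65,
) -> CutoffRule:
    """Pick an operating threshold from a ROC curve.

    ``youden`` maximises sensitivity + specificity − 1; the default
    ``sensitivity_floor`` maximises specificity among points whose
    sensitivity meets the floor — the screening-oriented choice of a
    high sensitivity with adequate specificity.  Ties are broken toward
    the less extreme threshold (closest to the median of the curve's
    observed thresholds).  Returns a weight-1 placeholder rule.
    """
    candidates = list(curve.finite_points)
    if not candidates:
        raise DegenerateInput("curve has no finite-threshold points")
    if policy == "youden":
        feasible = candidates
        key = lambda p: p.sensitivity + p.specificity - 1.0
    elif policy == "sensitivity_floor":
        feasible = [p for p in candidates if p.sensitivity >= min_sensitivity]
        if not feasible:
            raise NoFeasibleCutoff(
                f"no ROC point has sensitivity >= {min_sensitivity}"
            )
        key = lambda p: p.specificity
    else:
        raise ValueError(f"unknown policy {policy!r}")
    best = max(key(p) for p in feasible)
    tied = [p for p in feasible if key(p) == best]
    pooled_median = float(np.median([p.threshold for p in candidates]))
    chosen = min(tied, key=lambda p: (abs(p.threshold - pooled_median), p.threshold))
    return CutoffRule(
        variable="_selected", direction=curve.direction, threshold=chosen.threshold, weight=1
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U with midranks for ties; two-sided p.

    Exact enumeration when min(n) <= 8 and there are no ties between or
    within samples; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U for x, p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptySample("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_proportions(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2×k table, no continuity correction.

    Raises :class:`DegenerateTable` when any row or column margin is zero
    (expected counts must be positive).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or (table < 0).any():
        raise ValueError("counts must be a non-negative 2×k table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTable("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def table_row(
    values,
    labels,
    rule: CutoffRule,
    level: float = 0.95,
    swap_orientation: bool = False,
) -> dict:
    """Render one diagnostic-table row for a cutoff: sensitivity and
    specificity with exact CIs (as percentages), AUC, LR+ and the
    Mann–Whitney p of the group comparison.

    ``swap_orientation=True`` reports the event-group proportion as
    "specificity" and the non-event proportion as "sensitivity" — the
    orientation in which some published per-marker rows back-calculate;
    the default is the conventional orientation.
    """
    cm = confusion_at_cutoff(values, labels, rule)
    v, y = _clean(values, labels)
    sens_k, sens_n = cm.tp, cm.tp + cm.fn
    spec_k, spec_n = cm.tn, cm.tn + cm.fp
    if swap_orientation:
        pos = _positive_mask(v, rule.threshold, rule.direction)
        sens_k, sens_n = int(np.sum(pos & (y == 0))), int(np.sum(y == 0))
        spec_k, spec_n = int(np.sum(pos & (y == 1))), int(np.sum(y == 1))
    sens_ci = clopper_pearson(sens_k, sens_n, level)
    spec_ci = clopper_pearson(spec_k, spec_n, level)
    curve = roc_curve(v, y, rule.direction)
    _, p = mann_whitney_u(v[y == 1], v[y == 0])
    sens, spec = sens_k / sens_n, spec_k / spec_n
    return {
        "variable": rule.variable,
        "cutoff": f"{'<=' if rule.direction is Direction.AT_MOST else '>='}{rule.threshold:g}",
        "sensitivity_pct": round(100 * sens, 2),
        "sensitivity_ci_pct": (round(100 * sens_ci.lower, 2), round(100 * sens_ci.upper, 2)),
        "specificity_pct": round(100 * spec, 2),
        "specificity_ci_pct": (round(100 * spec_ci.lower, 2), round(100 * spec_ci.upper, 2)),
        "auc": round(curve.auc, 4),
        "likelihood_ratio": round(positive_likelihood_ratio(sens, spec), 3)
        if spec < 1
        else math.inf,
        "p_value": p,
    }


def render_table_rows(rows: list[dict]) -> pd.DataFrame:
    """Assemble diagnostic rows into a CSV-ready frame."""
    return pd.DataFrame(rows)
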