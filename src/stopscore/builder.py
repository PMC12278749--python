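"""Score development: category-based candidate screening, multivariable
logistic regression by maximum likelihood, Wald-test weighting, and
assembly of a score definition.

The development procedure mirrors how the STOP score was built: candidate
variables are grouped into four clinical categories (patient/injury,
hemorrhage/coagulation, inflammatory, cell-derived); a category enters the
score if one of its variables separates the sepsis group significantly;
ROC-derived cutoffs dichotomise the chosen variables; and a multivariable
logistic fit's Wald tests decide which variables are double-weighted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CutoffRule, Direction, ScoreDefinition
from .diagnostics import (
    DegenerateInput,
    chi_square_proportions,
    mann_whitney_u,
    roc_curve,
    select_cutoff,
)

__all__ = [
    "CATEGORIES",
    "STOP_CATEGORY_MAP",
    "ScreenResult",
    "LogisticFit",
    "UnknownVariable",
    "SeparationError",
    "RankDeficient",
    "NotConverged",
    "VariableMismatch",
    "screen_candidates",
    "fit_logistic",
    "assign_weights",
    "build_score",
    "develop_score",
]

# Deterministic category order used when assembling a definition.
CATEGORIES = ("cell_derived", "inflammatory", "patient_injury", "hemorrhage_coagulation")

# Category assignment of the four STOP variables.
STOP_CATEGORY_MAP: dict[str, str] = {
    "ep_small_per_ul": "cell_derived",
    "leukocytes_day1": "inflammatory",
    "iss": "patient_injury",
    "prbc_units_24h": "hemorrhage_coagulation",
}


class UnknownVariable(KeyError):
    pass


class SeparationError(RuntimeError):
    """The logistic likelihood diverges (quasi-complete separation)."""


class RankDeficient(np.linalg.LinAlgError):
    """Collinear predictors: the design matrix is rank deficient."""


class NotConverged(RuntimeError):
    pass


class VariableMismatch(ValueError):
    pass


@dataclass(frozen=True)
class ScreenResult:
    """Screening summary for one candidate variable."""

    variable: str
    category: str
    p_value: float
    auc: float
    direction: Direction
    significant: bool


def _binary_outcome(frame: pd.DataFrame, positive: str = "sepsis") -> np.ndarray:
    if "outcome" not in frame.columns:
        raise UnknownVariable("cohort frame has no 'outcome' column")
    return (frame["outcome"] == positive).to_numpy(dtype=int)


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[np.isfinite(values)])
    return u.size <= 2 and set(u).issubset({0.0, 1.0})


def screen_candidates(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    category_map: Mapping[str, str],
    alpha: float = 0.05,
    positive: str = "sepsis",
) -> dict[str, list[ScreenResult]]:
    """Screen candidates per category against the event-vs-rest contrast.

    Numeric variables are compared with the Mann–Whitney U test, binary
    variables with the chi-square test on proportions.  Within each
    category, significant variables are ranked by AUC descending; a
    category with no significant variable maps to an empty list
    (excluded from the score).
    """
    y = _binary_outcome(cohort, positive)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateInput("cohort must contain both outcome classes")
    results: dict[str, list[ScreenResult]] = {c: [] for c in CATEGORIES}
    for var in variables:
        if var not in cohort.columns:
            raise UnknownVariable(var)
        if var not in category_map:
            raise UnknownVariable(f"{var} has no category assignment")
        v = pd.to_numeric(cohort[var], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(v)
        vv, yy = v[keep], y[keep]
        if _is_binary(vv):
            tab = [
                [np.sum((vv == 1) & (yy == 1)), np.sum((vv == 0) & (yy == 1))],
                [np.sum((vv == 1) & (yy == 0)), np.sum((vv == 0) & (yy == 0))],
            ]
            _, p = chi_square_proportions(tab)
        else:
            _, p = mann_whitney_u(vv[yy == 1], vv[yy == 0])
        # orient toward the risk direction: pick the direction whose
        # inclusive-threshold ROC has AUC >= 0.5
        curve_low = roc_curve(vv, yy, Direction.AT_MOST)
        if curve_low.auc >= 0.5:
            auc, direction = curve_low.auc, Direction.AT_MOST
        else:
            curve_high = roc_curve(vv, yy, Direction.AT_LEAST)
            auc, direction = curve_high.auc, Direction.AT_LEAST
        cat = category_map[var]
        results.setdefault(cat, [])
        if p < alpha:
            results[cat].append(ScreenResult(var, cat, float(p), float(auc), direction, True))
        else:
            results[cat].append(ScreenResult(var, cat, float(p), float(auc), direction, False))
    for cat in results:
        results[cat].sort(key=lambda r: (-int(r.significant), -r.auc))
    return results


def selected_variables(screen: Mapping[str, list[ScreenResult]]) -> dict[str, ScreenResult]:
    """Top significant variable per category (categories with none are dropped)."""
    chosen = {}
    for cat in CATEGORIES:
        sig = [r for r in screen.get(cat, []) if r.significant]
        if sig:
            chosen[cat] = sig[0]
    return chosen


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald statistics.

    Coefficients are reported on both the internally standardized
    (z-scored) predictor scale and the raw scale; Wald z and p come from
    the standardized fit and are therefore invariant to predictor
    scaling.  ``coefficients``/``standard_errors`` map predictor name →
    value on the standardized scale; the intercept is under
    ``"intercept"``.
    """

    predictors: tuple[str, ...]
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    coefficients_raw: Mapping[str, float]
    wald_z: Mapping[str, float]
    wald_p: Mapping[str, float]
    n_used: int
    converged: bool
    log_likelihood: float

    def odds_ratios_raw(self) -> dict[str, float]:
        return {k: math.exp(v) for k, v in self.coefficients_raw.items() if k != "intercept"}


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100,
          ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Newton/IRLS for the binomial log-likelihood; returns (beta, cov, converged, ll)."""
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        if ridge > 0:
            info = info + ridge * np.eye(k)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            # numerical-stability fallback only; non-inferential
            step = np.linalg.solve(info + 1e-8 * np.eye(k), score)
        beta = beta + step
        diverged = np.max(np.abs(beta[1:])) > 15 if k > 1 else abs(beta[0]) > 50
        if diverged:
            raise SeparationError(
                "likelihood diverges: standardized coefficient exceeded 15 "
                "(quasi-complete separation)"
            )
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info + (ridge if ridge > 0 else 0.0) * np.eye(k))
    ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    return beta, cov, converged, ll


def fit_logistic(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str | Sequence[int] = "sepsis",
) -> LogisticFit:
    """Multivariable logistic regression by maximum likelihood (IRLS).

    Rows with missing values in any predictor are excluded (listwise
    deletion — no imputation).  Predictors are z-scored internally;
    convergence requires the score vector's max component < 1e-8 within
    100 iterations.  Standard errors come from the inverse observed
    information.  Raises :class:`SeparationError` when the standardized
    coefficients diverge and :class:`RankDeficient` on collinear
    predictors.
    """
    if isinstance(outcome, str):
        y_all = _binary_outcome(cohort, outcome).astype(float)
    else:
        y_all = np.asarray(outcome, dtype=float)
    cols = [pd.to_numeric(cohort[p], errors="coerce").to_numpy(dtype=float) for p in predictors]
    V = np.column_stack(cols) if cols else np.empty((len(y_all), 0))
    keep = np.all(np.isfinite(V), axis=1) & np.isfinite(y_all)
    V, y = V[keep], y_all[keep]
    n = int(keep.sum())
    if y.sum() == 0 or y.sum() == n:
        raise DegenerateInput("need at least one row per outcome class after listwise deletion")

    means = V.mean(axis=0) if V.size else np.empty(0)
    sds = V.std(axis=0, ddof=0) if V.size else np.empty(0)
    if np.any(sds == 0):
        bad = [p for p, s in zip(predictors, sds) if s == 0]
        raise RankDeficient(f"constant predictor(s): {', '.join(bad)}")
    Z = (V - means) / sds if V.size else V
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficient("collinear predictors: design matrix is rank deficient")

    beta, cov, converged, ll = _irls(X, y)
    se = np.sqrt(np.diag(cov))
    names = ["intercept"] + list(predictors)
    wald_z = {nm: float(b / s) for nm, b, s in zip(names, beta, se)}
    wald_p = {nm: float(2 * stats.norm.sf(abs(z))) for nm, z in wald_z.items()}
    # back-transform to the raw predictor scale
    raw = {}
    if len(predictors):
        slopes = beta[1:] / sds
        raw_intercept = beta[0] - float(np.sum(beta[1:] * means / sds))
        raw = {"intercept": float(raw_intercept)}
        raw.update({p: float(b) for p, b in zip(predictors, slopes)})
    else:
        raw = {"intercept": float(beta[0])}
    return LogisticFit(
        predictors=tuple(predictors),
        coefficients={nm: float(b) for nm, b in zip(names, beta)},
        standard_errors={nm: float(s) for nm, s in zip(names, se)},
        coefficients_raw=raw,
        wald_z=wald_z,
        wald_p=wald_p,
        n_used=n,
        converged=converged,
        log_likelihood=ll,
    )


def assign_weights(fit: LogisticFit, alpha: float = 0.05) -> dict[str, int]:
    """Double-weight Wald-significant predictors: weight 2 iff p < alpha, else 1."""
    if not fit.converged:
        raise NotConverged("logistic fit did not converge; weights undefined")
    return {p: (2 if fit.wald_p[p] < alpha else 1) for p in fit.predictors}


def build_score(
    cutoffs: Mapping[str, CutoffRule],
    weights: Mapping[str, int],
    name: str = "score",
    category_map: Mapping[str, str] | None = None,
) -> ScoreDefinition:
    """Combine per-variable cutoffs and weights into a ScoreDefinition.

    Rule order is normalized to the category order (cell-derived,
    inflammatory, patient/injury, hemorrhage/coagulation), so permuted
    inputs yield identical definitions.
    """
    if set(cutoffs) != set(weights):
        raise VariableMismatch(
            f"cutoff variables {sorted(cutoffs)} != weight variables {sorted(weights)}"
        )
    cmap = dict(STOP_CATEGORY_MAP if category_map is None else category_map)
    order = {c: i for i, c in enumerate(CATEGORIES)}

    def sort_key(var: str):
        return (order.get(cmap.get(var, ""), len(CATEGORIES)), var)

    rules = tuple(
        dataclasses.replace(cutoffs[var], variable=var, weight=int(weights[var]))
        for var in sorted(cutoffs, key=sort_key)
    )
    return ScoreDefinition(name=name, rules=rules)


def develop_score(
    cohort: pd.DataFrame,
    variables: Sequence[str] | None = None,
    category_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    policy: str = "sensitivity_floor",
    min_sensitivity: float = 0.65,
    positive: str = "sepsis",
    name: str = "developed",
    overrides: Mapping[str, str] | None = None,
) -> tuple[ScoreDefinition, pd.DataFrame]:
    """Run the full development pipeline on a labelled cohort.

    screen → per-category variable selection (``overrides`` maps
    category → variable to force a manual choice) → ROC cutoff per
    variable → multivariable logistic fit → Wald-based weights → score.
    Returns the definition and a per-variable development report.
    """
    cmap = dict(STOP_CATEGORY_MAP if category_map is None else category_map)
    if variables is None:
        variables = list(cmap)
    screen = screen_candidates(cohort, variables, cmap, alpha=alpha, positive=positive)
    chosen = selected_variables(screen)
    if overrides:
        for cat, var in overrides.items():
            match = [r for r in screen.get(cat, []) if r.variable == var]
            if not match:
                raise UnknownVariable(f"override {var!r} was not screened in category {cat!r}")
            chosen[cat] = match[0]
    if not chosen:
        raise DegenerateInput("no category produced a significant variable")

    y = _binary_outcome(cohort, positive)
    cutoffs: dict[str, CutoffRule] = {}
    for res in chosen.values():
        v = pd.to_numeric(cohort[res.variable], errors="coerce").to_numpy(dtype=float)
        curve = roc_curve(v, y, res.direction)
        rule = select_cutoff(curve, policy=policy, min_sensitivity=min_sensitivity)
        cutoffs[res.variable] = dataclasses.replace(rule, variable=res.variable)

    fit = fit_logistic(cohort, list(cutoffs), outcome=positive)
    weights = assign_weights(fit, alpha=alpha)
    definition = build_score(cutoffs, weights, name=name, category_map=cmap)

    report = pd.DataFrame(
        [
            {
                "variable": res.variable,
                "category": cat,
                "screen_p": res.p_value,
                "auc": res.auc,
                "direction": res.direction.value,
                "cutoff": cutoffs[res.variable].threshold,
                "wald_p": fit.wald_p[res.variable],
                "weight": weights[res.variable],
            }
            for cat, res in chosen.items()
        ]
    )
    return definition, report
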