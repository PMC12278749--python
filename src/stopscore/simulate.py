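"""Synthetic trauma-cohort generation.

Real patient-level data for the score-development study are not public;
this module generates cohorts with the statistical structure of the three
published study groups (no complication n=79, pneumonia n=16, sepsis
n=29) from their printed summaries:

* EP concentration and day-1 leukocytes: lognormal, fitted to the printed
  median and IQR.  A lognormal cannot match both absolute endpoints of an
  asymmetric IQR, so the declared contract is exact median and exact
  q3/q1 ratio.
* ISS: a lognormal fitted to median/IQR, rounded to integers and clipped
  to [16, 75] (inclusion required ISS >= 16).
* PRBC units in 24 h: zero-inflated — 0 with probability p_zero, else a
  positive lognormal draw; the positive component is moment-calibrated so
  the mixture reproduces the printed mean and the SD implied by the
  printed SEM (sd = sem·√n).

Each (group, variable) pair consumes an independent random substream, so
adding a variable never perturbs the draws of another at a fixed seed.

``make_fixture_124`` builds the deterministic 124-patient cohort whose
STOP-score histogram matches the published per-score counts exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort import Outcome, PatientRecord

__all__ = [
    "DistributionSpec",
    "GroupSpec",
    "CohortSpec",
    "InvalidSpec",
    "fit_lognormal_median_iqr",
    "default_cohort_spec",
    "generate_cohort",
    "make_fixture_124",
]

# 75th standard-normal percentile, the half-width of the IQR in z units
Z75 = float(stats.norm.ppf(0.75))

VARIABLES = ("ep_small_per_ul", "leukocytes_day1", "iss", "prbc_units_24h")
GROUPS = ("no_complication", "pneumonia", "sepsis")
# fixed substream indices; append-only so existing draws stay stable
_VAR_STREAM = {v: i for i, v in enumerate(VARIABLES)}
_MISSING_STREAM_OFFSET = 100
_GROUP_STREAM = {g: i for i, g in enumerate(GROUPS)}


class InvalidSpec(ValueError):
    pass


def fit_lognormal_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Fit a lognormal to a printed median and interquartile range.

    Returns ``(log_location, log_scale)`` with log_location = ln(median)
    and log_scale = ln(q3/q1) / (2·z₀.₇₅).  The fitted distribution
    reproduces the median exactly and the quartile *ratio* q3/q1 exactly
    (both absolute quartiles only when the printed IQR is log-symmetric).
    """
    if not (0 < q1 <= median <= q3):
        raise InvalidSpec(f"need 0 < q1 <= median <= q3, got ({median}, {q1}, {q3})")
    return math.log(median), math.log(q3 / q1) / (2 * Z75)


@dataclass(frozen=True)
class DistributionSpec:
    """One variable's generating distribution within one group.

    kinds: ``lognormal_median_iqr`` (params median, q1, q3),
    ``zero_inflated_count`` (params mean, sem, n, p_zero),
    ``truncated_discrete`` (params median, q1, q3, minimum, maximum).
    """

    kind: str
    params: Mapping[str, float]
    units: str = ""

    def __post_init__(self):
        p = dict(self.params)
        if self.kind in ("lognormal_median_iqr", "truncated_discrete"):
            fit_lognormal_median_iqr(p["median"], p["q1"], p["q3"])  # validates ordering
        elif self.kind == "zero_inflated_count":
            if p["mean"] < 0 or p["sem"] < 0 or not 0 <= p["p_zero"] < 1:
                raise InvalidSpec(f"invalid zero-inflated params: {p}")
            _zero_inflated_lognormal_params(p["mean"], p["sem"], p["n"], p["p_zero"])
        else:
            raise InvalidSpec(f"unknown distribution kind {self.kind!r}")
        object.__setattr__(self, "params", p)


def _zero_inflated_lognormal_params(
    mean: float, sem: float, n: float, p_zero: float
) -> tuple[float, float]:
    """(mu, sigma) of the positive lognormal component of the mixture.

    Chosen so the mixture mean equals ``mean`` and the mixture SD equals
    ``sem·√n``: with q = 1 − p_zero, E[Y] = mean/q and
    E[Y²] = (sd² + mean²)/q, giving sigma² = ln(E[Y²]/E[Y]²).
    """
    q = 1.0 - p_zero
    sd = sem * math.sqrt(n)
    ey = mean / q
    ey2 = (sd * sd + mean * mean) / q
    ratio = ey2 / (ey * ey)
    if ratio < 1.0:
        raise InvalidSpec(
            f"mixture moments infeasible for a lognormal (mean={mean}, sd={sd}, p_zero={p_zero})"
        )
    sigma2 = math.log(ratio)
    mu = math.log(ey) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class GroupSpec:
    n: int
    variables: Mapping[str, DistributionSpec]
    missingness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise InvalidSpec("group size must be >= 1")
        for var, rate in self.missingness.items():
            if not 0 <= rate < 1:
                raise InvalidSpec(f"missingness rate for {var} must lie in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Per-group sample sizes and per-variable generating distributions."""

    groups: Mapping[str, GroupSpec]
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "groups": {
                g: {
                    "n": gs.n,
                    "missingness": dict(gs.missingness),
                    "variables": {
                        v: {"kind": ds.kind, "params": dict(ds.params), "units": ds.units}
                        for v, ds in gs.variables.items()
                    },
                }
                for g, gs in self.groups.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortSpec":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        groups = {
            g: GroupSpec(
                n=int(gd["n"]),
                variables={
                    v: DistributionSpec(kind=vd["kind"], params=vd["params"], units=vd.get("units", ""))
                    for v, vd in gd["variables"].items()
                },
                missingness=gd.get("missingness", {}),
            )
            for g, gd in payload["groups"].items()
        }
        return cls(groups=groups, seed=int(payload.get("seed", 0)))


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The published study conditions: three groups (79/16/29) with the
    printed medians/IQRs and means±SEM of the four score variables.

    PRBC zero-inflation probabilities (0.6 / 0.7 / 0.3) are modelling
    assumptions: transfusion of >= 1 unit must be materially more
    prevalent in the sepsis group, consistent with the printed means.
    """

    def ln(median, q1, q3, units):
        return DistributionSpec("lognormal_median_iqr", {"median": median, "q1": q1, "q3": q3}, units)

    def iss(median, q1, q3):
        return DistributionSpec(
            "truncated_discrete",
            {"median": median, "q1": q1, "q3": q3, "minimum": 16, "maximum": 75},
            "ISS points",
        )

    def prbc(mean, sem, n, p_zero):
        return DistributionSpec(
            "zero_inflated_count", {"mean": mean, "sem": sem, "n": n, "p_zero": p_zero}, "units"
        )

    groups = {
        "no_complication": GroupSpec(
            n=79,
            variables={
                "ep_small_per_ul": ln(14904, 11652, 20520, "particles/uL"),
                "leukocytes_day1": ln(9.46, 7.99, 11.93, "1e3 cells/uL"),
                "iss": iss(24.0, 18.0, 29.0),
                "prbc_units_24h": prbc(2.48, 1.14, 79, 0.6),
            },
        ),
        "pneumonia": GroupSpec(
            n=16,
            variables={
                "ep_small_per_ul": ln(17682, 12795, 25703, "particles/uL"),
                "leukocytes_day1": ln(11.34, 6.49, 15.44, "1e3 cells/uL"),
                "iss": iss(25.0, 17.0, 41.0),
                "prbc_units_24h": prbc(1.50, 0.80, 16, 0.7),
            },
        ),
        "sepsis": GroupSpec(
            n=29,
            variables={
                "ep_small_per_ul": ln(12138, 8198, 16472, "particles/uL"),
                "leukocytes_day1": ln(6.95, 4.53, 9.13, "1e3 cells/uL"),
                "iss": iss(34.0, 23.5, 38.5),
                "prbc_units_24h": prbc(5.36, 1.70, 29, 0.3),
            },
        ),
    }
    return CohortSpec(groups=groups, seed=seed)


def _draw(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "lognormal_median_iqr":
        mu, sigma = fit_lognormal_median_iqr(
            spec.params["median"], spec.params["q1"], spec.params["q3"]
        )
        return np.exp(rng.normal(mu, sigma, size=n))
    if spec.kind == "truncated_discrete":
        mu, sigma = fit_lognormal_median_iqr(
            spec.params["median"], spec.params["q1"], spec.params["q3"]
        )
        vals = np.rint(np.exp(rng.normal(mu, sigma, size=n)))
        return np.clip(vals, spec.params.get("minimum", 0), spec.params.get("maximum", 75))
    if spec.kind == "zero_inflated_count":
        mu, sigma = _zero_inflated_lognormal_params(
            spec.params["mean"], spec.params["sem"], spec.params["n"], spec.params["p_zero"]
        )
        zero = rng.random(n) < spec.params["p_zero"]
        vals = np.exp(rng.normal(mu, sigma, size=n))
        vals[zero] = 0.0
        return vals
    raise InvalidSpec(f"unknown distribution kind {spec.kind!r}")


def generate_cohort(
    spec: CohortSpec, seed: int | None = None, n_scale: int = 1
) -> list[PatientRecord]:
    """Draw a synthetic cohort; reproducible given (spec, seed, n_scale).

    ``n_scale`` multiplies every group size (used for scaled-up recovery
    experiments).  Each (group, variable) pair uses an independent
    substream seeded from ``SeedSequence([seed, group, variable])``.
    """
    if seed is None:
        seed = spec.seed
    if n_scale < 1:
        raise InvalidSpec("n_scale must be >= 1")
    records: list[PatientRecord] = []
    pid = 0
    for group in GROUPS:
        if group not in spec.groups:
            continue
        gs = spec.groups[group]
        n = gs.n * n_scale
        draws: dict[str, np.ndarray] = {}
        for var, dspec in gs.variables.items():
            if var not in _VAR_STREAM:
                raise InvalidSpec(f"unknown variable {var!r}")
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), _GROUP_STREAM[group], _VAR_STREAM[var]])
            )
            vals = _draw(dspec, n, rng)
            rate = gs.missingness.get(var, 0.0)
            if rate > 0:
                miss_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [int(seed), _GROUP_STREAM[group], _VAR_STREAM[var] + _MISSING_STREAM_OFFSET]
                    )
                )
                vals = vals.astype(object)
                vals[miss_rng.random(n) < rate] = None
            draws[var] = vals
        for i in range(n):
            pid += 1

            def get(var):
                if var not in draws:
                    return None
                val = draws[var][i]
                return None if val is None else float(val)

            iss_val = get("iss")
            records.append(
                PatientRecord(
                    patient_id=f"S{pid:05d}",
                    ep_small_per_ul=get("ep_small_per_ul"),
                    leukocytes_day1=get("leukocytes_day1"),
                    iss=None if iss_val is None else int(iss_val),
                    prbc_units_24h=get("prbc_units_24h"),
                    outcome=Outcome(group),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Deterministic 124-patient fixture
#
# The published per-score stratification:
#   score 6: 8 patients, 6 sepsis     score 5: 6 patients, 3 sepsis
#   score 4: 18 patients, 10 sepsis   score 3: 19 patients, 5 sepsis
#   score <3: 73 patients, 5 sepsis   (total 124, 29 sepsis)
#
# Canonical rule combinations realising each level (EP and leukocytes
# weigh 2; ISS and PRBC weigh 1):
#   6 = EP + leuko + ISS + PRBC     5 = EP + leuko + ISS
#   4 = EP + leuko                  3 = EP + ISS
#   2 = leuko                       1 = ISS           0 = none
_FIXTURE_STRATA = (
    # (score, combo of met rules, n_total, n_sepsis)
    (6, ("ep", "leuko", "iss", "prbc"), 8, 6),
    (5, ("ep", "leuko", "iss"), 6, 3),
    (4, ("ep", "leuko"), 18, 10),
    (3, ("ep", "iss"), 19, 5),
)
_FIXTURE_COMBOS_BELOW = {2: ("leuko",), 1: ("iss",), 0: ()}
_FIXTURE_SEPSIS_BELOW = 5  # published: 5 of the 73 sub-threshold patients were septic

# values satisfying / violating each canonical cutoff, inside plausible
# clinical ranges (ISS kept >= 16 per the inclusion criterion)
_MET = {"ep": 11000.0, "leuko": 6.5, "iss": 30, "prbc": 2.0}
_UNMET = {"ep": 16000.0, "leuko": 10.5, "iss": 20, "prbc": 0.0}


def _fixture_record(pid: int, combo: tuple[str, ...], outcome: Outcome) -> PatientRecord:
    vals = {k: (_MET[k] if k in combo else _UNMET[k]) for k in _MET}
    return PatientRecord(
        patient_id=f"F{pid:03d}",
        ep_small_per_ul=vals["ep"],
        leukocytes_day1=vals["leuko"],
        iss=int(vals["iss"]),
        prbc_units_24h=vals["prbc"],
        outcome=outcome,
    )


def make_fixture_124() -> tuple[list[int], list[int], list[PatientRecord]]:
    """The deterministic 124-patient cohort reproducing the published
    per-score counts.

    Returns ``(scores, sepsis_indicators, records)``.  Only the pooled
    "<3" stratum was published, so its 68 non-sepsis patients are placed
    round-robin over scores 0/1/2 and its 5 sepsis cases at score 2; the
    aggregate-row PPV is invariant to that placement.  Non-sepsis
    outcome labels fill the published 79/16 no-complication/pneumonia
    split (the first 16 non-sepsis records are labelled pneumonia).
    """
    combo_by_score = {s: c for s, c, _, _ in _FIXTURE_STRATA}
    combo_by_score.update(_FIXTURE_COMBOS_BELOW)
    plan: list[tuple[int, bool]] = []  # (score, is_sepsis)
    for score, _, n_total, n_sepsis in _FIXTURE_STRATA:
        plan += [(score, True)] * n_sepsis + [(score, False)] * (n_total - n_sepsis)
    plan += [(2, True)] * _FIXTURE_SEPSIS_BELOW
    plan += [((0, 1, 2)[i % 3], False) for i in range(73 - _FIXTURE_SEPSIS_BELOW)]

    n_pneumonia = 0
    scores, outcomes, records = [], [], []
    for pid, (score, is_sepsis) in enumerate(plan, start=1):
        if is_sepsis:
            outcome = Outcome.SEPSIS
        elif n_pneumonia < 16:
            outcome = Outcome.PNEUMONIA
            n_pneumonia += 1
        else:
            outcome = Outcome.NO_COMPLICATION
        records.append(_fixture_record(pid, combo_by_score[score], outcome))
        scores.append(score)
        outcomes.append(int(is_sepsis))
    return scores, outcomes, records
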