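"""Diagnostic statistics against independent oracles.

Each numerical routine is checked against a brute-force or closed-form
oracle implemented here: pair-enumeration concordance for the ROC AUC,
bisection on exact binomial tails for the Clopper–Pearson interval,
rank-assignment enumeration for the exact Mann–Whitney p, and exhaustive
point search for cutoff selection.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from stopscore import (
    CutoffRule,
    Direction,
    clopper_pearson,
    confusion_at_cutoff,
    chi_square_proportions,
    mann_whitney_u,
    positive_likelihood_ratio,
    roc_curve,
    select_cutoff,
)
from stopscore.diagnostics import (
    DegenerateInput,
    DegenerateTable,
    EmptySample,
    NoFeasibleCutoff,
    UndefinedRatio,
    table_row,
)


# --- independent oracles ----------------------------------------------------

def concordance_auc(values, labels, direction):
    """Tie-corrected concordance probability by exhaustive pair enumeration."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    score = 0.0
    for p, n in itertools.product(pos, neg):
        better = p < n if direction == Direction.AT_MOST else p > n
        score += 1.0 if better else (0.5 if p == n else 0.0)
    return score / (len(pos) * len(neg))


def cp_bounds_by_bisection(k, n, level=0.95, tol=1e-12):
    """Invert the exact binomial tail sums by bisection."""
    alpha = (1 - level) / 2

    def upper_tail(p):  # P[X >= k | p]
        return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))

    def lower_tail(p):  # P[X <= k | p]
        return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(upper_tail, alpha, 0.0, 1.0)
    upper = 1.0 if k == n else bisect(lambda p: 1 - lower_tail(p), 1 - alpha, 0.0, 1.0)
    return lower, upper


def mwu_exact_enumeration(x, y):
    """Exact two-sided Mann–Whitney p over all rank assignments (no ties)."""
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rx = sum(ranks[v] for v in x)
    u_obs = rx - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, nx + ny + 1), nx):
        us.append(sum(combo) - nx * (nx + 1) / 2)
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(1.0, p)


# --- ROC --------------------------------------------------------------------

class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], Direction.AT_MOST)
        assert curve.auc == pytest.approx(1.0)

    def test_ties_only(self):
        curve = roc_curve([5, 5, 5, 5], [1, 1, 0, 0], Direction.AT_LEAST)
        assert curve.auc == pytest.approx(0.5)

    def test_missing_values_dropped(self):
        curve = roc_curve([1, None, 2, np.nan, 3, 4], [1, 1, 1, 0, 0, 0], Direction.AT_MOST)
        assert curve.auc == pytest.approx(concordance_auc([1, 2, 3, 4], [1, 1, 0, 0], Direction.AT_MOST))

    def test_degenerate_class_raises(self):
        with pytest.raises(DegenerateInput):
            roc_curve([1, 2, 3], [1, 1, 1], Direction.AT_MOST)

    def test_endpoints_and_sorting(self):
        curve = roc_curve([3, 1, 2], [1, 0, 1], Direction.AT_MOST)
        ts = [p.threshold for p in curve.points]
        assert ts == sorted(ts) and ts[0] == -math.inf and ts[-1] == math.inf
        sens = {p.threshold: p.sensitivity for p in curve.points}
        assert sens[-math.inf] == 0.0 and sens[math.inf] == 1.0
        assert all(0 <= p.sensitivity <= 1 and 0 <= p.specificity <= 1 for p in curve.points)

    @pytest.mark.parametrize("direction", [Direction.AT_MOST, Direction.AT_LEAST])
    def test_auc_equals_concordance_oracle(self, rng, direction):
        """Trapezoidal AUC equals (concordant + half-tied) / (n1*n2) on random data."""
        for _ in range(150):
            n1, n0 = rng.integers(1, 13, size=2)
            values = rng.integers(0, 8, size=n1 + n0).astype(float)  # integers force ties
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            curve = roc_curve(values, labels, direction)
            expected = concordance_auc(values.tolist(), labels.tolist(), direction)
            assert curve.auc == pytest.approx(expected, abs=1e-12)

    def test_random_6_vs_5_instance(self, rng):
        values = rng.normal(size=11)
        labels = np.r_[np.ones(6, int), np.zeros(5, int)]
        curve = roc_curve(values, labels, Direction.AT_LEAST)
        assert curve.auc == pytest.approx(
            concordance_auc(values.tolist(), labels.tolist(), Direction.AT_LEAST)
        )


# --- Clopper–Pearson --------------------------------------------------------

class TestClopperPearson:
    def test_published_sepsis_row(self):
        ci = clopper_pearson(55, 79, 0.95)
        assert (round(ci.lower, 4), round(ci.upper, 4)) == (0.5825, 0.7947)

    @pytest.mark.parametrize("k, n", [(0, 10), (10, 10), (10, 20), (1, 30), (55, 79)])
    def test_matches_bisection_oracle(self, k, n):
        ci = clopper_pearson(k, n)
        lo, hi = cp_bounds_by_bisection(k, n)
        assert ci.lower == pytest.approx(lo, abs=1e-10)
        assert ci.upper == pytest.approx(hi, abs=1e-10)

    def test_tail_inversion_identity(self):
        """Plugging the lower bound back into the upper-tail sum gives alpha/2."""
        for k, n in [(3, 12), (10, 20), (55, 79), (29, 124)]:
            ci = clopper_pearson(k, n)
            tail = stats.binom.sf(k - 1, n, ci.lower)
            assert tail == pytest.approx(0.025, abs=1e-8)
            tail_up = stats.binom.cdf(k, n, ci.upper)
            assert tail_up == pytest.approx(0.025, abs=1e-8)

    def test_edges(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    def test_ordering_invariant(self):
        ci = clopper_pearson(7, 31, 0.9)
        assert 0 <= ci.lower <= ci.estimate <= ci.upper <= 1

    @pytest.mark.parametrize("k, n, level", [(-1, 10, 0.95), (11, 10, 0.95), (5, 0, 0.95), (5, 10, 1.0)])
    def test_domain_errors(self, k, n, level):
        with pytest.raises(ValueError):
            clopper_pearson(k, n, level)


# --- likelihood ratio -------------------------------------------------------

class TestLikelihoodRatio:
    @pytest.mark.parametrize(
        "sens, spec, expected",
        [
            (0.6962, 0.6552, 2.019),
            (0.6962, 0.5862, 1.682),
            (0.7910, 0.5714, 1.846),
            (51 / 73, 21 / 29, 2.533),  # 2-dp-rounded inputs give 2.532; count ratios reproduce the print
        ],
    )
    def test_published_rows(self, sens, spec, expected):
        assert round(positive_likelihood_ratio(sens, spec), 3) == expected

    def test_specificity_zero_returns_sensitivity(self):
        assert positive_likelihood_ratio(0.4, 0.0) == pytest.approx(0.4)

    def test_specificity_one_undefined(self):
        with pytest.raises(UndefinedRatio):
            positive_likelihood_ratio(0.9, 1.0)


# --- confusion tables -------------------------------------------------------

class TestConfusion:
    def test_simple_split(self):
        cm = confusion_at_cutoff([1, 2, 3, 4], [1, 1, 0, 0], CutoffRule("v", Direction.AT_MOST, 2))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 0, 0, 2)

    def test_nothing_positive(self):
        cm = confusion_at_cutoff([1, 2, 3, 4], [1, 1, 0, 0], CutoffRule("v", Direction.AT_MOST, 0))
        assert (cm.tp, cm.fn) == (0, 2)

    def test_randomized_against_per_record_oracle(self, rng):
        for _ in range(25):
            values = rng.integers(0, 10, size=20).astype(float)
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                continue
            rule = CutoffRule("v", Direction.AT_LEAST, float(rng.integers(0, 10)))
            cm = confusion_at_cutoff(values, labels, rule)
            tp = sum(1 for v, y in zip(values, labels) if v >= rule.threshold and y == 1)
            fp = sum(1 for v, y in zip(values, labels) if v >= rule.threshold and y == 0)
            fn = sum(1 for v, y in zip(values, labels) if v < rule.threshold and y == 1)
            tn = sum(1 for v, y in zip(values, labels) if v < rule.threshold and y == 0)
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
            assert cm.tp + cm.fp + cm.fn + cm.tn == 20


# --- cutoff selection -------------------------------------------------------

class TestSelectCutoff:
    def test_perfect_separation_both_policies(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], Direction.AT_MOST)
        for policy in ("youden", "sensitivity_floor"):
            rule = select_cutoff(curve, policy=policy)
            assert rule.threshold == 3.0
            assert rule.direction is Direction.AT_MOST
            assert rule.weight == 1

    def test_single_distinct_value(self):
        curve = roc_curve([5, 5], [1, 0], Direction.AT_LEAST)
        assert select_cutoff(curve, policy="youden").threshold == 5.0

    def test_no_feasible_floor(self):
        # a curve built by roc_curve always contains a sensitivity-1 point
        # (the largest observed value under an inclusive comparison), so the
        # infeasible case needs a hand-built curve, e.g. from subsampled points
        from stopscore.diagnostics import RocCurve, RocPoint

        curve = RocCurve(
            direction=Direction.AT_MOST,
            points=(RocPoint(1.0, 0.2, 0.9), RocPoint(2.0, 0.4, 0.6)),
            auc=0.5,
        )
        with pytest.raises(NoFeasibleCutoff):
            select_cutoff(curve, policy="sensitivity_floor", min_sensitivity=0.65)

    @pytest.mark.parametrize("policy", ["youden", "sensitivity_floor"])
    def test_agrees_with_exhaustive_search(self, rng, policy):
        for _ in range(40):
            n = int(rng.integers(8, 20))
            values = rng.integers(0, 12, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            curve = roc_curve(values, labels, Direction.AT_LEAST)
            try:
                rule = select_cutoff(curve, policy=policy, min_sensitivity=0.5)
            except NoFeasibleCutoff:
                assert all(p.sensitivity < 0.5 for p in curve.finite_points)
                continue
            pts = curve.finite_points
            if policy == "youden":
                best = max(p.sensitivity + p.specificity - 1 for p in pts)
                winners = [p for p in pts if p.sensitivity + p.specificity - 1 == best]
            else:
                feas = [p for p in pts if p.sensitivity >= 0.5]
                best = max(p.specificity for p in feas)
                winners = [p for p in feas if p.specificity == best]
            assert rule.threshold in {p.threshold for p in winners}


# --- Mann–Whitney U ---------------------------------------------------------

class TestMannWhitney:
    def test_identical_samples_give_half_u(self):
        u, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n1*n2/2

    def test_tiny_exact_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 7, size=2)
            vals = rng.permutation(50)[: n1 + n2].astype(float)  # distinct -> no ties
            x, y = vals[:n1].tolist(), vals[n1:].tolist()
            u, p = mann_whitney_u(x, y)
            u_exp, p_exp = mwu_exact_enumeration(x, y)
            assert u == pytest.approx(u_exp)
            assert p == pytest.approx(p_exp, abs=1e-12)

    def test_large_shift_is_significant(self, rng):
        x = rng.normal(0, 1, size=60)
        y = rng.normal(1.2, 1, size=60)
        _, p = mann_whitney_u(x, y)
        assert p < 0.05

    def test_empty_sample(self):
        with pytest.raises(EmptySample):
            mann_whitney_u([], [1.0])


# --- chi-square -------------------------------------------------------------

class TestChiSquare:
    def test_homogeneous_table(self):
        stat, p = chi_square_proportions([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_computed(self):
        # all expected counts are 10; Pearson sum = 4 * (10-0 deviations) = 40
        stat, _ = chi_square_proportions([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_equals_squared_two_proportion_z(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 30, size=4)
            stat, _ = chi_square_proportions([[a, b], [c, d]])
            p1, p2 = a / (a + b), c / (c + d)
            pool = (a + c) / (a + b + c + d)
            z = (p1 - p2) / math.sqrt(pool * (1 - pool) * (1 / (a + b) + 1 / (c + d)))
            assert stat == pytest.approx(z * z, rel=1e-10)

    def test_zero_margin(self):
        with pytest.raises(DegenerateTable):
            chi_square_proportions([[0, 0], [5, 5]])


# --- report rows ------------------------------------------------------------

class TestTableRow:
    def test_swap_orientation_exchanges_group_proportions(self, rng):
        values = np.r_[rng.normal(0, 1, 30), rng.normal(1, 1, 15)]
        labels = np.r_[np.zeros(30, int), np.ones(15, int)]
        rule = CutoffRule("marker", Direction.AT_LEAST, 0.5)
        conv = table_row(values, labels, rule)
        swap = table_row(values, labels, rule, swap_orientation=True)
        # swapped "sensitivity" counts the non-event group's positives
        pos = values >= 0.5
        assert swap["sensitivity_pct"] == pytest.approx(100 * pos[:30].mean(), abs=0.01)
        assert swap["specificity_pct"] == pytest.approx(100 * pos[30:].mean(), abs=0.01)
        assert conv["sensitivity_pct"] == pytest.approx(100 * pos[30:].mean(), abs=0.01)
        assert conv["auc"] == swap["auc"]
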