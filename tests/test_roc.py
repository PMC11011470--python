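import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from triagecut import (
    DegenerateRocError,
    auc,
    auc_with_ci,
    empirical_roc,
    mann_whitney_auc,
    sensitivity_constrained_threshold,
    youden_optimal_threshold,
)

# ---------------------------------------------------------------------------
# Brute-force oracles: exhaustive enumeration at the distinct observed
# score values, independent of the implementation's vectorized path.


def brute_points(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cands = sorted({0.0, *scores.tolist(), np.nextafter(scores.max(), np.inf)})
    pts = []
    for t in cands:
        calls = scores >= t
        sens = np.mean(calls[labels == 1])
        spec = np.mean(~calls[labels == 0])
        pts.append((t, sens, spec))
    return pts


def brute_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_instance(rng, n_max=12, grid=None):
    n = rng.integers(4, n_max)
    while True:
        labels = rng.integers(0, 2, size=n)
        if 0 < labels.sum() < n:
            break
    if grid is None:
        scores = rng.random(n).round(2)
    else:
        scores = rng.choice(grid, size=n)
    return scores, labels


class TestEmpiricalRoc:
    def test_perfect_separation_reaches_corner(self):
        curve = empirical_roc([0.9, 0.1, 0.2], [1, 0, 0])
        perfect = [
            t for t, s, p in curve.points if s == 1.0 and p == 1.0
        ]
        assert perfect and all(0.2 < t <= 0.9 for t in perfect)

    def test_all_tied_scores_yield_endpoints_only(self):
        curve = empirical_roc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        # candidate set collapses to 0, 0.5, just-above-0.5
        assert len(curve) == 3
        assert curve.sensitivity.tolist() == [1.0, 1.0, 0.0]
        assert curve.specificity.tolist() == [0.0, 0.0, 1.0]

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateRocError):
            empirical_roc([0.1, 0.2], [1, 1])

    def test_points_match_bruteforce_enumeration(self, rng):
        for _ in range(300):
            scores, labels = random_instance(rng)
            curve = empirical_roc(scores, labels)
            expect = brute_points(scores, labels)
            got = curve.points
            assert len(got) == len(expect)
            for (t1, s1, p1), (t2, s2, p2) in zip(got, expect):
                assert t1 == pytest.approx(t2)
                assert s1 == pytest.approx(s2)
                assert p1 == pytest.approx(p2)

    def test_monotonicity_along_thresholds(self, rng):
        """Lowering the cutoff never lowers sensitivity or raises specificity."""
        for _ in range(200):
            scores, labels = random_instance(rng, grid=np.linspace(0, 1, 9))
            curve = empirical_roc(scores, labels)
            assert np.all(np.diff(curve.sensitivity) <= 1e-12)
            assert np.all(np.diff(curve.specificity) >= -1e-12)


class TestAuc:
    def test_perfect_separation_auc_one(self):
        assert auc(empirical_roc([0.9, 0.1, 0.2], [1, 0, 0])) == pytest.approx(1.0)

    def test_constant_score_auc_half(self):
        assert auc(empirical_roc([0.4] * 6, [0, 1, 0, 1, 1, 0])) == pytest.approx(0.5)

    def test_trapezoid_equals_rank_statistic_and_bruteforce(self, rng):
        for _ in range(400):
            scores, labels = random_instance(rng, grid=np.linspace(0, 1, 7))
            a_trap = auc(empirical_roc(scores, labels))
            a_rank = mann_whitney_auc(scores, labels)
            a_brute = brute_auc(scores, labels)
            assert a_trap == pytest.approx(a_rank, abs=1e-12)
            assert a_trap == pytest.approx(a_brute, abs=1e-12)

    def test_agrees_with_sklearn_cross_check(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng, n_max=40)
            assert auc(empirical_roc(scores, labels)) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_ci_brackets_point_estimate(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng, n_max=30)
            est = auc_with_ci(scores, labels)
            assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0

    def test_delong_interval_shrinks_with_n(self, rng):
        scores = rng.random(40)
        labels = (scores + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        small = auc_with_ci(scores[:20], labels[:20])
        big = auc_with_ci(np.tile(scores, 5), np.tile(labels, 5))
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)


class TestYouden:
    def test_perfect_separation_j_one_at_lowest_qualifying(self):
        curve = empirical_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        choice = youden_optimal_threshold(curve)
        assert choice.youden_j == pytest.approx(1.0)
        # tie-break: lowest threshold with J = 1 is just above the top negative
        assert choice.cutoff == pytest.approx(0.8)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(400):
            scores, labels = random_instance(rng, grid=np.linspace(0, 1, 6))
            curve = empirical_roc(scores, labels)
            choice = youden_optimal_threshold(curve)
            pts = brute_points(scores, labels)
            best_j = max(s + p - 1.0 for _, s, p in pts)
            tying = [t for t, s, p in pts if abs(s + p - 1.0 - best_j) < 1e-9]
            assert choice.youden_j == pytest.approx(best_j, abs=1e-9)
            assert choice.cutoff == pytest.approx(min(tying))
            assert choice.youden_j == pytest.approx(
                choice.sensitivity_at_cutoff + choice.specificity_at_cutoff - 1.0
            )

    def test_tie_broken_toward_lower_threshold(self):
        # two thresholds tie on J = 0: any single point, constant labels mix
        curve = empirical_roc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
        choice = youden_optimal_threshold(curve)
        scan = brute_points([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
        best = max(s + p - 1.0 for _, s, p in scan)
        ties = [t for t, s, p in scan if abs(s + p - 1.0 - best) < 1e-12]
        assert choice.cutoff == pytest.approx(min(ties))


class TestSensitivityConstrained:
    def test_matches_exhaustive_scan(self, rng):
        for _ in range(400):
            scores, labels = random_instance(rng, grid=np.linspace(0, 1, 6))
            curve = empirical_roc(scores, labels)
            choice = sensitivity_constrained_threshold(curve, 0.95)
            ok = [(t, s, p) for t, s, p in brute_points(scores, labels) if s >= 0.95]
            t_best = max(t for t, _, _ in ok)
            p_best = max(p for _, _, p in ok)
            assert choice.cutoff == pytest.approx(t_best)
            assert choice.specificity_at_cutoff == pytest.approx(p_best)
            assert choice.sensitivity_at_cutoff >= 0.95 - 1e-12

    def test_full_sensitivity_forces_min_positive_score(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng, n_max=15)
            curve = empirical_roc(scores, labels)
            choice = sensitivity_constrained_threshold(curve, 1.0)
            assert choice.cutoff == pytest.approx(scores[labels == 1].min())
            assert choice.sensitivity_at_cutoff == 1.0

    def test_policies_coincide_when_youden_point_is_largest_qualifying(self):
        # clean separation: Youden point has sens 1 and is the largest
        # threshold with sens >= 0.95, so both policies resolve identically
        scores = [0.9, 0.85, 0.8, 0.3, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        curve = empirical_roc(scores, labels)
        y = youden_optimal_threshold(curve)
        s = sensitivity_constrained_threshold(curve, 0.95)
        assert y.cutoff == pytest.approx(s.cutoff)
        assert y.sensitivity_at_cutoff == 1.0

    @given(min_sens=st.floats(0.05, 1.0))
    def test_constraint_always_met(self, min_sens):
        rng = np.random.default_rng(7)
        scores, labels = random_instance(rng, n_max=20)
        choice = sensitivity_constrained_threshold(
            empirical_roc(scores, labels), min_sens
        )
        assert choice.sensitivity_at_cutoff >= min_sens - 1e-9
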