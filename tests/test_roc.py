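"""Empirical ROC, AUC oracle equivalence, confidence intervals, Youden cut-off."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import sarcoscreen as sc


def brute_force_auc(scores, truth):
    """Mean over all (positive, negative) pairs: 1 if pos > neg, 1/2 if tied."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos, neg = scores[truth], scores[~truth]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, truth):
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    best = (-np.inf, None)
    for t in np.unique(scores):
        sens = np.mean(scores[truth] >= t)
        spec = np.mean(scores[~truth] < t)
        j = sens + spec - 1
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t < best[1]):
            best = (j, t)
    return best


def test_auc_tied_pair_example():
    scores = [2, 3, 1, 2]
    truth = [True, True, False, False]
    assert sc.roc_curve(scores, truth).auc == pytest.approx(0.875)
    assert sc.auc_mannwhitney(scores, truth) == pytest.approx(0.875)
    assert brute_force_auc(scores, truth) == pytest.approx(0.875)


def test_auc_perfect_separation():
    assert sc.roc_curve([5, 6, 1, 2], [1, 1, 0, 0]).auc == 1.0
    assert sc.auc_mannwhitney([5, 1], [True, False]) == 1.0


def test_auc_constant_scores_is_chance():
    assert sc.roc_curve([3, 3, 3, 3], [1, 0, 1, 0]).auc == pytest.approx(0.5)


def test_single_class_truth_is_fatal():
    with pytest.raises(ValueError, match="both classes"):
        sc.roc_curve([1, 2], [True, True])


def test_curve_geometry(rng):
    scores = rng.normal(size=300) + np.repeat([1.0, 0.0], 150)
    truth = np.repeat([True, False], 150)
    curve = sc.roc_curve(scores, truth)
    assert curve.fpr[0] == curve.tpr[0] == 0.0
    assert curve.fpr[-1] == curve.tpr[-1] == 1.0
    assert np.all(np.diff(curve.fpr) >= 0)
    assert np.all(np.diff(curve.tpr) >= 0)
    assert curve.points.shape == (len(curve.fpr), 2)


@given(st.data())
def test_trapezoid_equals_mannwhitney_equals_bruteforce(data):
    n_pos = data.draw(st.integers(1, 8))
    n_neg = data.draw(st.integers(1, 8))
    # small integer scores force plenty of ties
    scores = data.draw(st.lists(st.integers(0, 5), min_size=n_pos + n_neg,
                                max_size=n_pos + n_neg))
    truth = [True] * n_pos + [False] * n_neg
    expected = brute_force_auc(scores, truth)
    assert sc.roc_curve(scores, truth).auc == pytest.approx(expected, abs=1e-12)
    assert sc.auc_mannwhitney(scores, truth) == pytest.approx(expected, abs=1e-12)


def test_auc_agrees_with_sklearn_oracle(rng):
    """Independent cross-check against an established ROC implementation."""
    from sklearn.metrics import roc_auc_score

    scores = np.round(rng.normal(size=400), 1)  # coarse grid forces ties
    truth = rng.random(400) < 0.3
    truth[:2] = [True, False]
    expected = roc_auc_score(truth, scores)
    assert sc.roc_curve(scores, truth).auc == pytest.approx(expected, abs=1e-12)
    assert sc.auc_mannwhitney(scores, truth) == pytest.approx(expected, abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=200)
    truth = rng.random(200) < 0.4
    truth[:2] = [True, False]  # ensure both classes
    base = sc.auc_mannwhitney(scores, truth)
    for f in (np.exp, np.tanh, lambda x: 3 * x + 7, lambda x: x ** 3):
        assert sc.auc_mannwhitney(f(scores), truth) == pytest.approx(base, abs=1e-12)
        assert sc.roc_curve(f(scores), truth).auc == pytest.approx(base, abs=1e-12)


def test_binormal_closed_form_limit(rng):
    """Empirical AUC converges to Phi((mu1-mu0)/sqrt(s0^2+s1^2))."""
    mu1, mu0, s1, s0 = 1.2, 0.0, 1.0, 0.8
    n = 20_000
    scores = np.concatenate([rng.normal(mu1, s1, n), rng.normal(mu0, s0, n)])
    truth = np.repeat([True, False], n)
    expected = stats.norm.cdf((mu1 - mu0) / np.hypot(s0, s1))
    assert sc.auc_mannwhitney(scores, truth) == pytest.approx(expected, abs=0.01)


def test_delong_interval_covers_truth(rng):
    """Nominal 95% DeLong interval covers the binormal true AUC ~95% of the time."""
    true_auc = stats.norm.cdf(1.0 / np.sqrt(2))  # mu diff 1, unit variances
    hits = 0
    reps = 300
    for _ in range(reps):
        scores = np.concatenate([rng.normal(1.0, 1.0, 60), rng.normal(0.0, 1.0, 140)])
        truth = np.repeat([True, False], [60, 140])
        lo, hi = sc.auc_ci(scores, truth, method="delong")
        hits += lo <= true_auc <= hi
    # binomial 3-sigma band around 0.95
    se = np.sqrt(0.95 * 0.05 / reps)
    assert abs(hits / reps - 0.95) < 3 * se + 0.01


def test_delong_and_bootstrap_agree(rng):
    scores = np.concatenate([rng.normal(1.0, 1.0, 70), rng.normal(0.0, 1.0, 130)])
    truth = np.repeat([True, False], [70, 130])
    d_lo, d_hi = sc.auc_ci(scores, truth, method="delong")
    b_lo, b_hi = sc.auc_ci(scores, truth, method="bootstrap", n_boot=2000, seed=5)
    assert d_lo == pytest.approx(b_lo, abs=0.02)
    assert d_hi == pytest.approx(b_hi, abs=0.02)


def test_perfect_separation_ci_upper_bound_truncated(rng):
    scores = np.concatenate([rng.uniform(2, 3, 100), rng.uniform(0, 1, 100)])
    truth = np.repeat([True, False], 100)
    lo, hi = sc.auc_ci(scores, truth, method="delong")
    assert hi == 1.0 and lo <= 1.0


def test_delong_needs_two_per_class():
    with pytest.raises(ValueError, match="at least 2"):
        sc.auc_ci([1.0, 0.0], [True, False], method="delong")


class TestYoudenCutoff:
    def test_perfectly_separated(self):
        res = sc.optimal_cutoff_youden([10, 12, 1, 2], [1, 1, 0, 0])
        assert res.threshold == 10 and res.youden_j == pytest.approx(1.0)

    def test_all_scores_equal_degenerate_tie(self):
        res = sc.optimal_cutoff_youden([4, 4, 4], [True, False, True])
        assert res.youden_j == pytest.approx(0.0)
        assert res.threshold == 4
        assert res.tie

    def test_enumerated_example(self):
        res = sc.optimal_cutoff_youden([3, 5, 7, 1, 2, 6], [1, 1, 1, 0, 0, 0])
        assert res.threshold == 3
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(2 / 3)
        assert res.youden_j == pytest.approx(2 / 3)

    @given(st.data())
    def test_matches_brute_force(self, data):
        n = data.draw(st.integers(4, 20))
        scores = data.draw(st.lists(st.integers(0, 10), min_size=n, max_size=n))
        truth = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if all(truth) or not any(truth):
            return
        expect_j, expect_t = brute_force_youden(scores, truth)
        res = sc.optimal_cutoff_youden(scores, truth)
        assert res.youden_j == pytest.approx(expect_j, abs=1e-12)
        if not res.tie or res.threshold != np.inf:
            assert res.threshold == expect_t

    def test_j_equals_max_tpr_minus_fpr(self, rng):
        scores = rng.normal(size=150) + np.repeat([0.8, 0.0], [50, 100])
        truth = np.repeat([True, False], [50, 100])
        curve = sc.roc_curve(scores, truth)
        res = sc.optimal_cutoff_youden(scores, truth)
        assert res.youden_j == pytest.approx(float(np.max(curve.tpr - curve.fpr)))

    def test_integer_grid_search(self):
        scores = [2.4, 3.6, 1.2, 2.9]
        truth = [True, True, False, False]
        res = sc.optimal_cutoff_youden(scores, truth, grid=range(0, 5))
        assert float(res.threshold).is_integer()
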