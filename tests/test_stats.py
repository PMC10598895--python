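"""Validation statistics: AUC/DeLong, Youden, exact binomial intervals,
odds ratios, AUC-driven sample size."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from gadas import (
    binom_ci,
    delong_compare,
    odds_ratio,
    roc_auc,
    sample_size_auc,
    youden_threshold,
)
from gadas.errors import DegenerateLabelsError, RangeError
from gadas.stats import _hanley_mcneil_var


def pair_count_auc(scores, labels):
    """Exhaustive Mann-Whitney pair counting (lower score = positive)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x < y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


# -- AUC ---------------------------------------------------------------------


def test_spec_toy_set_auc():
    scores = [1.0, 3.0, 2.0, 4.0, 5.0]
    labels = [True, True, False, False, False]
    r = roc_auc(scores, labels)
    assert r.auc == pytest.approx(5 / 6)
    assert r.auc == pytest.approx(pair_count_auc(scores, labels))


def test_perfect_separation_and_all_ties():
    assert roc_auc([-5, -6, 1, 2], [1, 1, 0, 0]).auc == 1.0
    assert roc_auc([3.0] * 6, [1, 1, 0, 0, 0, 0]).auc == 0.5


def test_degenerate_labels_rejected():
    with pytest.raises(DegenerateLabelsError):
        roc_auc([1.0, 2.0], [True, True])


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    scores=st.lists(st.floats(-50, 50, allow_nan=False), min_size=4, max_size=50),
    data=st.data(),
)
def test_auc_equals_exhaustive_pair_counting(scores, data):
    n = len(scores)
    labels = data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < n
        )
    )
    r = roc_auc(scores, labels)
    assert r.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
    # independent library cross-check on the negated (higher = positive) scale
    assert r.auc == pytest.approx(
        roc_auc_score(labels, [-s for s in scores]), abs=1e-12
    )


def test_auc_invariant_under_strictly_monotone_transform():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=80)
    labels = rng.random(80) < 0.3
    labels[:2] = [True, False]
    transformed = np.expm1(scores) + 3 * scores  # strictly increasing
    assert roc_auc(scores, labels).auc == pytest.approx(
        roc_auc(transformed, labels).auc, abs=1e-12
    )


def test_roc_curve_monotone_and_ci_ordered():
    rng = np.random.default_rng(4)
    scores = np.concatenate([rng.normal(-8, 4, 40), rng.normal(5, 4, 160)])
    labels = np.array([True] * 40 + [False] * 160)
    r = roc_auc(scores, labels)
    curve = np.array([(fpr, tpr) for fpr, tpr, _ in r.curve])
    assert (np.diff(curve[:, 0]) >= 0).all() and (np.diff(curve[:, 1]) >= 0).all()
    assert 0.0 <= r.auc_ci[0] <= r.auc <= r.auc_ci[1] <= 1.0


def test_delong_interval_width_shrinks_with_n():
    rng = np.random.default_rng(5)

    def width(n):
        scores = np.concatenate([rng.normal(-5, 4, n // 5), rng.normal(3, 4, n)])
        labels = np.array([True] * (n // 5) + [False] * n)
        lo, hi = roc_auc(scores, labels).auc_ci
        return hi - lo

    assert width(500) < width(50)


# -- Youden threshold --------------------------------------------------------


def brute_force_youden(scores, labels):
    """Scan every candidate cut-off (midpoints of adjacent distinct scores)."""
    u = np.unique(scores)
    cands = np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2, [u[-1]]])
    pos = np.asarray(scores)[np.asarray(labels)]
    neg = np.asarray(scores)[~np.asarray(labels)]
    best_j, best_t = -np.inf, None
    for t in cands:
        j = np.mean(pos <= t) - np.mean(neg <= t)
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_youden_matches_brute_force_scan(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(0, 6, 40), 1)
    labels = rng.random(40) < 0.4
    labels[:2] = [True, False]
    r = roc_auc(scores, labels)
    t, j = brute_force_youden(scores, labels)
    assert youden_threshold(r) == pytest.approx(t)
    assert r.sensitivity - (1 - r.specificity) == pytest.approx(j, abs=1e-12)


def test_perfect_separation_returns_gap_midpoint():
    scores = [-9.0, -7.0, 2.0, 4.0, 6.0]
    labels = [True, True, False, False, False]
    assert youden_threshold(roc_auc(scores, labels)) == pytest.approx(-2.5)


def test_duplicated_score_never_changes_max_youden():
    scores = [-6.0, -2.0, -1.0, 3.0, 5.0]
    labels = [True, True, False, False, False]
    j1 = brute_force_youden(scores, labels)[1]
    j2 = brute_force_youden(scores + [-2.0], labels + [True])[1]
    r1 = roc_auc(scores, labels)
    assert r1.sensitivity + r1.specificity - 1 == pytest.approx(j1)
    assert j1 == pytest.approx(j2)


# -- exact binomial intervals ------------------------------------------------


def test_published_sensitivity_interval_reproduced():
    """50 of 56 difficult intubations detected: 89.3% (78.1-96.0%)."""
    lo, hi = binom_ci(50, 56, 0.95)
    assert round(lo, 3) == 0.781
    assert round(hi, 3) == 0.960


def test_boundary_counts():
    assert binom_ci(0, 20)[0] == 0.0
    assert binom_ci(20, 20)[1] == 1.0


def bisect_tail_inversion(k, n, level):
    """Invert the binomial tails by bisection (independent oracle)."""
    alpha = 1 - level

    def lower():
        if k == 0:
            return 0.0
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if sps.binom.sf(k - 1, n, mid) < alpha / 2:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    def upper():
        if k == n:
            return 1.0
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if sps.binom.cdf(k, n, mid) < alpha / 2:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    return lower(), upper()


@pytest.mark.parametrize("k,n", [(1, 10), (5, 9), (50, 56), (115, 2012), (7, 7)])
def test_interval_matches_tail_inversion_oracle(k, n):
    lo, hi = binom_ci(k, n, 0.95)
    olo, ohi = bisect_tail_inversion(k, n, 0.95)
    assert lo == pytest.approx(olo, abs=1e-9)
    assert hi == pytest.approx(ohi, abs=1e-9)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(n=st.integers(2, 400), data=st.data())
def test_interval_contains_the_point_estimate(n, data):
    k = data.draw(st.integers(1, n - 1))
    lo, hi = binom_ci(k, n, 0.95)
    assert lo < k / n < hi


def test_invalid_counts_rejected():
    with pytest.raises(RangeError):
        binom_ci(5, 4)
    with pytest.raises(RangeError):
        binom_ci(-1, 4)


# -- paired AUC comparison ---------------------------------------------------


def test_identical_markers_compare_equal():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=60)
    labels = rng.random(60) < 0.4
    labels[:2] = [True, False]
    a, b, p = delong_compare(scores, scores, labels)
    assert a == b
    assert p == 1.0


def test_swapping_markers_preserves_p_value():
    rng = np.random.default_rng(7)
    s1 = rng.normal(size=100)
    s2 = s1 + rng.normal(0, 2, size=100)
    labels = rng.random(100) < 0.3
    labels[:2] = [True, False]
    a1, b1, p1 = delong_compare(s1, s2, labels)
    a2, b2, p2 = delong_compare(s2, s1, labels)
    assert (a1, b1) == (b2, a2)
    assert p1 == pytest.approx(p2)


def test_informative_vs_noise_marker_detected():
    """A separating marker against pure noise at n = 200: DeLong rejects and
    a paired sign-flip permutation oracle agrees."""
    rng = np.random.default_rng(8)
    n_pos, n_neg = 40, 160
    labels = np.array([True] * n_pos + [False] * n_neg)
    informative = np.concatenate([rng.normal(-10, 2, n_pos), rng.normal(5, 2, n_neg)])
    noise = rng.normal(0, 5, n_pos + n_neg)
    a, b, p = delong_compare(informative, noise, labels)
    assert a > 0.99 and p < 0.01

    def auc(scores):
        return roc_auc(scores, labels).auc

    observed = abs(auc(informative) - auc(noise))
    count = 0
    n_perm = 400
    for _ in range(n_perm):
        swap = rng.random(len(labels)) < 0.5
        s_a = np.where(swap, noise, informative)
        s_b = np.where(swap, informative, noise)
        if abs(auc(s_a) - auc(s_b)) >= observed:
            count += 1
    assert (count + 1) / (n_perm + 1) < 0.05


# -- odds ratios -------------------------------------------------------------


def test_unit_odds_ratio():
    r = odds_ratio(1, 1, 1, 1)
    assert r.odds_ratio == 1.0
    assert r.ci[0] < 1.0 < r.ci[1]
    assert not r.corrected


def test_reconstructed_screening_table():
    """2x2 reconstructed from the published sensitivity/specificity counts."""
    r = odds_ratio(50, 6, 115, 1897)
    assert r.odds_ratio == pytest.approx((50 * 1897) / (6 * 115), rel=1e-12)
    assert r.odds_ratio == pytest.approx(137.5, abs=0.1)
    assert not r.corrected


def test_zero_cell_triggers_haldane_correction():
    r = odds_ratio(10, 0, 5, 20)
    assert r.corrected
    assert np.isfinite(r.odds_ratio)
    assert np.isfinite(r.ci[0]) and np.isfinite(r.ci[1])


def test_empty_margin_rejected():
    with pytest.raises(RangeError):
        odds_ratio(0, 0, 5, 5)


# -- AUC-driven sample size --------------------------------------------------


def _power(n, auc_alt, auc_null, alpha, frac):
    n_pos = int(round(frac * n))
    n_neg = n - n_pos
    z = sps.norm.ppf(1 - alpha / 2)
    se0 = np.sqrt(_hanley_mcneil_var(auc_null, n_pos, n_neg))
    se1 = np.sqrt(_hanley_mcneil_var(auc_alt, n_pos, n_neg))
    return sps.norm.cdf(((auc_alt - auc_null) - z * se0) / se1)


def test_design_scenario_requires_thousands():
    n = sample_size_auc(0.9, 0.8, alpha=0.05, power=0.8, positive_fraction=0.025)
    assert 800 <= n <= 4000


def test_returned_n_is_the_power_boundary():
    n = sample_size_auc(0.9, 0.8, 0.05, 0.8, 0.05)
    assert _power(n, 0.9, 0.8, 0.05, 0.05) >= 0.8
    assert _power(n - 1, 0.9, 0.8, 0.05, 0.05) < 0.8


def test_better_class_balance_reduces_n():
    n_rare = sample_size_auc(0.9, 0.8, 0.05, 0.8, 0.025)
    n_balanced = sample_size_auc(0.9, 0.8, 0.05, 0.8, 0.05)
    assert n_balanced < n_rare


def test_infeasible_order_rejected():
    with pytest.raises(RangeError):
        sample_size_auc(0.8, 0.9)
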