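"""ROC discrimination: Mann-Whitney AUC, DeLong variance and paired test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulvalid import (auc_ci, auc_mann_whitney, auc_with_ci,
                      delong_components_and_variance, delong_paired_test)
from pulvalid.discrimination import DegenerateInputError, roc_points


def brute_force_auc(pos, neg):
    """Independent O(n^2) oracle: mean pairwise win rate with half for ties."""
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_small_example():
    assert auc_mann_whitney([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)


def test_auc_all_ties_is_half():
    assert auc_mann_whitney([0.3] * 5, [0.3] * 7) == pytest.approx(0.5)


def test_auc_perfect_separation():
    assert auc_mann_whitney([0.8, 0.9], [0.1, 0.2, 0.3]) == 1.0


def test_auc_empty_class_rejected():
    with pytest.raises(DegenerateInputError):
        auc_mann_whitney([], [0.1])


def test_auc_matches_brute_force_on_random_instances(rng):
    for _ in range(200):
        m = rng.integers(1, 50)
        n = rng.integers(1, 50)
        # mixed continuous and discretised scores so ties occur
        pos = np.round(rng.random(m), rng.integers(1, 4))
        neg = np.round(rng.random(n), rng.integers(1, 4))
        assert auc_mann_whitney(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1).map(lambda x: round(x, 3)), min_size=1, max_size=20),
       st.lists(st.floats(0, 1).map(lambda x: round(x, 3)), min_size=1, max_size=20))
def test_auc_symmetry(pos, neg):
    """auc(scores) + auc(1 - scores) = 1 (scores rounded so 1-x is exact)."""
    a = auc_mann_whitney(pos, neg)
    b = auc_mann_whitney([1 - x for x in neg], [1 - x for x in pos])
    assert a == pytest.approx(b)
    flipped = auc_mann_whitney([1 - x for x in pos], [1 - x for x in neg])
    assert a + flipped == pytest.approx(1.0)


def test_auc_invariant_under_monotone_transform(rng):
    pos, neg = rng.random(30), rng.random(40)
    base = auc_mann_whitney(pos, neg)
    for f in (np.exp, lambda x: x**3 + x, lambda x: np.log1p(x)):
        assert auc_mann_whitney(f(pos), f(neg)) == pytest.approx(base)


def test_delong_variance_hand_computed_3_plus_3():
    """Placement-component table for pos=[3,2,1], neg=[2.5,0.5,0]:
    V10 = [1, 2/3, 2/3], V01 = [1/3, 1, 1], so AUC = 7/9 and
    variance = (1/27)/3 + (4/27)/3 = 5/81."""
    auc, var = delong_components_and_variance([3, 2, 1], [2.5, 0.5, 0])
    assert auc == pytest.approx(7 / 9)
    assert var == pytest.approx(5 / 81)


def test_delong_variance_zero_on_perfect_separation():
    with pytest.warns(UserWarning, match="degenerate"):
        auc, var = delong_components_and_variance([5, 6, 7], [1, 2, 3])
    assert auc == 1.0 and var == 0.0


def test_delong_variance_scales_inversely_with_n(rng):
    pos = rng.normal(1.0, 1.0, 40)
    neg = rng.normal(0.0, 1.0, 60)
    _, var1 = delong_components_and_variance(pos, neg)
    _, var2 = delong_components_and_variance(np.repeat(pos, 2), np.repeat(neg, 2))
    assert var2 == pytest.approx(var1 / 2, rel=0.05)


def test_delong_requires_two_per_class():
    with pytest.raises(DegenerateInputError):
        delong_components_and_variance([1.0], [0.0, 0.5])


def test_paired_test_identical_scores():
    scores = [0.9, 0.2, 0.7, 0.4, 0.6, 0.1]
    labels = [1, 0, 1, 0, 1, 0]
    res = delong_paired_test(scores, scores, labels)
    assert res.difference == 0.0 and res.z_statistic == 0.0 and res.p_value == 1.0


def test_paired_test_anti_classifier_on_separable_instance():
    scores_a = np.array([0.9, 0.8, 0.85, 0.95, 0.1, 0.2, 0.15, 0.05])
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    with pytest.warns(UserWarning, match="degenerate"):
        res = delong_paired_test(scores_a, 1 - scores_a, labels)
    assert res.auc_a == 1.0 and res.auc_b == 0.0
    assert res.difference == pytest.approx(1.0)
    assert res.p_value == 0.0


def test_paired_test_against_sign_flip_permutation(rng):
    """Small 4+4 instance: the DeLong p-value agrees in direction and rough
    magnitude with an exact model-swap permutation distribution."""
    scores_a = np.array([0.9, 0.6, 0.7, 0.55, 0.3, 0.45, 0.2, 0.5])
    scores_b = np.array([0.8, 0.4, 0.75, 0.35, 0.45, 0.5, 0.3, 0.6])
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    res = delong_paired_test(scores_a, scores_b, labels)

    def auc_diff(a, b):
        return (auc_mann_whitney(a[labels == 1], a[labels == 0])
                - auc_mann_whitney(b[labels == 1], b[labels == 0]))

    observed = auc_diff(scores_a, scores_b)
    assert np.sign(res.z_statistic) == np.sign(observed)
    count = 0
    n = len(labels)
    for mask in range(2 ** n):
        swap = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        a = np.where(swap, scores_b, scores_a)
        b = np.where(swap, scores_a, scores_b)
        if abs(auc_diff(a, b)) >= abs(observed) - 1e-12:
            count += 1
    p_perm = count / 2 ** n
    assert abs(res.p_value - p_perm) < 0.3
    assert (res.p_value < 0.5) == (p_perm < 0.5) or abs(p_perm - 0.5) < 0.1


def test_auc_ci_examples():
    assert auc_ci(0.7, 0.0) == (0.7, 0.7)
    lo, hi = auc_ci(0.5, 0.0025)
    assert (lo, hi) == pytest.approx((0.402, 0.598), abs=5e-4)
    assert auc_ci(0.99, 0.01)[1] == 1.0    # truncation


def test_auc_with_ci_result_invariants(rng):
    scores = rng.random(200)
    labels = rng.random(200) < 0.3
    res = auc_with_ci(scores, labels)
    assert res.ci_low <= res.auc <= res.ci_high
    assert res.n_pos == labels.sum() and res.n_neg == (~labels).sum()


def test_roc_points_monotone(rng):
    scores = rng.random(100)
    labels = rng.random(100) < 0.4
    pts = roc_points(scores, labels)
    assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
    assert pts[-1, 0] == 1.0 and pts[-1, 1] == 1.0


def test_auc_stable_across_seeds_on_model_consistent_cohorts(m6np_like):
    """Model-generated cohorts of n=20000: AUC varies by <0.01 across seeds
    and matches the ground-truth-probability AUC."""
    from pulvalid import generate_from_model
    aucs = []
    for seed in (1, 2, 3):
        cohort, truth = generate_from_model(m6np_like, n=20000, seed=seed)
        y = np.array([r.outcome == "ep" for r in cohort])
        p_ep = truth.ep_probabilities()
        aucs.append(auc_mann_whitney(p_ep[y], p_ep[~y]))
    assert max(aucs) - min(aucs) < 0.01
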