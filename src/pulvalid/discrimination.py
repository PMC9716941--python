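"""ROC discrimination: Mann-Whitney AUC, DeLong variance and paired test.

The AUC is the probability that a randomly chosen EP gets a higher predicted
risk than a randomly chosen non-EP, with ties counting one half (the
Mann-Whitney identity).  Variances and the paired two-model test use the
structural-components construction: each positive contributes a placement
value V10 (its mean win rate against the negatives), each negative a V01,
and the AUC variance is var(V10)/n_pos + var(V01)/n_neg.  Computation is
O(n log n) via midranks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


class DegenerateInputError(ValueError):
    """Input lacks the variation needed for the requested statistic."""


@dataclass(frozen=True)
class AUCResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    degenerate_variance: bool = False

    def __post_init__(self) -> None:
        assert self.n_pos >= 1 and self.n_neg >= 1
        assert self.ci_low <= self.auc <= self.ci_high


@dataclass(frozen=True)
class PairedAUCTest:
    auc_a: float
    auc_b: float
    difference: float
    z_statistic: float
    p_value: float
    covariance: float


def _check_classes(pos_scores, neg_scores) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("both score classes must be nonempty")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation placement components (V10 for positives, V01 for
    negatives), midrank convention for ties."""
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    ranks = rankdata(all_scores)           # midranks
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m
    return v10, v01


def auc_mann_whitney(pos_scores, neg_scores) -> float:
    """AUC as the mean pairwise win rate of positives over negatives."""
    pos, neg = _check_classes(pos_scores, neg_scores)
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def delong_components_and_variance(pos_scores, neg_scores) -> tuple[float, float]:
    """AUC and its DeLong variance.

    Needs at least two observations per class for a nonzero variance;
    perfect separation gives variance 0 with a degenerate-variance warning.
    """
    pos, neg = _check_classes(pos_scores, neg_scores)
    if pos.size < 2 or neg.size < 2:
        raise DegenerateInputError(
            "need >= 2 positives and >= 2 negatives for a variance estimate"
        )
    v10, v01 = _placements(pos, neg)
    variance = float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)
    auc = float(v10.mean())
    if variance == 0.0:
        warnings.warn("degenerate DeLong variance (all placement components equal)",
                      stacklevel=2)
    return auc, variance


def auc_ci(auc: float, variance: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the AUC scale, truncated to [0, 1]."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variance)
    return (max(0.0, auc - half), min(1.0, auc + half))


def auc_with_ci(scores, labels, level: float = 0.95) -> AUCResult:
    """Convenience wrapper: AUC, DeLong variance and Wald CI from scores
    plus binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    auc, var = delong_components_and_variance(pos, neg)
    lo, hi = auc_ci(auc, var, level)
    return AUCResult(auc=auc, variance=var, ci_low=lo, ci_high=hi,
                     n_pos=int(pos.size), n_neg=int(neg.size),
                     degenerate_variance=(var == 0.0))


def delong_paired_test(scores_a, scores_b, labels) -> PairedAUCTest:
    """DeLong's test for the AUC difference of two models on the same records.

    Identical score vectors short-circuit to z=0, p=1; any other
    zero-variance difference is an error rather than a spurious infinity.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must be aligned")
    pos_a, neg_a = a[labels], a[~labels]
    pos_b, neg_b = b[labels], b[~labels]
    if pos_a.size < 2 or neg_a.size < 2:
        raise DegenerateInputError("need >= 2 records in each outcome class")

    v10_a, v01_a = _placements(pos_a, neg_a)
    v10_b, v01_b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    m, n = pos_a.size, neg_a.size
    var_a = float(np.var(v10_a, ddof=1) / m + np.var(v01_a, ddof=1) / n)
    var_b = float(np.var(v10_b, ddof=1) / m + np.var(v01_b, ddof=1) / n)
    cov = float(np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
                + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n)

    diff = auc_a - auc_b
    var_diff = var_a + var_b - 2.0 * cov
    if np.array_equal(a, b) or (var_diff <= 0 and diff == 0.0):
        return PairedAUCTest(auc_a=auc_a, auc_b=auc_b, difference=float(diff),
                             z_statistic=0.0, p_value=1.0, covariance=cov)
    if var_diff <= 0:
        # degenerate separation (e.g. a perfect vs an anti-classifier):
        # the estimated uncertainty vanishes while the AUCs differ
        warnings.warn("degenerate variance of the AUC difference; "
                      "reporting the certainty limit", stacklevel=2)
        z = math.inf if diff > 0 else -math.inf
        return PairedAUCTest(auc_a=auc_a, auc_b=auc_b, difference=float(diff),
                             z_statistic=z, p_value=0.0, covariance=cov)
    z = diff / np.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return PairedAUCTest(auc_a=auc_a, auc_b=auc_b, difference=float(diff),
                         z_statistic=float(z), p_value=min(1.0, p), covariance=cov)


def roc_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) pairs over all score thresholds, for external plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tpr = tps[distinct] / max(1, labels.sum())
    fpr = fps[distinct] / max(1, (~labels).sum())
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
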