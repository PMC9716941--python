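"""Threshold classification accuracy and McNemar paired comparisons.

At a risk threshold a PUL is called high risk of EP when the predicted EP
probability reaches the threshold.  The reported measures follow the
validation literature for this model family: sensitivity (EP called high
risk), false positive rate (non-EP called high risk), negative predictive
value (non-EP among the low-risk calls) and the proportion classified low
risk, each with a Wilson score 95% CI.  Paired model comparisons use
McNemar's test on the discordant classifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2
from statsmodels.stats.proportion import proportion_confint

#: discordant-pair count at or above which the chi-square approximation
#: (with continuity correction) replaces the exact binomial test.
MCNEMAR_EXACT_LIMIT = 25

DEFAULT_THRESHOLDS = (0.025, 0.05, 0.10)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def __post_init__(self) -> None:
        assert min(self.tp, self.fp, self.tn, self.fn) >= 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Proportion:
    """A proportion with its Wilson 95% CI; undefined when the denominator
    is zero (estimate and CI are then None, never silently 0)."""

    numerator: int
    denominator: int
    estimate: float | None
    ci: tuple[float, float] | None

    @property
    def defined(self) -> bool:
        return self.estimate is not None


@dataclass(frozen=True)
class AccuracyMeasures:
    sensitivity: Proportion
    fpr: Proportion
    npv: Proportion
    pct_low_risk: Proportion
    counts: ConfusionCounts


@dataclass(frozen=True)
class McNemarResult:
    b: int                  # A high, B low
    c: int                  # A low, B high
    p_value: float
    method: str             # "exact" | "chi2_cc" | "no_discordance"
    restricted_to: str


def wilson_proportion(k: int, n: int, level: float = 0.95) -> Proportion:
    if n == 0:
        return Proportion(numerator=k, denominator=0, estimate=None, ci=None)
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    est = k / n
    # analytic Wilson bounds always bracket the estimate; guard round-off
    lo = min(max(0.0, float(lo)), est)
    hi = max(min(1.0, float(hi)), est)
    return Proportion(numerator=k, denominator=n, estimate=est, ci=(lo, hi))


def confusion_at_threshold(p_ep, ep_flags, threshold: float) -> ConfusionCounts:
    """Confusion counts with the high-risk rule p_ep >= threshold."""
    p = np.asarray(p_ep, dtype=float)
    y = np.asarray(ep_flags, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("p_ep and ep_flags must be aligned")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    high = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(high & y)),
        fp=int(np.sum(high & ~y)),
        tn=int(np.sum(~high & ~y)),
        fn=int(np.sum(~high & y)),
        threshold=threshold,
    )


def accuracy_measures(counts: ConfusionCounts) -> AccuracyMeasures:
    """Sensitivity, FPR, NPV and percent-low-risk with Wilson CIs."""
    return AccuracyMeasures(
        sensitivity=wilson_proportion(counts.tp, counts.tp + counts.fn),
        fpr=wilson_proportion(counts.fp, counts.fp + counts.tn),
        npv=wilson_proportion(counts.tn, counts.tn + counts.fn),
        pct_low_risk=wilson_proportion(counts.tn + counts.fn, counts.n),
        counts=counts,
    )


def accuracy_table(p_ep, ep_flags, thresholds=DEFAULT_THRESHOLDS) -> dict[float, AccuracyMeasures]:
    return {t: accuracy_measures(confusion_at_threshold(p_ep, ep_flags, t))
            for t in thresholds}


def accuracy_table_frame(table: dict[float, AccuracyMeasures]) -> pd.DataFrame:
    """Flat per-threshold table (point estimate + CI per measure)."""
    rows = []
    for thr, m in sorted(table.items()):
        for name, prop in [("sensitivity", m.sensitivity), ("fpr", m.fpr),
                           ("npv", m.npv), ("pct_low_risk", m.pct_low_risk)]:
            rows.append({
                "threshold": thr,
                "measure": name,
                "numerator": prop.numerator,
                "denominator": prop.denominator,
                "estimate": prop.estimate,
                "ci_low": prop.ci[0] if prop.ci else None,
                "ci_high": prop.ci[1] if prop.ci else None,
            })
    return pd.DataFrame(rows)


def write_accuracy_csv(table: dict[float, AccuracyMeasures], path: str | Path) -> None:
    accuracy_table_frame(table).to_csv(Path(path), index=False)


def mcnemar_paired(high_a, high_b, restrict_to: str = "all",
                   ep_flags=None) -> McNemarResult:
    """McNemar's test on discordant high-risk calls of two models.

    ``restrict_to='positives'`` compares the models' sensitivities (EP
    records only), ``'negatives'`` their FPRs.  Exact two-sided binomial
    p-value when the discordant total is below ``MCNEMAR_EXACT_LIMIT``,
    chi-square with continuity correction otherwise; zero discordance gives
    p = 1 by convention.
    """
    a = np.asarray(high_a, dtype=bool)
    b = np.asarray(high_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("high_a and high_b must be aligned")
    if restrict_to not in ("all", "positives", "negatives"):
        raise ValueError(f"unknown restriction {restrict_to!r}")
    if restrict_to != "all":
        if ep_flags is None:
            raise ValueError("ep_flags required when restricting the comparison")
        y = np.asarray(ep_flags, dtype=bool)
        if y.shape != a.shape:
            raise ValueError("ep_flags must be aligned with the classifications")
        mask = y if restrict_to == "positives" else ~y
        a, b = a[mask], b[mask]

    nb = int(np.sum(a & ~b))
    nc = int(np.sum(~a & b))
    total = nb + nc
    if total == 0:
        return McNemarResult(b=nb, c=nc, p_value=1.0, method="no_discordance",
                             restricted_to=restrict_to)
    if total < MCNEMAR_EXACT_LIMIT:
        p = min(1.0, 2.0 * float(binom.cdf(min(nb, nc), total, 0.5)))
        method = "exact"
    else:
        stat = (abs(nb - nc) - 1.0) ** 2 / total
        p = float(chi2.sf(stat, df=1))
        method = "chi2_cc"
    return McNemarResult(b=nb, c=nc, p_value=p, method=method,
                         restricted_to=restrict_to)
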