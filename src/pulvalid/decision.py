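"""Decision-curve analysis: net benefit of a model versus treat-all/none.

The net benefit at a risk threshold pt is the true-positive rate minus the
false-positive rate weighted by the odds pt/(1-pt); the weight encodes the
number of false positives a clinician accepts per true positive (19:1 at a
5% threshold).  A model has clinical utility at a threshold only when its
net benefit exceeds both default strategies (classify everyone high risk,
classify no one high risk).  Net benefit is reported per patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import ConfusionCounts, confusion_at_threshold

DEFAULT_GRID = np.round(np.arange(0.01, 0.501, 0.01), 10)


@dataclass(frozen=True)
class NetBenefitPoint:
    threshold: float
    nb_model: float
    nb_all: float
    nb_none: float = 0.0
    has_utility: bool = False


@dataclass(frozen=True)
class DecisionCurve:
    model_name: str
    points: tuple[NetBenefitPoint, ...]

    def __post_init__(self) -> None:
        thr = [p.threshold for p in self.points]
        assert all(0.0 < t < 1.0 for t in thr), "grid must lie in (0, 1)"
        assert all(b > a for a, b in zip(thr, thr[1:])), "grid must be strictly increasing"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": [p.threshold for p in self.points],
             "nb_model": [p.nb_model for p in self.points],
             "nb_all": [p.nb_all for p in self.points],
             "nb_none": [p.nb_none for p in self.points],
             "has_utility": [p.has_utility for p in self.points]}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def threshold_weight(pt: float) -> float:
    """Odds weight pt/(1-pt); its reciprocal is the accepted number of false
    positives per true positive."""
    if not (0.0 < pt < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {pt}")
    return pt / (1.0 - pt)


def net_benefit(counts: ConfusionCounts, n: int, pt: float) -> float:
    """nb = tp/n - (fp/n) * pt/(1-pt)."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if counts.n != n:
        raise ValueError(f"confusion counts total {counts.n} != cohort size {n}")
    return counts.tp / n - (counts.fp / n) * threshold_weight(pt)


def nb_treat_all(prevalence: float, pt: float) -> float:
    """Net benefit of classifying every record high risk; crosses zero
    exactly at pt = prevalence."""
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must be in [0, 1]")
    return prevalence - (1.0 - prevalence) * threshold_weight(pt)


def decision_curve(p_ep, ep_flags, grid=DEFAULT_GRID,
                   model_name: str = "model") -> DecisionCurve:
    """Net benefit of the model versus the default strategies over a
    threshold grid."""
    p = np.asarray(p_ep, dtype=float)
    y = np.asarray(ep_flags, dtype=bool)
    if p.size == 0:
        raise ValueError("empty cohort")
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0.0) | (grid >= 1.0)):
        raise ValueError("grid thresholds must lie in (0, 1)")
    n = p.size
    prevalence = float(y.mean())
    points = []
    for pt in grid:
        counts = confusion_at_threshold(p, y, float(pt))
        nb = net_benefit(counts, n, float(pt))
        nb_all = nb_treat_all(prevalence, float(pt))
        points.append(NetBenefitPoint(
            threshold=float(pt), nb_model=nb, nb_all=nb_all,
            has_utility=bool(nb > max(nb_all, 0.0)),
        ))
    return DecisionCurve(model_name=model_name, points=tuple(points))
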