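"""Seeded synthetic PUL cohort generator.

Two modes:

* **descriptive** (:func:`generate_cohort`) — emulates the marginal
  structure of a real emergency-unit PUL validation cohort: outcome mix
  461/362/238 (failed PUL / IUP / EP, with 46 of the EP persisting PUL) out
  of 1061, first hCG log-normal with median 703 IU/L and quartiles 210/2312,
  hCG ratio log-normal within each outcome class (declining for failed PUL,
  roughly doubling for IUP, near-plateau for EP) tuned so the mixture median
  is about 0.94, and a 13/71/16% split of sampling intervals over the
  24-39 / 40-56 / 57-72 h bins.

* **model-consistent** (:func:`generate_from_model`) — draws each record's
  outcome from the predicted probabilities of a given model, so the model is
  perfectly calibrated on its own data by construction.  This gives
  downstream validation a known ground truth (slope 1, intercept 0,
  recoverable AUC).

All randomness flows from a single integer seed through named spawned
sub-streams, so outputs are reproducible and adding a sampler does not
perturb unrelated fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .cohort import Cohort, PULRecord
from .models import ModelSpec, OUTCOME_ORDER, predict_matrix

_CLASSES = ("failed_pul", "iup", "ep")

# stream names in a fixed order; indices into SeedSequence.spawn
_STREAMS = ("class", "hcg1", "ratio", "interval", "age",
            "bleeding", "prior_ep", "iud", "inpatient",
            "pul_type", "ppul", "outcome", "contamination")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass(frozen=True)
class GeneratorParams:
    """Distributions governing the synthetic cohort generator.

    Defaults (see :func:`default_params`) reproduce the descriptive
    statistics of a 1061-woman emergency-unit validation cohort.
    """

    n: int = 1061
    prevalences: tuple[float, float, float] = (461 / 1061, 362 / 1061, 238 / 1061)
    hcg1_log_median: float = math.log(703.0)
    hcg1_log_sigma: float = (math.log(2312.0) - math.log(210.0)) / (2 * norm.ppf(0.75))
    hcg1_range: tuple[float, float] = (7.0, 180_000.0)
    #: class-conditional log-normal hCG-ratio parameters (failed, iup, ep)
    ratio_log_median: tuple[float, float, float] = (
        math.log(0.51), math.log(2.0), math.log(0.95))
    ratio_log_sigma: tuple[float, float, float] = (0.50, 0.30, 0.55)
    ratio_range: tuple[float, float] = (0.06, 5.65)
    interval_bins: tuple[tuple[float, float], ...] = ((24.0, 39.0), (40.0, 56.0), (57.0, 72.0))
    interval_weights: tuple[float, ...] = (141 / 1061, 751 / 1061, 169 / 1061)
    age_median: float = 31.0
    age_sigma: float = (35.0 - 26.0) / (2 * norm.ppf(0.75))
    age_range: tuple[float, float] = (15.0, 49.0)
    bleeding_rate: float = 723 / 1061
    prior_ep_rate: float = 76 / 1061
    iud_rate: float = 30 / 1061
    inpatient_rate: float = 89 / 1061
    pul_type_rates: tuple[float, float, float] = (793 / 1061, 239 / 1061, 29 / 1061)
    ppul_fraction_of_ep: float = 46 / 238
    #: optional contamination appended after the main cohort (records with
    #: out-of-window sampling intervals, GTD or lost-to-follow-up outcomes)
    n_out_of_window: int = 0
    n_gtd: int = 0
    n_lost: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        if abs(sum(self.interval_weights) - 1.0) > 1e-9:
            raise ValueError("interval weights must sum to 1")
        if any(s <= 0 for s in self.ratio_log_sigma) or self.hcg1_log_sigma <= 0:
            raise ValueError("log-sigmas must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """True generating class per record, and the generating probability
    triples when the model-consistent mode was used."""

    ids: tuple[str, ...]
    true_class: tuple[str, ...]
    probabilities: np.ndarray | None = None   # (n, 3) in OUTCOME_ORDER

    def ep_probabilities(self) -> np.ndarray:
        if self.probabilities is None:
            raise ValueError("no generating probabilities (descriptive mode)")
        return self.probabilities[:, 2]


def default_params(seed: int = 0, n: int = 1061) -> GeneratorParams:
    """Generator parameters matched to the reference validation cohort's
    marginals (outcome mix, hCG quartiles, interval mix, covariate rates)."""
    return GeneratorParams(n=n, seed=seed)


def _sample_covariates(params: GeneratorParams, n: int, rngs) -> dict[str, np.ndarray]:
    log_h1 = rngs["hcg1"].normal(params.hcg1_log_median, params.hcg1_log_sigma, n)
    hcg1 = np.clip(np.exp(log_h1), *params.hcg1_range)
    bins = rngs["interval"].choice(len(params.interval_bins), size=n,
                                   p=np.asarray(params.interval_weights))
    lo = np.array([params.interval_bins[b][0] for b in bins])
    hi = np.array([params.interval_bins[b][1] for b in bins])
    interval = lo + rngs["interval"].random(n) * (hi - lo)
    age = np.clip(rngs["age"].normal(params.age_median, params.age_sigma, n),
                  *params.age_range)
    return {
        "hcg1": hcg1,
        "interval": interval,
        "age": age,
        "bleeding": rngs["bleeding"].random(n) < params.bleeding_rate,
        "prior_ep": rngs["prior_ep"].random(n) < params.prior_ep_rate,
        "iud": rngs["iud"].random(n) < params.iud_rate,
        "inpatient": rngs["inpatient"].random(n) < params.inpatient_rate,
        "pul_type": rngs["pul_type"].choice(
            ("true_pul", "probable_iup", "probable_ep"), size=n,
            p=np.asarray(params.pul_type_rates)),
    }


def _sample_ratio_for_classes(params: GeneratorParams, classes: np.ndarray,
                              rng) -> np.ndarray:
    mu = np.asarray(params.ratio_log_median)[classes]
    sig = np.asarray(params.ratio_log_sigma)[classes]
    ratio = np.exp(rng.normal(mu, sig))
    return np.clip(ratio, *params.ratio_range)


def _build_records(ids, cov, hcg2, outcomes) -> list[PULRecord]:
    return [
        PULRecord(
            id=ids[i],
            age=float(cov["age"][i]),
            hcg1=float(cov["hcg1"][i]),
            hcg2=float(hcg2[i]),
            interval_hours=float(cov["interval"][i]),
            vaginal_bleeding=bool(cov["bleeding"][i]),
            prior_ep=bool(cov["prior_ep"][i]),
            iud=bool(cov["iud"][i]),
            inpatient=bool(cov["inpatient"][i]),
            pul_type=str(cov["pul_type"][i]),
            outcome=outcomes[i],
        )
        for i in range(len(ids))
    ]


def _contaminate(params: GeneratorParams, rngs, start_index: int) -> list[PULRecord]:
    """Optional appended records outside the analysis population."""
    extra: list[PULRecord] = []
    rng = rngs["contamination"]
    k = params.n_out_of_window + params.n_gtd + params.n_lost
    if k == 0:
        return extra
    classes = rng.choice(3, size=k, p=np.asarray(params.prevalences))
    cov = _sample_covariates(replace(params, seed=params.seed), k, rngs)
    ratio = _sample_ratio_for_classes(params, classes, rng)
    hcg2 = cov["hcg1"] * ratio
    for j in range(k):
        idx = start_index + j
        if j < params.n_out_of_window:
            outcome = _CLASSES[classes[j]]
            interval = float(rng.uniform(8.0, 23.0) if rng.random() < 0.5
                             else rng.uniform(73.0, 168.0))
        else:
            outcome = "gtd" if j < params.n_out_of_window + params.n_gtd else "lost"
            interval = float(cov["interval"][j])
        extra.append(PULRecord(
            id=f"S{idx:06d}", age=float(cov["age"][j]),
            hcg1=float(cov["hcg1"][j]), hcg2=float(hcg2[j]),
            interval_hours=interval,
            vaginal_bleeding=bool(cov["bleeding"][j]),
            prior_ep=bool(cov["prior_ep"][j]), iud=bool(cov["iud"][j]),
            inpatient=bool(cov["inpatient"][j]),
            pul_type=str(cov["pul_type"][j]), outcome=outcome,
        ))
    return extra


def generate_cohort(params: GeneratorParams | None = None,
                    seed: int | None = None) -> tuple[Cohort, GroundTruth]:
    """Descriptive-mode cohort: outcome classes from the prevalence mixture,
    hCG dynamics from the class-conditional ratio distributions."""
    params = params or default_params()
    if seed is not None:
        params = replace(params, seed=seed)
    rngs = _rngs(params.seed)
    n = params.n
    classes = rngs["class"].choice(3, size=n, p=np.asarray(params.prevalences))
    cov = _sample_covariates(params, n, rngs)
    ratio = _sample_ratio_for_classes(params, classes, rngs["ratio"])
    hcg2 = cov["hcg1"] * ratio

    outcomes = [_CLASSES[c] for c in classes]
    is_ep = classes == 2
    ppul_draw = rngs["ppul"].random(n) < params.ppul_fraction_of_ep
    for i in np.nonzero(is_ep & ppul_draw)[0]:
        outcomes[i] = "ppul"

    ids = [f"S{i:06d}" for i in range(n)]
    records = _build_records(ids, cov, hcg2, outcomes)
    records += _contaminate(params, rngs, start_index=n)
    cohort = Cohort.from_records(records, provenance=f"synthetic descriptive seed={params.seed}")
    truth = GroundTruth(ids=tuple(ids), true_class=tuple(_CLASSES[c] for c in classes))
    return cohort, truth


def generate_from_model(spec: ModelSpec, covariate_params: GeneratorParams | None = None,
                        n: int | None = None, seed: int | None = None
                        ) -> tuple[Cohort, GroundTruth]:
    """Model-consistent cohort: covariates as in descriptive mode (ratio from
    the marginal mixture, not conditioned on outcome), outcomes drawn from
    the model's predicted probabilities."""
    params = covariate_params or default_params()
    if n is not None:
        params = replace(params, n=n)
    if seed is not None:
        params = replace(params, seed=seed)
    rngs = _rngs(params.seed)
    n = params.n
    cov = _sample_covariates(params, n, rngs)
    mix_classes = rngs["class"].choice(3, size=n, p=np.asarray(params.prevalences))
    ratio = _sample_ratio_for_classes(params, mix_classes, rngs["ratio"])
    hcg2 = cov["hcg1"] * ratio

    probs = predict_matrix(spec, cov["hcg1"], hcg2)
    u = rngs["outcome"].random(n)
    drawn = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    outcomes = [OUTCOME_ORDER[c] for c in drawn]

    ids = [f"M{i:06d}" for i in range(n)]
    records = _build_records(ids, cov, hcg2, outcomes)
    cohort = Cohort.from_records(
        records, provenance=f"synthetic model-consistent spec={spec.name!r} seed={params.seed}")
    truth = GroundTruth(ids=tuple(ids), true_class=tuple(outcomes),
                        probabilities=probs)
    return cohort, truth


def adjudicate_ppul(values, times_days) -> bool:
    """Plateau adjudication for persisting PUL.

    True iff some run of at least three consecutive hCG values, spanning at
    most 7 days, has every successive relative change below 15% of the
    preceding value.  Fewer than three measurements cannot plateau.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times_days, dtype=float)
    if values.shape != times.shape:
        raise ValueError("values and times must be aligned")
    if np.any(np.diff(times) < 0):
        raise ValueError("timestamps must be nondecreasing")
    k = values.size
    if k < 3:
        return False
    flat = np.abs(np.diff(values)) / values[:-1] < 0.15
    for start in range(k - 2):
        for stop in range(start + 2, k):
            if times[stop] - times[start] > 7.0:
                break
            if np.all(flat[start:stop]):
                return True
    return False
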