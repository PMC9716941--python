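"""Config-driven multinomial logistic risk models for PUL triage.

The triage models of the M4/M6 family are polynomial multinomial logistic
regressions on the two serum hCG values, predicting the probabilities of the
three PUL outcomes (failed PUL, IUP, EP) with failed PUL as the reference
class.  Coefficients are never hard-coded here: they are loaded from a JSON
config transcribed from the published equations, so the whole validation
machinery is coefficient-agnostic.  The configs shipped under
``pulvalid/configs`` are synthetic placeholders with the published models'
functional form but coefficients derived from this package's own cohort
simulator; see their ``note`` fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

OUTCOME_ORDER = ("failed_pul", "iup", "ep")


class ConfigError(ValueError):
    """Malformed or unknown-key model configuration."""


class NumericError(ArithmeticError):
    """Non-finite quantity produced during prediction."""


# Basis functions map (hcg1, hcg2) arrays to a predictor column.  Natural
# logarithms throughout; any base change is absorbable into coefficients.
BASIS_FUNCTIONS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "intercept": lambda h1, h2: np.ones_like(h1),
    "log_hcg1": lambda h1, h2: np.log(h1),
    "log_hcg1_sq": lambda h1, h2: np.log(h1) ** 2,
    "log_ratio": lambda h1, h2: np.log(h2 / h1),
    "log_ratio_sq": lambda h1, h2: np.log(h2 / h1) ** 2,
    "log_hcg1_x_log_ratio": lambda h1, h2: np.log(h1) * np.log(h2 / h1),
}


@dataclass(frozen=True)
class OutcomeLogit:
    """Linear predictor for one non-reference outcome: sum of coeff * basis."""

    outcome: str
    terms: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.terms]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate basis function in logit {self.outcome!r}")
        for n in names:
            if n not in BASIS_FUNCTIONS:
                raise ConfigError(
                    f"unknown basis function {n!r} in logit {self.outcome!r}; "
                    f"known: {sorted(BASIS_FUNCTIONS)}"
                )


@dataclass(frozen=True)
class ModelSpec:
    """A named triage model: one logit per non-reference outcome.

    ``reference_outcome`` is always failed PUL (its logit is identically 0).
    """

    name: str
    logits: tuple[OutcomeLogit, ...]
    reference_outcome: str = "failed_pul"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("model name must be nonempty")
        if self.reference_outcome != "failed_pul":
            raise ConfigError("reference outcome must be failed_pul")
        labels = sorted(l.outcome for l in self.logits)
        if labels != ["ep", "iup"]:
            raise ConfigError(f"expected exactly the logits ['ep', 'iup'], got {labels}")

    def logit_for(self, outcome: str) -> OutcomeLogit:
        for l in self.logits:
            if l.outcome == outcome:
                return l
        raise KeyError(outcome)

    # ---- JSON config round-trip -------------------------------------------

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ModelSpec":
        allowed = {"name", "reference", "logits", "note"}
        unknown = set(payload) - allowed
        if unknown:
            raise ConfigError(f"unknown keys in model config: {sorted(unknown)}")
        if "name" not in payload or "logits" not in payload:
            raise ConfigError("model config requires 'name' and 'logits'")
        reference = payload.get("reference", "failed_pul")
        logits = []
        for outcome, terms in payload["logits"].items():
            if not isinstance(terms, Mapping):
                raise ConfigError(f"logit {outcome!r} must map basis name -> coefficient")
            logits.append(
                OutcomeLogit(outcome=outcome,
                             terms=tuple((str(k), float(v)) for k, v in terms.items()))
            )
        return cls(name=str(payload["name"]), logits=tuple(logits),
                   reference_outcome=reference, note=str(payload.get("note", "")))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "reference": self.reference_outcome,
            "logits": {l.outcome: {n: c for n, c in l.terms} for l in self.logits},
        }
        if self.note:
            d["note"] = self.note
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelSpec":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ConfigError(f"invalid JSON in model config {path}: {e}") from e
        return cls.from_dict(payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class ProbabilityTriple:
    """Predicted probabilities of (failed PUL, IUP, EP); sums to 1."""

    p_failed: float
    p_iup: float
    p_ep: float

    def __post_init__(self) -> None:
        for v in (self.p_failed, self.p_iup, self.p_ep):
            if not (0.0 < v < 1.0) and not math.isclose(v, 0.0) and not math.isclose(v, 1.0):
                raise NumericError(f"probability {v} outside [0, 1]")
        if abs(self.p_failed + self.p_iup + self.p_ep - 1.0) > 1e-12:
            raise NumericError("probabilities do not sum to 1 within 1e-12")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_failed, self.p_iup, self.p_ep)


def _eta_matrix(spec: ModelSpec, hcg1: np.ndarray, hcg2: np.ndarray) -> np.ndarray:
    """(n, 3) linear predictors in OUTCOME_ORDER; reference column is 0."""
    n = hcg1.shape[0]
    eta = np.zeros((n, 3))
    for col, outcome in enumerate(OUTCOME_ORDER[1:], start=1):
        logit = spec.logit_for(outcome)
        acc = np.zeros(n)
        for name, coeff in logit.terms:
            acc += coeff * BASIS_FUNCTIONS[name](hcg1, hcg2)
        eta[:, col] = acc
    return eta


def linear_predictor(record, logit_spec: OutcomeLogit) -> float:
    """Evaluate one outcome's linear predictor for a single record."""
    h1 = np.asarray([record.hcg1], dtype=float)
    h2 = np.asarray([record.hcg2], dtype=float)
    eta = 0.0
    for name, coeff in logit_spec.terms:
        eta += coeff * float(BASIS_FUNCTIONS[name](h1, h2)[0])
    return eta


def softmax_triples(eta: np.ndarray) -> np.ndarray:
    """Row-wise softmax of an (n, 3) logit matrix, numerically stable."""
    shifted = eta - eta.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=1, keepdims=True)


def predict_matrix(spec: ModelSpec, hcg1, hcg2) -> np.ndarray:
    """Vectorised prediction: (n, 3) probabilities in OUTCOME_ORDER."""
    h1 = np.asarray(hcg1, dtype=float)
    h2 = np.asarray(hcg2, dtype=float)
    eta = _eta_matrix(spec, h1, h2)
    if not np.all(np.isfinite(eta)):
        bad = int(np.argwhere(~np.isfinite(eta))[0, 0])
        raise NumericError(f"non-finite linear predictor at row {bad}")
    return softmax_triples(eta)


def predict_probabilities(record, spec: ModelSpec) -> ProbabilityTriple:
    """Predicted (failed PUL, IUP, EP) probabilities for one record."""
    h1 = np.asarray([record.hcg1], dtype=float)
    h2 = np.asarray([record.hcg2], dtype=float)
    eta = _eta_matrix(spec, h1, h2)
    if not np.all(np.isfinite(eta)):
        raise NumericError(f"non-finite linear predictor for record {record.id!r}")
    p = softmax_triples(eta)[0]
    return ProbabilityTriple(p_failed=float(p[0]), p_iup=float(p[1]), p_ep=float(p[2]))


def predict_cohort(cohort, spec: ModelSpec) -> np.ndarray:
    """(n, 3) probability matrix for every record of a cohort, in order."""
    h1 = np.array([r.hcg1 for r in cohort], dtype=float)
    h2 = np.array([r.hcg2 for r in cohort], dtype=float)
    return predict_matrix(spec, h1, h2)


def classify_risk(p_ep: float, threshold: float) -> str:
    """High/low risk call: high iff the predicted EP probability reaches the
    threshold (>=)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return "high" if p_ep >= threshold else "low"


def predicted_outcome(triple: ProbabilityTriple) -> str:
    """Most probable outcome; ties broken failed_pul < iup < ep."""
    probs = triple.as_tuple()
    best = max(probs)
    for label, p in zip(OUTCOME_ORDER, probs):
        if p == best:
            return label
    raise AssertionError("unreachable")


def builtin_config_path(name: str) -> Path:
    """Path of a shipped placeholder model config ('m6np_like' or 'm4_like')."""
    path = Path(__file__).parent / "configs" / f"{name}_synthetic.json"
    if not path.exists():
        raise ConfigError(f"no builtin config named {name!r}")
    return path


def load_builtin(name: str) -> ModelSpec:
    return ModelSpec.from_json(builtin_config_path(name))
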