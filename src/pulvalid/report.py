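"""End-to-end validation pipeline and structured reporting.

``run_validate`` executes the full battery on a cohort for one or two
models: inclusion filtering, prediction, ROC discrimination, calibration
(intercept, slope, loess curve), threshold classification with paired
McNemar comparisons, and decision-curve analysis.  Results are gathered in a
:class:`ValidationReport` and can be persisted as JSON plus flat CSV
artifacts (accuracy table, calibration curve, decision curve per model).
``run_sensitivity_analysis`` repeats the run without the sampling-interval
filter and tabulates the deltas.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (CalibrationCurve, CalibrationSummary,
                          calibration_summary, loess_calibration_curve)
from .classification import (DEFAULT_THRESHOLDS, accuracy_table,
                             accuracy_table_frame, mcnemar_paired)
from .cohort import (Cohort, ExclusionLog, apply_inclusion_criteria,
                     dichotomize_outcome, outcome_counts, read_cohort_csv)
from .decision import DEFAULT_GRID, decision_curve
from .discrimination import AUCResult, auc_with_ci, delong_paired_test
from .models import ModelSpec, predict_cohort


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one validation run."""

    cohort_path: str | None = None
    model_paths: tuple[str, ...] = ()
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    loess_span: float = 0.75
    loess_degree: int = 1
    grid: tuple[float, ...] = tuple(DEFAULT_GRID)
    min_hours: float = 24.0
    max_hours: float = 72.0
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.thresholds:
            if not (0.0 < t < 1.0):
                raise ValueError(f"threshold {t} outside (0, 1)")


@dataclass
class ModelResults:
    name: str
    auc: AUCResult
    calibration: CalibrationSummary
    curve: CalibrationCurve
    accuracy: dict
    decision: object
    p_ep: np.ndarray


@dataclass
class ValidationReport:
    n: int
    outcome_counts: dict[str, int]
    ep_prevalence: float
    exclusion_counts: dict[str, int]
    models: list[ModelResults]
    paired_auc: dict | None = None
    mcnemar: dict | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        payload = {
            "cohort": {
                "n": self.n,
                "outcome_counts": self.outcome_counts,
                "ep_prevalence": self.ep_prevalence,
                "exclusions": self.exclusion_counts,
            },
            "models": {},
            "metadata": self.metadata,
        }
        for m in self.models:
            payload["models"][m.name] = {
                "auc": {"auc": m.auc.auc, "variance": m.auc.variance,
                        "ci": [m.auc.ci_low, m.auc.ci_high],
                        "n_pos": m.auc.n_pos, "n_neg": m.auc.n_neg},
                "calibration": {
                    "citl": m.calibration.citl, "citl_ci": list(m.calibration.citl_ci),
                    "slope": m.calibration.slope, "slope_ci": list(m.calibration.slope_ci),
                    "mean_predicted": m.calibration.mean_predicted,
                    "observed_rate": m.calibration.observed_rate,
                },
                "accuracy": accuracy_table_frame(m.accuracy).to_dict(orient="records"),
            }
        if self.paired_auc is not None:
            payload["paired_auc"] = self.paired_auc
        if self.mcnemar is not None:
            payload["mcnemar"] = self.mcnemar
        return payload

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


class StageError(RuntimeError):
    """An error in a named pipeline stage, with context."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r}: {original}")
        self.stage = stage
        self.original = original


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_").lower()


def validate_models(cohort: Cohort, specs: list[ModelSpec],
                    thresholds=DEFAULT_THRESHOLDS, loess_span: float = 0.75,
                    loess_degree: int = 1, grid=DEFAULT_GRID,
                    min_hours: float = 24.0, max_hours: float = 72.0,
                    ) -> ValidationReport:
    """Run the complete validation battery in memory.

    Filtering happens first; all measures are computed on the retained
    cohort against the dichotomised EP outcome.
    """
    try:
        analysis, log = apply_inclusion_criteria(cohort, min_hours=min_hours,
                                                 max_hours=max_hours)
    except Exception as e:
        raise StageError("filter", e) from e
    if len(analysis) == 0:
        raise StageError("filter", ValueError("no records retained by inclusion criteria"))

    y = np.array([dichotomize_outcome(r.outcome) for r in analysis])
    results: list[ModelResults] = []
    for spec in specs:
        try:
            probs = predict_cohort(analysis, spec)
            p_ep = probs[:, 2]
        except Exception as e:
            raise StageError(f"predict[{spec.name}]", e) from e
        try:
            auc = auc_with_ci(p_ep, y)
        except Exception as e:
            raise StageError(f"discrimination[{spec.name}]", e) from e
        try:
            summary = calibration_summary(p_ep, y)
            curve = loess_calibration_curve(p_ep, y, span=loess_span,
                                            degree=loess_degree)
        except Exception as e:
            raise StageError(f"calibration[{spec.name}]", e) from e
        try:
            acc = accuracy_table(p_ep, y, thresholds)
            dc = decision_curve(p_ep, y, grid=grid, model_name=spec.name)
        except Exception as e:
            raise StageError(f"classification[{spec.name}]", e) from e
        results.append(ModelResults(name=spec.name, auc=auc, calibration=summary,
                                    curve=curve, accuracy=acc, decision=dc,
                                    p_ep=p_ep))

    paired = None
    mcn = None
    if len(results) == 2:
        a, b = results
        test = delong_paired_test(a.p_ep, b.p_ep, y)
        paired = {"model_a": a.name, "model_b": b.name,
                  "auc_a": test.auc_a, "auc_b": test.auc_b,
                  "difference": test.difference, "z": test.z_statistic,
                  "p_value": test.p_value}
        mcn = {}
        for t in thresholds:
            high_a = a.p_ep >= t
            high_b = b.p_ep >= t
            mcn[str(t)] = {
                restrict: {
                    "b": r.b, "c": r.c, "p_value": r.p_value, "method": r.method,
                }
                for restrict, r in [
                    ("positives", mcnemar_paired(high_a, high_b, "positives", y)),
                    ("negatives", mcnemar_paired(high_a, high_b, "negatives", y)),
                    ("all", mcnemar_paired(high_a, high_b, "all")),
                ]
            }

    counts = outcome_counts(analysis)
    return ValidationReport(
        n=len(analysis),
        outcome_counts=counts,
        ep_prevalence=float(y.mean()),
        exclusion_counts=log.counts,
        models=results,
        paired_auc=paired,
        mcnemar=mcn,
    )


def run_validate(config: RunConfig, cohort: Cohort | None = None,
                 specs: list[ModelSpec] | None = None) -> ValidationReport:
    """File-driven entry point: load cohort and model configs, validate,
    persist JSON + CSV artifacts under ``config.out_dir``."""
    if cohort is None:
        if config.cohort_path is None:
            raise StageError("load", ValueError("no cohort path or in-memory cohort given"))
        try:
            cohort = read_cohort_csv(config.cohort_path)
        except Exception as e:
            raise StageError("load", e) from e
    if specs is None:
        try:
            specs = [ModelSpec.from_json(p) for p in config.model_paths]
        except Exception as e:
            raise StageError("config", e) from e
    if not specs:
        raise StageError("config", ValueError("at least one model spec is required"))

    report = validate_models(cohort, specs, thresholds=config.thresholds,
                             loess_span=config.loess_span,
                             loess_degree=config.loess_degree,
                             grid=np.asarray(config.grid),
                             min_hours=config.min_hours,
                             max_hours=config.max_hours)
    report.metadata = {
        "seed": config.seed,
        "software_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "cohort_provenance": cohort.provenance,
        "config_hashes": {p: _hash_file(p) for p in config.model_paths
                          if Path(p).exists()},
        "thresholds": list(config.thresholds),
        "interval_window_hours": [config.min_hours, config.max_hours],
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        for m in report.models:
            tag = _safe_name(m.name)
            from .classification import write_accuracy_csv
            write_accuracy_csv(m.accuracy, out / f"accuracy_{tag}.csv")
            m.curve.to_csv(out / f"calibration_curve_{tag}.csv")
            m.decision.to_csv(out / f"decision_curve_{tag}.csv")
    return report


def _measure_rows(report: ValidationReport) -> pd.DataFrame:
    rows = []
    for m in report.models:
        for thr, meas in sorted(m.accuracy.items()):
            for name, prop in [("sensitivity", meas.sensitivity), ("fpr", meas.fpr),
                               ("npv", meas.npv), ("pct_low_risk", meas.pct_low_risk)]:
                rows.append({"model": m.name, "threshold": thr, "measure": name,
                             "estimate": prop.estimate})
        rows.append({"model": m.name, "threshold": None, "measure": "auc",
                     "estimate": m.auc.auc})
        rows.append({"model": m.name, "threshold": None, "measure": "citl",
                     "estimate": m.calibration.citl})
        rows.append({"model": m.name, "threshold": None, "measure": "slope",
                     "estimate": m.calibration.slope})
    return pd.DataFrame(rows)


def run_sensitivity_analysis(config: RunConfig, cohort: Cohort | None = None,
                             specs: list[ModelSpec] | None = None
                             ) -> tuple[ValidationReport, ValidationReport, pd.DataFrame]:
    """Run with the sampling-interval filter and without it (all intervals),
    returning both reports and a side-by-side delta table of all measures."""
    base = run_validate(config, cohort=cohort, specs=specs)
    open_config = RunConfig(
        cohort_path=config.cohort_path, model_paths=config.model_paths,
        thresholds=config.thresholds, loess_span=config.loess_span,
        loess_degree=config.loess_degree, grid=config.grid,
        min_hours=0.0, max_hours=float("inf"),
        out_dir=None, seed=config.seed,
    )
    full = run_validate(open_config, cohort=cohort, specs=specs)

    left = _measure_rows(base).rename(columns={"estimate": "windowed"})
    right = _measure_rows(full).rename(columns={"estimate": "all_intervals"})
    delta = left.merge(right, on=["model", "threshold", "measure"], how="outer")
    delta["delta"] = delta["all_intervals"] - delta["windowed"]
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        delta.to_csv(out / "sensitivity_delta.csv", index=False)
        full.to_json(out / "report_all_intervals.json")
    return base, full, delta
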