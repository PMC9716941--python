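"""Cohort data model, CSV I/O, inclusion filtering and outcome coding.

A PUL (pregnancy of unknown location) cohort is a list of women, each with
two serum hCG measurements taken 24-72 h apart, a handful of clinical flags,
an ultrasound-based PUL type, and a final adjudicated outcome.  The analysis
dichotomises the outcome into ectopic pregnancy (EP, including persisting
PUL) versus non-EP (intrauterine pregnancy or spontaneously failing PUL).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

PUL_TYPES = ("true_pul", "probable_iup", "probable_ep")
OUTCOMES = ("failed_pul", "iup", "ep", "ppul", "gtd", "lost")
#: outcomes that are legal in an analysis cohort (GTD and lost-to-follow-up
#: must be excluded before prediction).
ANALYSIS_OUTCOMES = ("failed_pul", "iup", "ep", "ppul")

INTERVAL_BINS = ("lt24", "24-39", "40-56", "57-72", "gt72")

RETAINED = "retained"
EXCLUDED_INTERVAL = "excluded_interval"
EXCLUDED_GTD = "excluded_gtd"
EXCLUDED_LOST = "excluded_lost"


class InvalidRecordError(ValueError):
    """A record field violates its domain constraint."""


@dataclass(frozen=True)
class PULRecord:
    """One woman's two-hCG presentation plus covariates and outcome.

    hCG values are serum concentrations in IU/L; ``interval_hours`` is the
    elapsed time between the two samples.
    """

    id: str
    age: float
    hcg1: float
    hcg2: float
    interval_hours: float
    vaginal_bleeding: bool = False
    prior_ep: bool = False
    iud: bool = False
    inpatient: bool = False
    pul_type: str = "true_pul"
    outcome: str = "failed_pul"

    def __post_init__(self) -> None:
        if not self.hcg1 > 0:
            raise InvalidRecordError(f"record {self.id!r}: hcg1 must be > 0, got {self.hcg1}")
        if not self.hcg2 > 0:
            raise InvalidRecordError(f"record {self.id!r}: hcg2 must be > 0, got {self.hcg2}")
        if not self.interval_hours > 0:
            raise InvalidRecordError(
                f"record {self.id!r}: interval_hours must be > 0, got {self.interval_hours}"
            )
        if self.pul_type not in PUL_TYPES:
            raise InvalidRecordError(f"record {self.id!r}: unknown pul_type {self.pul_type!r}")
        if self.outcome not in OUTCOMES:
            raise InvalidRecordError(f"record {self.id!r}: unknown outcome {self.outcome!r}")

    @property
    def hcg_ratio(self) -> float:
        return compute_hcg_ratio(self)


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of PUL records with a provenance label."""

    records: tuple[PULRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise InvalidRecordError(f"duplicate record ids in cohort: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_records(cls, records: Iterable[PULRecord], provenance: str = "") -> "Cohort":
        return cls(records=tuple(records), provenance=provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "age": [r.age for r in self.records],
                "hcg1": [r.hcg1 for r in self.records],
                "hcg2": [r.hcg2 for r in self.records],
                "interval_hours": [r.interval_hours for r in self.records],
                "bleeding": [int(r.vaginal_bleeding) for r in self.records],
                "prior_ep": [int(r.prior_ep) for r in self.records],
                "iud": [int(r.iud) for r in self.records],
                "inpatient": [int(r.inpatient) for r in self.records],
                "pul_type": [r.pul_type for r in self.records],
                "outcome": [r.outcome for r in self.records],
            }
        )


@dataclass
class ExclusionLog:
    """Per-record disposition of an inclusion-criteria pass.

    Dispositions partition the input cohort; counts always sum to the input
    size.  An empty retained cohort is legal and flagged.
    """

    dispositions: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = {k: 0 for k in (RETAINED, EXCLUDED_INTERVAL, EXCLUDED_GTD, EXCLUDED_LOST)}
        for d in self.dispositions.values():
            c[d] += 1
        return c

    @property
    def n_input(self) -> int:
        return len(self.dispositions)

    @property
    def empty_retained(self) -> bool:
        return self.counts[RETAINED] == 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": self.counts,
            "empty_retained": self.empty_retained,
            "dispositions": self.dispositions,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def compute_hcg_ratio(record: PULRecord) -> float:
    """Ratio of the second to the first serum hCG (the key dynamic predictor)."""
    if not record.hcg1 > 0:
        raise InvalidRecordError(f"record {record.id!r}: hcg1 must be > 0")
    if not record.hcg2 > 0:
        raise InvalidRecordError(f"record {record.id!r}: hcg2 must be > 0")
    return record.hcg2 / record.hcg1


def interval_bin(interval_hours: float) -> str:
    """Bin a sampling interval into the descriptive-table categories.

    Boundaries are inclusive integer hours; the 40-56 h bin is the clinical
    48+/-8 h window.
    """
    if not interval_hours > 0:
        raise InvalidRecordError(f"interval_hours must be > 0, got {interval_hours}")
    if interval_hours < 24:
        return "lt24"
    if interval_hours < 40:
        return "24-39"
    if interval_hours <= 56:
        return "40-56"
    if interval_hours <= 72:
        return "57-72"
    return "gt72"


def apply_inclusion_criteria(
    cohort: Cohort,
    min_hours: float = 24.0,
    max_hours: float = 72.0,
    exclude_gtd: bool = True,
    exclude_lost: bool = True,
) -> tuple[Cohort, ExclusionLog]:
    """Filter a cohort to the analysis window and analysable outcomes.

    Defaults retain records with ``min_hours <= interval_hours <= max_hours``
    (both ends inclusive) and drop gestational trophoblastic disease and
    lost-to-follow-up records.  With ``min_hours=0, max_hours=inf`` only the
    outcome exclusions apply, which reproduces the all-intervals cohort used
    for sensitivity analysis.  Outcome exclusions take precedence over the
    interval exclusion when both apply.
    """
    log = ExclusionLog()
    kept: list[PULRecord] = []
    for r in cohort:
        if exclude_gtd and r.outcome == "gtd":
            log.dispositions[r.id] = EXCLUDED_GTD
        elif exclude_lost and r.outcome == "lost":
            log.dispositions[r.id] = EXCLUDED_LOST
        elif not (min_hours <= r.interval_hours <= max_hours):
            log.dispositions[r.id] = EXCLUDED_INTERVAL
        else:
            log.dispositions[r.id] = RETAINED
            kept.append(r)
    return Cohort.from_records(kept, provenance=cohort.provenance), log


def dichotomize_outcome(outcome: str) -> bool:
    """EP-positive coding: ep and ppul are positive, failed_pul and iup negative.

    Persisting PUL counts as ectopic because it is managed as one; GTD and
    lost-to-follow-up records must be excluded before this point.
    """
    if outcome in ("ep", "ppul"):
        return True
    if outcome in ("failed_pul", "iup"):
        return False
    if outcome in OUTCOMES:
        raise InvalidRecordError(
            f"outcome {outcome!r} must be excluded before dichotomisation"
        )
    raise InvalidRecordError(f"unknown outcome {outcome!r}")


_CSV_COLUMNS = [
    "id", "age", "hcg1", "hcg2", "interval_hours",
    "bleeding", "prior_ep", "iud", "inpatient", "pul_type", "outcome",
]
_FLAG_COLUMNS = {"bleeding": "vaginal_bleeding", "prior_ep": "prior_ep",
                 "iud": "iud", "inpatient": "inpatient"}


def _parse_flag(value) -> bool:
    if pd.isna(value):
        raise ValueError("missing")
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("1", "true", "yes", "y"):
            return True
        if v in ("0", "false", "no", "n", ""):
            return False
        raise InvalidRecordError(f"unparseable flag value {value!r}")
    return bool(int(value))


def read_cohort_csv(path: str | Path, provenance: str | None = None) -> Cohort:
    """Read a cohort CSV.

    The interval may be given directly (``interval_hours``) or as two
    ISO-8601 datetime columns ``t1``/``t2``; an explicit interval takes
    precedence.  Missing covariate flags default to absent with a warning;
    hCG values and the interval may never be missing.
    """
    df = pd.read_csv(Path(path), dtype={"id": str})
    if "interval_hours" in df.columns:
        interval = pd.to_numeric(df["interval_hours"])
    elif {"t1", "t2"} <= set(df.columns):
        t1 = pd.to_datetime(df["t1"])
        t2 = pd.to_datetime(df["t2"])
        interval = (t2 - t1).dt.total_seconds() / 3600.0
    else:
        raise InvalidRecordError(
            "cohort CSV needs an interval_hours column or t1/t2 datetime columns"
        )
    for col in ("id", "hcg1", "hcg2", "pul_type", "outcome"):
        if col not in df.columns:
            raise InvalidRecordError(f"cohort CSV missing required column {col!r}")
        if df[col].isna().any():
            raise InvalidRecordError(f"cohort CSV has missing values in column {col!r}")
    if interval.isna().any():
        raise InvalidRecordError("cohort CSV has missing sampling intervals")

    records = []
    for i, row in df.iterrows():
        flags = {}
        for col, fieldname in _FLAG_COLUMNS.items():
            if col in df.columns and not pd.isna(row[col]):
                flags[fieldname] = _parse_flag(row[col])
            else:
                warnings.warn(
                    f"record {row['id']!r}: covariate {col!r} missing, assuming absent",
                    stacklevel=2,
                )
                flags[fieldname] = False
        records.append(
            PULRecord(
                id=str(row["id"]),
                age=float(row["age"]) if "age" in df.columns and not pd.isna(row["age"]) else float("nan"),
                hcg1=float(row["hcg1"]),
                hcg2=float(row["hcg2"]),
                interval_hours=float(interval.iloc[i]),
                pul_type=str(row["pul_type"]),
                outcome=str(row["outcome"]),
                **flags,
            )
        )
    return Cohort.from_records(records, provenance=provenance or str(path))


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    cohort.to_frame().to_csv(Path(path), index=False, columns=_CSV_COLUMNS)


def outcome_counts(cohort: Cohort | Sequence[PULRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in cohort:
        counts[r.outcome] = counts.get(r.outcome, 0) + 1
    return counts


def relabel(record: PULRecord, **changes) -> PULRecord:
    """Return a copy of a record with fields replaced (validation re-runs)."""
    return replace(record, **changes)
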