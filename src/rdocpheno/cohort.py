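"""Admission-level cohort table and derived outcome variables.

The unit of the regression analyses is the *admission* (a patient may be
admitted more than once); baseline characteristics are tabulated at the
*patient* level by keeping each patient's chronologically first admission.
Length of stay is dichotomized at 3 days — under South Korea's Mental Health
Promotion and Welfare Act an involuntary psychiatric admission may last up to
3 days, so a stay strictly longer than 3 days marks a clinically serious
admission.  A stay of exactly 3 days is coded short (0), matching that legal
window.

No within-patient clustering correction is applied downstream; a warning is
logged when repeat patients are present so the analyst knows the regressions
treat admissions as independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DIAGNOSES",
    "FLAG_COLS",
    "COHORT_COLUMNS",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "los_binary",
    "to_patient_baseline",
    "join_scores",
]

logger = logging.getLogger(__name__)

DIAGNOSES = ("depression", "schizophrenia", "bipolar_disorder")
SEXES = ("female", "male")
FLAG_COLS = ("htn", "dm", "stroke", "renal", "pneumonia")
COHORT_COLUMNS = (
    "patient_id",
    "admission_id",
    "diagnosis",
    "age",
    "sex",
    "los_days",
    "cci",
    *FLAG_COLS,
)

#: Default dichotomization threshold for length of stay, in days.
LOS_THRESHOLD_DAYS = 3.0


@dataclass
class CohortTable:
    """A validated cohort at either admission or patient-baseline unit."""

    df: pd.DataFrame
    unit: str = "admission"

    def __post_init__(self):
        if self.unit not in ("admission", "patient_baseline"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        _validate(self.df)
        if self.unit == "patient_baseline" and self.df["patient_id"].duplicated().any():
            raise ValidationError("patient_baseline table has repeated patient_id")
        if self.unit == "admission" and self.df["patient_id"].duplicated().any():
            logger.warning(
                "cohort contains repeat admissions for %d patients; regressions treat admissions as independent",
                int(self.df["patient_id"].duplicated().sum()),
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in COHORT_COLUMNS and c != "los_gt3"]

    def groups(self) -> list[str]:
        return [d for d in DIAGNOSES if d in set(self.df["diagnosis"])]


def _bad(rows: pd.Index, message: str) -> ValidationError:
    listed = ", ".join(map(str, rows[:10]))
    more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
    return ValidationError(f"{message}: rows {listed}{more}", rows=list(rows))


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort missing columns: {missing}")
    bad = df.index[~df["diagnosis"].isin(DIAGNOSES)]
    if len(bad):
        raise _bad(bad, f"diagnosis not in {DIAGNOSES}")
    bad = df.index[~df["sex"].isin(SEXES)]
    if len(bad):
        raise _bad(bad, f"sex not in {SEXES}")
    bad = df.index[~(df["los_days"] > 0)]
    if len(bad):
        raise _bad(bad, "los_days must be > 0")
    bad = df.index[df["age"] < 0]
    if len(bad):
        raise _bad(bad, "age must be >= 0")
    bad = df.index[df["cci"] < 0]
    if len(bad):
        raise _bad(bad, "cci must be >= 0")
    for c in FLAG_COLS:
        bad = df.index[~df[c].isin([0, 1])]
        if len(bad):
            raise _bad(bad, f"flag {c} must be 0/1")
    dup = df.index[df["admission_id"].duplicated(keep=False)]
    if len(dup):
        raise _bad(dup, "duplicate admission_id")


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate an admission-level cohort CSV.

    Extra columns beyond the schema (e.g. joined score columns) are kept.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "admission_id": str})
    return CohortTable(df=df, unit="admission")


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.df.to_csv(path, index=False)


def los_binary(los_days, threshold: float = LOS_THRESHOLD_DAYS):
    """1 iff stay strictly exceeds the threshold (exactly-at-threshold codes short).

    Accepts a scalar or an array/Series; threshold must be positive.
    """
    if not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    if np.isscalar(los_days):
        return int(los_days > threshold)
    return (np.asarray(los_days) > threshold).astype(int)


def to_patient_baseline(cohort: CohortTable) -> CohortTable:
    """Collapse to one record per patient: the chronologically first admission.

    Admission order is encoded by admission_id (lexicographic ties broken the
    same way), so the operation is deterministic and idempotent.
    """
    df = cohort.df.sort_values("admission_id", kind="stable")
    first = df.drop_duplicates(subset="patient_id", keep="first").reset_index(drop=True)
    return CohortTable(df=first, unit="patient_baseline")


def join_scores(cohort: CohortTable, scores: pd.DataFrame) -> CohortTable:
    """Join a score matrix (admission_id + domain columns) onto the cohort.

    Every admission must have a score row; missing admissions abort with
    their ids listed.
    """
    missing = sorted(set(cohort.df["admission_id"]) - set(scores["admission_id"]))
    if missing:
        shown = ", ".join(missing[:10])
        raise ValidationError(
            f"{len(missing)} admissions have no scores: {shown}"
            + ("" if len(missing) <= 10 else " ..."),
            rows=missing,
        )
    merged = cohort.df.merge(scores, on="admission_id", how="left", validate="one_to_one")
    return CohortTable(df=merged, unit=cohort.unit)
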