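"""Cohort data model, CSV I/O, unit conversion, and HOMA-IR computation.

The cohort is a flat per-subject table of clinical measurements. Glucose is
stored in mg/dL (US clinical convention, matching ADA thresholds) and
converted to mmol/L at the single point where HOMA-IR is computed. Insulin
is assumed reported in mU/L (equivalently µU/mL); no pmol/L conversion is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "Cohort",
    "CohortValidationError",
    "HOMA_DENOMINATOR",
    "MGDL_PER_MMOL_GLUCOSE",
    "compute_homa_ir",
    "glucose_mgdl_to_mmol",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Denominator of the homeostasis-model insulin-resistance index.
HOMA_DENOMINATOR = 22.5

#: Molar mass scaling for glucose: 18.0 mg/dL per mmol/L.
MGDL_PER_MMOL_GLUCOSE = 18.0

SEX_VALUES = ("female", "male")

#: Continuous physiological columns, all strictly positive when present.
CONTINUOUS_FIELDS = (
    "age",
    "bmi",
    "waist_hip_ratio",
    "fpg",
    "fpi",
    "sbp",
    "dbp",
    "triglycerides",
    "total_chol",
    "hdl_chol",
    "ldl_chol",
    "alt",
    "ast",
)

#: Optional lifestyle covariates with their admissible coded values.
LIFESTYLE_FIELDS = {
    "physical_activity": ("low", "adequate"),
    "alcohol": ("no", "yes"),
    "smoking": ("never", "former", "current"),
    "education": (0, 1, 2, 3),
    "hepatitis_history": ("no", "yes"),
}

REQUIRED_COLUMNS = ("subject_id", "sex") + CONTINUOUS_FIELDS

ALL_COLUMNS = REQUIRED_COLUMNS + tuple(LIFESTYLE_FIELDS) + ("homa_ir",)


class CohortValidationError(ValueError):
    """A subject record or cohort table violates a physiological invariant."""


def compute_homa_ir(fpi: float, fpg_mmol: float) -> float:
    """HOMA-IR index from fasting insulin (mU/L) and glucose (mmol/L).

    HOMA-IR = FPI × FPG / 22.5, with glucose in mmol/L. Dimensionless;
    higher values indicate greater insulin resistance.
    """
    if not fpi > 0:
        raise CohortValidationError(f"fpi must be positive, got {fpi!r}")
    if not fpg_mmol > 0:
        raise CohortValidationError(f"fpg_mmol must be positive, got {fpg_mmol!r}")
    return fpi * fpg_mmol / HOMA_DENOMINATOR


def glucose_mgdl_to_mmol(fpg_mgdl: float) -> float:
    """Convert fasting plasma glucose from mg/dL to mmol/L (divide by 18)."""
    if not np.all(np.asarray(fpg_mgdl) > 0):
        raise CohortValidationError(f"fpg_mgdl must be positive, got {fpg_mgdl!r}")
    return fpg_mgdl / MGDL_PER_MMOL_GLUCOSE


@dataclass
class SubjectRecord:
    """One individual's clinical measurements.

    Continuous fields carry clinical units: bmi kg/m², fpg mg/dL, fpi mU/L,
    blood pressures mmHg, lipids mg/dL, transaminases U/L. ``homa_ir`` is
    derived and may be absent until computed.
    """

    subject_id: str
    sex: str
    age: float
    bmi: float
    waist_hip_ratio: float
    fpg: float
    fpi: float
    sbp: float
    dbp: float
    triglycerides: float
    total_chol: float
    hdl_chol: float
    ldl_chol: float
    alt: float
    ast: float
    physical_activity: Optional[str] = None
    alcohol: Optional[str] = None
    smoking: Optional[str] = None
    education: Optional[int] = None
    hepatitis_history: Optional[str] = None
    homa_ir: Optional[float] = None

    def validate(self) -> None:
        if self.sex not in SEX_VALUES:
            raise CohortValidationError(
                f"subject {self.subject_id}: sex must be one of {SEX_VALUES}, got {self.sex!r}"
            )
        for name in CONTINUOUS_FIELDS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if not v > 0:
                raise CohortValidationError(
                    f"subject {self.subject_id}: {name} must be strictly positive, got {v}"
                )
        if self._present("waist_hip_ratio") and not (0 < self.waist_hip_ratio < 2):
            raise CohortValidationError(
                f"subject {self.subject_id}: waist_hip_ratio out of (0, 2): {self.waist_hip_ratio}"
            )
        if self._present("bmi") and not (10 <= self.bmi <= 100):
            raise CohortValidationError(
                f"subject {self.subject_id}: bmi out of [10, 100]: {self.bmi}"
            )
        if self._present("fpg") and self.fpg < 20:
            raise CohortValidationError(
                f"subject {self.subject_id}: fpg below 20 mg/dL: {self.fpg}"
            )
        for name, allowed in LIFESTYLE_FIELDS.items():
            v = getattr(self, name)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                if v not in allowed:
                    raise CohortValidationError(
                        f"subject {self.subject_id}: {name} must be one of {allowed}, got {v!r}"
                    )
        if self._present("homa_ir"):
            expected = compute_homa_ir(self.fpi, glucose_mgdl_to_mmol(self.fpg))
            if abs(self.homa_ir - expected) > 1e-9:
                raise CohortValidationError(
                    f"subject {self.subject_id}: homa_ir={self.homa_ir} inconsistent "
                    f"with fpi×(fpg/18)/22.5={expected}"
                )

    def _present(self, name: str) -> bool:
        v = getattr(self, name)
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    def with_homa_ir(self) -> "SubjectRecord":
        """Return a copy with homa_ir filled from fpi and fpg."""
        hi = compute_homa_ir(self.fpi, glucose_mgdl_to_mmol(self.fpg))
        return SubjectRecord(**{**self.__dict__, "homa_ir": hi})


@dataclass
class Cohort:
    """An ordered collection of validated subject records.

    Backed by a pandas DataFrame with one row per subject and the canonical
    column order of :data:`ALL_COLUMNS`; subject ids are unique and row
    order is stable across a CSV round trip.
    """

    df: pd.DataFrame
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortValidationError(f"cohort table missing columns: {missing}")
        for c in ALL_COLUMNS:
            if c not in self.df.columns:
                self.df[c] = np.nan
        self.df = self.df.loc[:, list(ALL_COLUMNS)].reset_index(drop=True)
        ids = self.df["subject_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise CohortValidationError(f"duplicate subject_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[SubjectRecord]:
        return [self._row_to_record(row) for _, row in self.df.iterrows()]

    @staticmethod
    def _row_to_record(row: pd.Series) -> SubjectRecord:
        kwargs = {}
        for f in dc_fields(SubjectRecord):
            v = row.get(f.name)
            if isinstance(v, float) and math.isnan(v):
                v = None
            if f.name == "education" and v is not None:
                v = int(v)
            kwargs[f.name] = v
        return SubjectRecord(**kwargs)

    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord], provenance: str = "records") -> "Cohort":
        rows = []
        for r in records:
            r.validate()
            rows.append({f.name: getattr(r, f.name) for f in dc_fields(SubjectRecord)})
        if not rows:
            raise CohortValidationError("cannot build an empty cohort")
        return cls(pd.DataFrame(rows), provenance=provenance)

    def compute_homa_ir(self) -> "Cohort":
        """Fill the homa_ir column from fpi and fpg for every subject."""
        df = self.df.copy()
        df["homa_ir"] = df["fpi"] * (df["fpg"] / MGDL_PER_MMOL_GLUCOSE) / HOMA_DENOMINATOR
        return Cohort(df, provenance=self.provenance)

    @property
    def homa_ir(self) -> np.ndarray:
        return self.df["homa_ir"].to_numpy(dtype=float)


@dataclass
class RejectReport:
    """Row-numbered diagnostics for rows dropped during CSV ingestion."""

    rejects: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row_number: int, reason: str) -> None:
        self.rejects.append((row_number, reason))

    def __len__(self) -> int:
        return len(self.rejects)


def read_cohort_csv(
    path,
    column_map: Optional[dict[str, str]] = None,
    compute_homa: bool = True,
) -> tuple[Cohort, RejectReport]:
    """Read a cohort CSV, validating each row against the record invariants.

    Parameters
    ----------
    path : path-like
        CSV file with a header row, UTF-8, "." decimal point.
    column_map : dict, optional
        Maps canonical field names to the file's column names.
    compute_homa : bool
        Fill ``homa_ir`` from fpi and fpg (default). Rows violating any
        invariant are dropped and reported with their 1-based data row
        number; they never abort the read.

    Returns
    -------
    (Cohort, RejectReport)
    """
    raw = pd.read_csv(path, dtype={"subject_id": str})
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")

    report = RejectReport()
    kept = []
    for i, row in raw.iterrows():
        try:
            rec = Cohort._row_to_record(row)
            rec.validate()
        except (CohortValidationError, TypeError, ValueError) as exc:
            report.add(i + 1, str(exc))
            continue
        kept.append(row)
    if not kept:
        raise CohortValidationError(f"{path}: no valid rows (all {len(raw)} rejected)")
    cohort = Cohort(pd.DataFrame(kept), provenance=str(path))
    if compute_homa:
        cohort = cohort.compute_homa_ir()
    return cohort, report


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort to CSV with deterministic column order and full float
    precision; absent optional fields become empty cells, never zeros."""
    if len(cohort) == 0:
        raise CohortValidationError("refusing to write an empty cohort")
    # default float repr round-trips exactly, so read-back equals input
    cohort.df.to_csv(path, index=False, columns=list(ALL_COLUMNS))
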