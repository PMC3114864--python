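"""Ordinal risk grading of continuous cardiometabolic variables.

Each clinical variable is mapped to an integer grade 1, 2, ... against
published reference thresholds (AHA for lipids, blood pressure, BMI; ADA
for fasting glucose). Grade 1 is the reference (lowest-risk) category and
larger grades always mean greater risk, so protective variables (HDL
cholesterol) are graded on a reversed scale. The graded matrix — not the
raw measurements — is what the two-cluster K-means consumes: grading is
the standardization step that puts variables with different units on a
common ordinal risk scale.

Thresholds live in data (YAML-serializable scheme objects), never in the
clustering code, and are overridable per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort_io import Cohort

__all__ = [
    "VariableGrading",
    "GradingScheme",
    "GradedCohort",
    "GradingError",
    "grade_value",
    "default_scheme",
    "grade_cohort",
    "scheme_to_yaml",
    "scheme_from_yaml",
]


class GradingError(ValueError):
    """Invalid grading configuration or ungradeable input."""


@dataclass(frozen=True)
class VariableGrading:
    """Ordered thresholds mapping one continuous variable to risk grades.

    ``thresholds`` are strictly increasing boundary values in the variable's
    own unit; a value equal to a boundary falls in the worse grade (ADA
    "≥126" convention). ``direction='lower_is_worse'`` reverses the grade
    order so a higher grade still means greater risk. ``sex_specific`` maps
    sex to per-sex thresholds and overrides ``thresholds`` when present.
    """

    variable: str
    thresholds: tuple[float, ...] = ()
    direction: str = "higher_is_worse"
    sex_specific: Optional[dict[str, tuple[float, ...]]] = None

    def __post_init__(self) -> None:
        if self.direction not in ("higher_is_worse", "lower_is_worse"):
            raise GradingError(f"{self.variable}: unknown direction {self.direction!r}")
        for thr in self._all_threshold_sets():
            if any(b <= a for a, b in zip(thr, thr[1:])):
                raise GradingError(
                    f"{self.variable}: thresholds must be strictly increasing, got {thr}"
                )
            if len(thr) == 0:
                raise GradingError(f"{self.variable}: empty threshold list")

    def _all_threshold_sets(self):
        if self.sex_specific is not None:
            return [tuple(t) for t in self.sex_specific.values()]
        return [tuple(self.thresholds)]

    def thresholds_for(self, sex: Optional[str]) -> tuple[float, ...]:
        if self.sex_specific is not None:
            if sex is None:
                raise GradingError(
                    f"{self.variable}: sex-specific grading requires a sex"
                )
            try:
                return tuple(self.sex_specific[sex])
            except KeyError:
                raise GradingError(
                    f"{self.variable}: no thresholds for sex {sex!r}"
                ) from None
        return tuple(self.thresholds)

    @property
    def n_grades(self) -> int:
        return len(self._all_threshold_sets()[0]) + 1


def grade_value(value: float, grading: VariableGrading, sex: Optional[str] = None) -> int:
    """Grade one value: 1 + number of crossed thresholds, risk-ordered.

    For ``higher_is_worse`` the grade is 1 plus the count of thresholds
    less than or equal to the value; for ``lower_is_worse`` the scale is
    mirrored so the largest grade is still the riskiest.
    """
    thr = grading.thresholds_for(sex)
    base = 1 + sum(1 for t in thr if value >= t)
    if grading.direction == "lower_is_worse":
        return (len(thr) + 2) - base
    return base


# Default reference thresholds: AHA categories for BMI, lipids and blood
# pressure, ADA 2010 fasting-glucose categories, conventional upper limits
# of normal for transaminases, and the FPI >= 12 mU/L abnormality cutoff
# used in the confirmation variant. Units follow the cohort schema.
_DEFAULT_GRADINGS: tuple[VariableGrading, ...] = (
    VariableGrading("bmi", (25.0, 30.0, 35.0)),
    VariableGrading(
        "waist_hip_ratio",
        sex_specific={"female": (0.80, 0.85), "male": (0.90, 0.95)},
    ),
    VariableGrading("fpg", (100.0, 126.0)),
    VariableGrading("triglycerides", (150.0, 200.0, 500.0)),
    VariableGrading("total_chol", (200.0, 240.0)),
    VariableGrading(
        "hdl_chol",
        direction="lower_is_worse",
        sex_specific={"female": (50.0,), "male": (40.0,)},
    ),
    VariableGrading("sbp", (120.0, 140.0, 160.0)),
    VariableGrading("dbp", (80.0, 90.0, 100.0)),
    VariableGrading("alt", (40.0,)),
    VariableGrading("ast", (40.0,)),
)

FPI_GRADING = VariableGrading("fpi", (12.0,))


@dataclass(frozen=True)
class GradingScheme:
    """The full set of variable gradings used to build the graded matrix."""

    gradings: tuple[VariableGrading, ...]
    includes_fpi: bool = False

    def __post_init__(self) -> None:
        names = [g.variable for g in self.gradings]
        if len(set(names)) != len(names):
            raise GradingError(f"duplicate variables in scheme: {names}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(g.variable for g in self.gradings)

    def __getitem__(self, variable: str) -> VariableGrading:
        for g in self.gradings:
            if g.variable == variable:
                return g
        raise KeyError(variable)


def default_scheme(include_fpi: bool = False) -> GradingScheme:
    """The documented default scheme of ten graded attributes (BMI,
    waist/hip ratio, FPG, triglycerides, total and HDL cholesterol,
    systolic/diastolic pressure, ALT, AST); with ``include_fpi`` an
    eleventh binary FPI grade at 12 mU/L is appended."""
    gradings = _DEFAULT_GRADINGS + ((FPI_GRADING,) if include_fpi else ())
    return GradingScheme(gradings, includes_fpi=include_fpi)


@dataclass
class GradedCohort:
    """Subjects × variables matrix of integer risk grades."""

    subject_ids: list[str]
    grades: np.ndarray  # int matrix, shape (n_subjects, n_variables)
    variables: tuple[str, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.grades = np.asarray(self.grades, dtype=int)
        if self.grades.ndim != 2 or self.grades.shape != (
            len(self.subject_ids),
            len(self.variables),
        ):
            raise GradingError("grade matrix shape mismatch")
        if (self.grades < 1).any():
            raise GradingError("grades must all be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.grades, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=list(self.variables),
        )


def grade_cohort(cohort: Cohort, scheme: GradingScheme) -> GradedCohort:
    """Grade every subject on every scheme variable.

    Subjects missing any scheme variable (or missing sex where a grading is
    sex-specific) are excluded and counted, mirroring a complete-case rule.
    """
    df = cohort.df
    ids, rows = [], []
    n_excluded = 0
    for _, row in df.iterrows():
        vals = [row.get(v) for v in scheme.variables]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            n_excluded += 1
            continue
        sex = row.get("sex")
        rows.append([grade_value(v, scheme[name], sex) for name, v in zip(scheme.variables, vals)])
        ids.append(str(row["subject_id"]))
    if not rows:
        raise GradingError("no subject has complete data for the grading scheme")
    return GradedCohort(ids, np.array(rows, dtype=int), scheme.variables, n_excluded)


def scheme_to_yaml(scheme: GradingScheme) -> str:
    """Serialize a scheme to YAML (inverse of :func:`scheme_from_yaml`)."""
    payload = {
        "includes_fpi": scheme.includes_fpi,
        "variables": [
            {
                "variable": g.variable,
                "direction": g.direction,
                **(
                    {"sex_specific": {s: list(t) for s, t in g.sex_specific.items()}}
                    if g.sex_specific is not None
                    else {"thresholds": list(g.thresholds)}
                ),
            }
            for g in scheme.gradings
        ],
    }
    return yaml.safe_dump(payload, sort_keys=False)


def scheme_from_yaml(text: str) -> GradingScheme:
    payload = yaml.safe_load(text)
    gradings = []
    for item in payload["variables"]:
        sex_specific = item.get("sex_specific")
        gradings.append(
            VariableGrading(
                variable=item["variable"],
                thresholds=tuple(item.get("thresholds", ())),
                direction=item.get("direction", "higher_is_worse"),
                sex_specific=(
                    {s: tuple(t) for s, t in sex_specific.items()}
                    if sex_specific is not None
                    else None
                ),
            )
        )
    return GradingScheme(tuple(gradings), includes_fpi=payload.get("includes_fpi", False))
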