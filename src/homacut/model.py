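"""Model/Results interface for the HOMA-IR reference-cutoff procedure.

:class:`HomaCutoffModel` wraps the full unsupervised pipeline — grade the
cardiometabolic variables against reference ranges, pseudo-label subjects
with two-cluster K-means, scan HOMA-IR cutoffs for maximum Matthews
correlation — behind a ``fit()`` call that returns a
:class:`HomaCutoffResults` carrying the selected cutoff, the scan table,
ROC curve, per-attribute ANOVA diagnostics and the population banding,
with a ``summary()`` in the spirit of statsmodels results objects.

>>> from homacut import GeneratorConfig, generate_cohort, HomaCutoffModel
>>> cohort, truth = generate_cohort(GeneratorConfig(seed=7))
>>> res = HomaCutoffModel(cohort).fit(seed=7)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import (
    AttributeAnova,
    ClusterAssignment,
    ClusterModel,
    anova_per_attribute,
    kmeans_fit,
)
from .cohort_io import Cohort, read_cohort_csv
from .cutoff import (
    COARSE_GRID,
    FINE_STEP,
    CutoffScanRow,
    ROCCurve,
    best_cutoff_by_mcc,
    reference_bands,
    roc_auc,
    scan_cutoffs,
)
from .grading import GradedCohort, GradingScheme, default_scheme, grade_cohort

__all__ = ["HomaCutoffModel", "HomaCutoffResults", "scan_to_frame"]


def scan_to_frame(scan: Sequence[CutoffScanRow]) -> pd.DataFrame:
    """Scan rows as a tidy table (one row per candidate cutoff)."""
    return pd.DataFrame(
        {
            "cutoff": [r.cutoff for r in scan],
            "tp": [r.confusion.tp for r in scan],
            "fp": [r.confusion.fp for r in scan],
            "tn": [r.confusion.tn for r in scan],
            "fn": [r.confusion.fn for r in scan],
            "sensitivity": [r.sensitivity for r in scan],
            "specificity": [r.specificity for r in scan],
            "mcc": [r.mcc for r in scan],
        }
    )


class HomaCutoffModel:
    """The cutoff-definition procedure bound to one cohort.

    Parameters
    ----------
    cohort : Cohort
        Validated cohort with HOMA-IR computed.
    scheme : GradingScheme, optional
        Grading thresholds; defaults to the ten-attribute reference scheme
        (pass ``default_scheme(include_fpi=True)`` for the eleven-variable
        confirmation variant).
    grid : (start, stop, step)
        Coarse cutoff grid; default 0.30–7.80 by 0.25.
    fine_step : float
        Step of the fine scan spanning one coarse step either side of the
        coarse optimum.
    band_low : float
        Lower (conventional) bound of the borderline band; the upper bound
        is the fitted cutoff.
    """

    def __init__(
        self,
        cohort: Cohort,
        scheme: Optional[GradingScheme] = None,
        grid: tuple[float, float, float] = COARSE_GRID,
        fine_step: float = FINE_STEP,
        band_low: float = 2.60,
    ) -> None:
        self.cohort = cohort
        self.scheme = scheme if scheme is not None else default_scheme()
        self.grid = grid
        self.fine_step = fine_step
        self.band_low = band_low

    @classmethod
    def from_csv(cls, path, column_map=None, **kwargs) -> "HomaCutoffModel":
        cohort, _ = read_cohort_csv(path, column_map=column_map)
        return cls(cohort, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "dataframe", **kwargs) -> "HomaCutoffModel":
        cohort = Cohort(df.copy(), provenance=provenance).compute_homa_ir()
        return cls(cohort, **kwargs)

    def fit(self, n_restarts: int = 50, seed: int = 0) -> "HomaCutoffResults":
        """Grade, cluster, scan; return the fitted results."""
        graded = grade_cohort(self.cohort, self.scheme)
        km, assignment = kmeans_fit(graded, n_restarts=n_restarts, seed=seed)
        # scan only subjects that survived grading, keyed by subject id
        keep = self.cohort.df["subject_id"].astype(str).isin(set(graded.subject_ids))
        homa = self.cohort.df.loc[keep, "homa_ir"].to_numpy(dtype=float)
        labels = assignment.is_resistant.astype(int)

        coarse = scan_cutoffs(homa, labels, self.grid)
        coarse_cut, coarse_row = best_cutoff_by_mcc(coarse)
        step = self.grid[2]
        fine_grid = (coarse_cut - step, coarse_cut + step, self.fine_step)
        fine = scan_cutoffs(homa, labels, fine_grid)
        fine_cut, fine_row = best_cutoff_by_mcc(fine)
        roc = roc_auc(coarse)
        # the borderline band [band_low, cutoff] is undefined when the fitted
        # cutoff does not exceed the conventional lower bound
        bands = (
            reference_bands(homa, self.band_low, coarse_cut)
            if coarse_cut > self.band_low
            else None
        )
        anova = anova_per_attribute(graded, assignment)
        return HomaCutoffResults(
            model=self,
            graded=graded,
            kmeans=km,
            assignment=assignment,
            coarse_scan=coarse,
            fine_scan=fine,
            cutoff=coarse_cut,
            cutoff_row=coarse_row,
            fine_cutoff=fine_cut,
            fine_cutoff_row=fine_row,
            roc=roc,
            bands=bands,
            anova=anova,
            homa_values=homa,
        )


@dataclass
class HomaCutoffResults:
    """Fitted cutoff, scan tables, ROC, banding and cluster diagnostics."""

    model: HomaCutoffModel
    graded: GradedCohort
    kmeans: ClusterModel
    assignment: ClusterAssignment
    coarse_scan: list[CutoffScanRow]
    fine_scan: list[CutoffScanRow]
    cutoff: float
    cutoff_row: CutoffScanRow
    fine_cutoff: float
    fine_cutoff_row: CutoffScanRow
    roc: ROCCurve
    bands: Optional[dict[str, float]]
    anova: list[AttributeAnova]
    homa_values: np.ndarray

    @property
    def mcc(self) -> float:
        return self.cutoff_row.mcc

    @property
    def auc(self) -> float:
        return self.roc.auc

    def scan_frame(self, fine: bool = False) -> pd.DataFrame:
        return scan_to_frame(self.fine_scan if fine else self.coarse_scan)

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [a.variable for a in self.anova],
                "resistant_center": [a.mean_resistant for a in self.anova],
                "control_center": [a.mean_control for a in self.anova],
                "F": [a.f_stat for a in self.anova],
                "p": [a.p_value for a in self.anova],
            }
        )

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.assignment.subject_ids,
                "cluster_id": self.assignment.cluster_id,
                "is_resistant": self.assignment.is_resistant.astype(int),
            }
        )

    def summary(self) -> str:
        """Plain-text report of the fitted cutoff and its diagnostics."""
        a = self.assignment
        lines = [
            "HOMA-IR reference-cutoff fit",
            "=" * 60,
            f"subjects graded        {len(self.graded.subject_ids):>8d}"
            f"   (excluded: {self.graded.n_excluded})",
            f"resistant / control    {a.n_resistant:>8d} / {a.n_control}",
            f"k-means WCSS           {self.kmeans.wcss:>12.3f}   (restart {self.kmeans.best_restart})",
            "-" * 60,
            f"best cutoff (coarse)   {self.cutoff:>8.2f}   MCC {self.mcc:.3f}"
            f"   sens {self.cutoff_row.sensitivity:.3f}   spec {self.cutoff_row.specificity:.3f}",
            f"best cutoff (fine)     {self.fine_cutoff:>8.2f}   MCC {self.fine_cutoff_row.mcc:.3f}",
            f"ROC AUC (scan)         {self.auc:>8.3f}",
            "-" * 60,
        ]
        if self.bands is not None:
            lines += [
                f"bands at {self.model.band_low:.2f} / {self.cutoff:.2f}:",
                f"  normal (< {self.model.band_low:.2f})           {self.bands['normal']:6.1%}",
                f"  borderline high               {self.bands['borderline_high']:6.1%}",
                f"  high (> {self.cutoff:.2f})             {self.bands['high']:6.1%}",
            ]
        else:
            lines.append(
                f"bands undefined: fitted cutoff {self.cutoff:.2f} <= lower bound "
                f"{self.model.band_low:.2f}"
            )
        lines += [
            "-" * 60,
            "per-attribute ANOVA (cluster centers are mean grades):",
        ]
        for r in self.anova:
            p = f"{r.p_value:.2e}" if not r.degenerate else "0 (degenerate)"
            lines.append(
                f"  {r.variable:<16s} {r.mean_resistant:6.2f} {r.mean_control:6.2f}"
                f"   F={r.f_stat:10.2f}   p={p}"
            )
        return "\n".join(lines)

    def plot_roc(self, path=None):
        """Static ROC figure; saves to ``path`` when given, else returns the
        matplotlib axes."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(self.roc.fpr, self.roc.tpr, marker="o", ms=3, lw=1.2)
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate (1 - specificity)")
        ax.set_ylabel("true positive rate (sensitivity)")
        ax.set_title(f"HOMA-IR cutoff scan ROC (AUC = {self.roc.auc:.3f})")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return ax
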