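"""Cutoff scanning: confusion matrices, MCC, ROC, and reference bands.

Given per-subject HOMA-IR values and binary insulin-resistance labels
(pseudo-labels from clustering, or latent truth in simulations), a grid of
candidate cutoffs is scanned; at each cutoff a subject is called positive
when HOMA-IR exceeds the cutoff (strict ``>``, matching the "high" band
being values above the upper reference bound). The best cutoff maximizes
the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

the Pearson correlation between predicted and true labels; it is robust to
class imbalance, and is defined as 0 whenever a marginal is empty. Ties are
broken toward the larger cutoff (higher specificity).

The module also reconstructs integer confusion counts from published
(sensitivity, specificity) pairs printed to 3 decimals, so a published scan
table can be re-verified from counts rather than rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "CutoffScanRow",
    "ROCCurve",
    "CutoffError",
    "ReconstructionError",
    "confusion_at_cutoff",
    "mcc",
    "reconstruct_integer_confusion",
    "scan_cutoffs",
    "best_cutoff_by_mcc",
    "roc_auc",
    "reference_bands",
    "cutoff_grid",
]

#: Coarse scan grid: cutoffs 0.30 to 7.80 in steps of 0.25 (31 points).
COARSE_GRID = (0.30, 7.80, 0.25)

#: Fine scan step around the coarse optimum.
FINE_STEP = 0.05


class CutoffError(ValueError):
    """Invalid input to a cutoff-scan operation."""


class ReconstructionError(ValueError):
    """No (or no unique) integer confusion matrix matches the printed rates."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary decision rule against reference labels.

    Counts may be fractional when reconstructed from rounded rates."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise CutoffError(f"negative confusion count in {self}")

    @property
    def positives(self) -> float:
        return self.tp + self.fn

    @property
    def negatives(self) -> float:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.positives if self.positives else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / self.negatives if self.negatives else math.nan


def mcc(confusion: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix, in [-1, 1].

    Returns 0.0 when any marginal (predicted or actual class total) is
    empty, the standard convention for the degenerate denominator.
    """
    tp, fp, tn, fn = confusion.tp, confusion.fp, confusion.tn, confusion.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass(frozen=True)
class CutoffScanRow:
    """One scanned cutoff with its confusion counts and summary rates."""

    cutoff: float
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    mcc: float

    @classmethod
    def from_confusion(cls, cutoff: float, cm: ConfusionMatrix) -> "CutoffScanRow":
        return cls(cutoff, cm, cm.sensitivity, cm.specificity, mcc(cm))


def confusion_at_cutoff(
    homa_values: Sequence[float],
    labels: Sequence[int],
    cutoff: float,
    strict: bool = True,
) -> ConfusionMatrix:
    """Tally a cutoff rule against binary labels.

    Predicted positive iff value > cutoff (strict, the default) or
    value >= cutoff when ``strict=False``.
    """
    v = np.asarray(homa_values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise CutoffError("homa_values and labels must be equal-length 1-D vectors")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise CutoffError("both classes must be present in labels")
    pred = v > cutoff if strict else v >= cutoff
    pos = y == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _integers_rounding_to(rate: float, denom: int, decimals: int = 3) -> list[int]:
    """All integers k in [0, denom] with round(k/denom, decimals) == rate."""
    lo = max(0, math.floor((rate - 0.5 * 10 ** -decimals) * denom) - 1)
    hi = min(denom, math.ceil((rate + 0.5 * 10 ** -decimals) * denom) + 1)
    return [k for k in range(lo, hi + 1) if round(k / denom, decimals) == round(rate, decimals)]


def reconstruct_integer_confusion(
    sens: float,
    spec: float,
    positives: int,
    negatives: int,
    printed_mcc: Optional[float] = None,
    decimals: int = 3,
) -> ConfusionMatrix:
    """Recover integer confusion counts from rates printed to 3 decimals.

    Finds the integer TP in [0, positives] whose ratio rounds to ``sens``
    and likewise TN for ``spec``. When rounding is not injective (possible
    whenever the group size exceeds 1000, since the integer grid spacing
    drops below the rounding bin width) several candidates can match; if
    ``printed_mcc`` is supplied, candidates are filtered to those whose
    recomputed MCC rounds to it. A residual ambiguity, or an empty
    candidate set, raises :class:`ReconstructionError` listing candidates.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ReconstructionError(f"rates out of [0,1]: sens={sens}, spec={spec}")
    if positives <= 0 or negatives <= 0:
        raise ReconstructionError("positives and negatives must be > 0")
    tps = _integers_rounding_to(sens, positives, decimals)
    tns = _integers_rounding_to(spec, negatives, decimals)
    candidates = [
        ConfusionMatrix(tp=tp, fp=negatives - tn, tn=tn, fn=positives - tp)
        for tp in tps
        for tn in tns
    ]
    if printed_mcc is not None:
        candidates = [c for c in candidates if round(mcc(c), decimals) == round(printed_mcc, decimals)]
    if len(candidates) == 1:
        return candidates[0]
    detail = [(c.tp, c.tn) for c in candidates]
    kind = "no" if not candidates else "ambiguous"
    raise ReconstructionError(
        f"{kind} integer reconstruction for sens={sens}, spec={spec} "
        f"at n=({positives}, {negatives}); candidates (TP, TN): {detail}"
    )


def cutoff_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid of cutoffs (robust to float step error)."""
    if step <= 0:
        raise CutoffError("grid step must be positive")
    n = int(round((stop - start) / step))
    if n < 0:
        raise CutoffError("empty grid: stop < start")
    return start + step * np.arange(n + 1)


def scan_cutoffs(
    homa_values: Sequence[float],
    labels: Sequence[int],
    grid: tuple[float, float, float] = COARSE_GRID,
    strict: bool = True,
) -> list[CutoffScanRow]:
    """Scan a cutoff grid, one row per grid point.

    Along increasing cutoffs, sensitivity is non-increasing and specificity
    non-decreasing (fewer subjects are called positive).
    """
    rows = []
    for c in cutoff_grid(*grid):
        cm = confusion_at_cutoff(homa_values, labels, float(c), strict=strict)
        rows.append(CutoffScanRow.from_confusion(float(c), cm))
    return rows


def best_cutoff_by_mcc(scan: Sequence[CutoffScanRow]) -> tuple[float, CutoffScanRow]:
    """Row of maximal MCC; exact ties go to the larger cutoff (the more
    specific rule)."""
    if not scan:
        raise CutoffError("empty scan")
    best = max(scan, key=lambda r: (r.mcc, r.cutoff))
    return best.cutoff, best


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points with trapezoidal area."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float


def roc_auc(scan: Sequence[CutoffScanRow]) -> ROCCurve:
    """ROC curve from a scan: points (1 − specificity, sensitivity) plus
    the (0,0) and (1,1) anchors, sorted by FPR then TPR; AUC by trapezoid."""
    pts = {(0.0, 0.0), (1.0, 1.0)}
    pts.update((1.0 - r.specificity, r.sensitivity) for r in scan)
    ordered = sorted(pts)
    fpr = np.array([p[0] for p in ordered])
    tpr = np.array([p[1] for p in ordered])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(tuple(fpr), tuple(tpr), auc)


def reference_bands(
    homa_values: Sequence[float], low: float, high: float
) -> dict[str, float]:
    """Population fractions below, within, and above the reference band.

    Bands: normal (< low), borderline-high ([low, high]) and high (> high).
    Fractions sum to 1.
    """
    if low >= high:
        raise CutoffError(f"band bounds must satisfy low < high, got {low} >= {high}")
    v = np.asarray(homa_values, dtype=float)
    if v.size == 0:
        raise CutoffError("no HOMA-IR values")
    n = v.size
    return {
        "normal": float(np.sum(v < low)) / n,
        "borderline_high": float(np.sum((v >= low) & (v <= high))) / n,
        "high": float(np.sum(v > high)) / n,
    }
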