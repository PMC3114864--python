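"""Two-cluster K-means pseudo-labeling of graded cohorts.

Subjects are partitioned by Lloyd's algorithm (k = 2, Euclidean distance on
the raw integer grades) into an insulin-resistant group and a control
group. Grades are deliberately not re-standardized: the grading step is
itself the standardization, and rescaling would distort the intended
weighting of the ordinal risk scale.

Initialization samples two distinct subjects as starting centers; the fit
is repeated over seeded restarts and the minimum within-cluster
sum-of-squares (WCSS) solution is kept. Should a cluster empty out during
iteration, its center is reseeded at the point farthest from its assigned
center. The cluster whose mean per-subject grade sum is larger is labeled
"resistant"; the labeling is invariant to cluster id renumbering.

Between-group separation per attribute is summarized by one-way ANOVA on
the grades (two groups, df (1, n−2)), whose F statistic equals the squared
pooled-variance two-sample t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grading import GradedCohort

__all__ = [
    "ClusterModel",
    "ClusterAssignment",
    "AttributeAnova",
    "ClusterError",
    "kmeans_fit",
    "assign_ir_label",
    "anova_per_attribute",
]

MAX_ITER = 300


class ClusterError(ValueError):
    """Degenerate clustering input or failed fit."""


@dataclass
class ClusterModel:
    """A fitted k=2 partition: centers, WCSS, and restart bookkeeping."""

    centers: np.ndarray  # (2, n_variables)
    wcss: float
    n_iter: int
    best_restart: int
    labels_: np.ndarray  # cluster ids in {0, 1}, one per subject


@dataclass
class ClusterAssignment:
    """Per-subject pseudo-labels: cluster id and insulin-resistance flag."""

    subject_ids: list[str]
    cluster_id: np.ndarray  # {1, 2}
    is_resistant: np.ndarray  # bool
    n_resistant: int
    n_control: int


@dataclass(frozen=True)
class AttributeAnova:
    """One-way two-group ANOVA of a single graded attribute."""

    variable: str
    mean_resistant: float
    mean_control: float
    f_stat: float
    p_value: float
    degenerate: bool = False  # zero within-group variance with unequal means


def _wcss(x: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(((x - centers[assign]) ** 2).sum())


def _lloyd(x: np.ndarray, init_centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """One Lloyd run from given centers; returns (centers, assignment, iters)."""
    centers = init_centers.astype(float).copy()
    assign = np.full(len(x), -1)
    prev_wcss = np.inf
    for it in range(1, MAX_ITER + 1):
        d = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d.argmin(axis=1)
        for _ in range(2):  # fixing one cluster can, rarely, empty the other
            empty = [k for k in range(2) if not np.any(new_assign == k)]
            if not empty:
                break
            k = empty[0]
            # reseed the empty center at the point farthest from its center
            far = ((x - centers[1 - k]) ** 2).sum(axis=1).argmax()
            centers[k] = x[far]
            new_assign = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2).argmin(axis=1)
        cur_wcss = _wcss(x, centers, new_assign)
        assert cur_wcss <= prev_wcss + 1e-9, "Lloyd iteration increased WCSS"
        if np.array_equal(new_assign, assign):
            return centers, assign, it
        assign = new_assign
        for k in range(2):
            centers[k] = x[assign == k].mean(axis=0)
        prev_wcss = _wcss(x, centers, assign)
    return centers, assign, MAX_ITER


def kmeans_fit(
    graded: GradedCohort, n_restarts: int = 50, seed: int = 0
) -> tuple[ClusterModel, ClusterAssignment]:
    """Best-of-restarts two-cluster K-means on the graded matrix.

    Each restart draws two distinct subject rows as initial centers from a
    seeded generator; the restart with minimal WCSS wins. Requires at least
    two distinct grade rows.
    """
    x = np.asarray(graded.grades, dtype=float)
    if len(np.unique(x, axis=0)) < 2:
        raise ClusterError("all grade rows identical; no 2-partition exists")
    if n_restarts < 1:
        raise ClusterError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for r in range(n_restarts):
        # sample two subjects with distinct grade vectors as seeds
        while True:
            i, j = rng.choice(len(x), size=2, replace=False)
            if not np.array_equal(x[i], x[j]):
                break
        centers, assign, n_iter = _lloyd(x, np.stack([x[i], x[j]]))
        w = _wcss(x, centers, assign)
        if best is None or w < best.wcss - 1e-12:
            best = ClusterModel(centers, w, n_iter, r, assign)
    assert best is not None
    return best, assign_ir_label(best, graded)


def assign_ir_label(model: ClusterModel, graded: GradedCohort) -> ClusterAssignment:
    """Label the cluster with the larger mean grade sum as insulin resistant.

    Ties on mean grade sum fall back to the higher mean FPG grade; an exact
    tie on both criteria is pathological and raises.
    """
    x = np.asarray(graded.grades, dtype=float)
    assign = model.labels_
    sums = x.sum(axis=1)
    mean_sum = [sums[assign == k].mean() for k in range(2)]
    if mean_sum[0] != mean_sum[1]:
        resistant_k = int(np.argmax(mean_sum))
    else:
        try:
            fpg_col = graded.variables.index("fpg")
        except ValueError:
            fpg_col = None
        if fpg_col is None:
            raise ClusterError("tied grade sums and no fpg column to break the tie")
        mean_fpg = [x[assign == k, fpg_col].mean() for k in range(2)]
        if mean_fpg[0] == mean_fpg[1]:
            raise ClusterError("exact tie on grade sum and FPG grade between clusters")
        resistant_k = int(np.argmax(mean_fpg))
    is_res = assign == resistant_k
    return ClusterAssignment(
        subject_ids=list(graded.subject_ids),
        cluster_id=np.where(is_res, 1, 2),
        is_resistant=is_res,
        n_resistant=int(is_res.sum()),
        n_control=int((~is_res).sum()),
    )


def anova_per_attribute(
    graded: GradedCohort, assignment: ClusterAssignment
) -> list[AttributeAnova]:
    """One-way ANOVA of each graded attribute between the two clusters.

    F = between-group MS / within-group MS with df (1, n−2); equals the
    square of the pooled-variance two-sample t statistic. Zero within-group
    variance with unequal means is flagged degenerate with p = 0.
    """
    res = assignment.is_resistant
    if not (res.any() and (~res).any()):
        raise ClusterError("both groups must be nonempty for ANOVA")
    out = []
    n = len(res)
    for j, var in enumerate(graded.variables):
        g1 = graded.grades[res, j].astype(float)
        g2 = graded.grades[~res, j].astype(float)
        m1, m2 = g1.mean(), g2.mean()
        grand = np.concatenate([g1, g2]).mean()
        ss_between = len(g1) * (m1 - grand) ** 2 + len(g2) * (m2 - grand) ** 2
        ss_within = ((g1 - m1) ** 2).sum() + ((g2 - m2) ** 2).sum()
        if ss_within == 0:
            if m1 != m2:
                out.append(AttributeAnova(var, m1, m2, np.inf, 0.0, degenerate=True))
            else:
                out.append(AttributeAnova(var, m1, m2, 0.0, 1.0))
            continue
        f = (ss_between / 1.0) / (ss_within / (n - 2))
        p = float(stats.f.sf(f, 1, n - 2))
        out.append(AttributeAnova(var, m1, m2, float(f), p))
    return out
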