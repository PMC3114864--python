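import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from homacut import (
    ConfusionMatrix,
    best_cutoff_by_mcc,
    confusion_at_cutoff,
    mcc,
    reconstruct_integer_confusion,
    reference_bands,
    roc_auc,
    scan_cutoffs,
)
from homacut.cutoff import (
    COARSE_GRID,
    CutoffError,
    ReconstructionError,
    cutoff_grid,
)


class TestConfusionAtCutoff:
    def test_perfect_split(self):
        cm = confusion_at_cutoff([1, 2, 3, 4], [0, 0, 1, 1], 2.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_cutoff_below_min_predicts_all_positive(self):
        cm = confusion_at_cutoff([1, 2, 3, 4], [0, 1, 0, 1], 0.0)
        assert cm.tp == 2 and cm.fn == 0 and cm.tn == 0 and cm.fp == 2

    def test_boundary_is_strict(self):
        # a value equal to the cutoff is predicted negative
        cm = confusion_at_cutoff([3.0, 3.0], [0, 1], 3.0)
        assert cm.tp == 0 and cm.fn == 1 and cm.tn == 1 and cm.fp == 0

    def test_single_class_rejected(self):
        with pytest.raises(CutoffError):
            confusion_at_cutoff([1, 2], [1, 1], 1.5)


class TestMcc:
    def test_published_row_counts(self):
        # counts reconstructed from the published sens/spec at 795/1059
        assert mcc(ConfusionMatrix(tp=490, fn=305, tn=824, fp=235)) == pytest.approx(
            0.400, abs=5e-4
        )

    def test_perfect_classifier(self):
        assert mcc(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0)) == 1.0

    def test_uninformative_classifier(self):
        # sensitivity = specificity = 0.5 at any class sizes
        assert mcc(ConfusionMatrix(tp=5, fn=5, tn=20, fp=20)) == 0.0

    def test_zero_marginal_convention(self):
        # nothing predicted positive: an empty marginal gives MCC 0
        assert mcc(ConfusionMatrix(tp=0, fn=10, tn=10, fp=0)) == 0.0

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_pearson_of_binary_labels(self, tp, fp, tn, fn):
        # MCC is the Pearson correlation between predicted and true labels,
        # independently computed by sklearn from expanded label vectors
        if min(tp + fn, tn + fp) == 0:
            return
        y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        ours = mcc(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
        theirs = matthews_corrcoef(y_true, y_pred)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestReconstruction:
    def test_published_best_row(self):
        cm = reconstruct_integer_confusion(0.616, 0.778, 795, 1059)
        assert (cm.tp, cm.tn) == (490, 824)
        assert (cm.fn, cm.fp) == (305, 235)

    def test_extreme_row(self):
        cm = reconstruct_integer_confusion(1.000, 0.004, 795, 1059)
        assert (cm.tp, cm.tn) == (795, 4)

    def test_impossible_rate_errors(self):
        # no integer out of 3 rounds to 0.500
        with pytest.raises(ReconstructionError, match="no integer"):
            reconstruct_integer_confusion(0.500, 0.500, 3, 3)

    def test_ambiguous_rate_errors_and_lists_candidates(self):
        # at n=1059 two TN values round to 0.907
        with pytest.raises(ReconstructionError, match="ambiguous"):
            reconstruct_integer_confusion(0.333, 0.907, 795, 1059)

    def test_printed_mcc_resolves_ambiguity(self):
        cm = reconstruct_integer_confusion(0.333, 0.907, 795, 1059, printed_mcc=0.299)
        assert round(mcc(cm), 3) == 0.299


class TestScan:
    def test_coarse_grid_has_31_rows(self):
        values = np.linspace(0.1, 10, 200)
        labels = (values > 4).astype(int)
        rows = scan_cutoffs(values, labels, COARSE_GRID)
        assert len(rows) == 31
        assert rows[0].cutoff == pytest.approx(0.30)
        assert rows[-1].cutoff == pytest.approx(7.80)

    def test_monotone_staircases(self):
        values = np.arange(1, 11, dtype=float)
        labels = (values > 5).astype(int)
        rows = scan_cutoffs(values, labels, (0.5, 10.5, 1.0))
        sens = [r.sensitivity for r in rows]
        spec = [r.specificity for r in rows]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_fine_grid_nests_coarse_optimum(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(1, 0.6, 400)
        labels = (rng.random(400) < 1 / (1 + np.exp(-(values - 3)))).astype(int)
        rows = scan_cutoffs(values, labels, COARSE_GRID)
        cut, _ = best_cutoff_by_mcc(rows)
        fine = scan_cutoffs(values, labels, (cut - 0.25, cut + 0.25, 0.05))
        assert any(math.isclose(r.cutoff, cut, abs_tol=1e-9) for r in fine)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_scan_monotonicity_property(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(0.8, 0.7, 150)
        labels = rng.integers(0, 2, 150)
        if labels.all() or not labels.any():
            return
        rows = scan_cutoffs(values, labels, (0.2, 8.0, 0.2))
        sens = [r.sensitivity for r in rows]
        spec = [r.specificity for r in rows]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))


class TestBestCutoff:
    def test_singleton(self):
        rows = scan_cutoffs([1.0, 2.0], [0, 1], (1.5, 1.5, 1.0))
        cut, row = best_cutoff_by_mcc(rows)
        assert cut == 1.5 and row is rows[0]

    def test_tie_breaks_to_larger_cutoff(self):
        # two cutoffs in the same gap produce identical confusion matrices
        rows = scan_cutoffs([1.0, 1.0, 4.0, 4.0], [0, 0, 1, 1], (2.0, 3.0, 1.0))
        assert rows[0].mcc == rows[1].mcc == 1.0
        cut, _ = best_cutoff_by_mcc(rows)
        assert cut == 3.0

    def test_empty_scan_errors(self):
        with pytest.raises(CutoffError):
            best_cutoff_by_mcc([])


class TestRoc:
    def test_perfect_scan_auc_one(self):
        rows = scan_cutoffs([1, 1, 4, 4], [0, 0, 1, 1], (0.5, 4.5, 0.5))
        assert roc_auc(rows).auc == pytest.approx(1.0)

    def test_null_marker_auc_near_half(self):
        rng = np.random.default_rng(12)
        values = rng.lognormal(1, 0.5, 2000)
        labels = rng.integers(0, 2, 2000)  # independent of values
        rows = scan_cutoffs(values, labels, (0.2, 12.0, 0.1))
        assert roc_auc(rows).auc == pytest.approx(0.5, abs=0.05)

    def test_degenerate_anchors_only(self):
        # a scan whose points all coincide with the anchors
        rows = scan_cutoffs([1.0, 2.0], [0, 1], (0.0, 3.0, 3.0))
        assert roc_auc(rows).auc == pytest.approx(0.5)

    def test_auc_close_to_rank_statistic(self):
        # on a dense grid the scan ROC approaches the exact rank AUC
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.lognormal(0.7, 0.5, 500), rng.lognormal(1.4, 0.5, 500)])
        labels = np.repeat([0, 1], 500)
        rows = scan_cutoffs(values, labels, (0.01, 25.0, 0.01))
        assert roc_auc(rows).auc == pytest.approx(
            roc_auc_score(labels, values), abs=5e-3
        )

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.5, 7.5, 120)
        labels = rng.integers(0, 2, 120)
        if labels.all() or not labels.any():
            return
        grid_pts = np.quantile(values, np.linspace(0, 1, 40))
        rows = [
            r
            for g in grid_pts
            for r in scan_cutoffs(values, labels, (float(g), float(g), 1.0))
        ]
        transformed = np.exp(values)  # strictly monotone
        rows_t = [
            r
            for g in np.exp(grid_pts)
            for r in scan_cutoffs(transformed, labels, (float(g), float(g), 1.0))
        ]
        assert roc_auc(rows).auc == pytest.approx(roc_auc(rows_t).auc, abs=1e-12)


class TestBands:
    def test_one_per_band(self):
        b = reference_bands([1, 3, 5], 2.6, 3.8)
        assert b == pytest.approx({"normal": 1 / 3, "borderline_high": 1 / 3, "high": 1 / 3})

    def test_all_below(self):
        b = reference_bands([1, 2], 2.6, 3.8)
        assert b["normal"] == 1.0 and b["high"] == 0.0

    def test_bounds_validated(self):
        with pytest.raises(CutoffError):
            reference_bands([1.0], 3.8, 2.6)

    @given(st.lists(st.floats(0.01, 20), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_fractions_sum_to_one(self, values):
        b = reference_bands(values, 2.6, 3.8)
        assert sum(b.values()) == pytest.approx(1.0, abs=1e-12)


def test_cutoff_grid_robust_to_float_step():
    g = cutoff_grid(*COARSE_GRID)
    assert len(g) == 31
    assert g[-1] == pytest.approx(7.80)
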