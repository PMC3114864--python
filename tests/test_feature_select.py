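import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from homacut import (
    SupervisedDataset,
    cv_auroc,
    dichotomize_outcome,
    select_features,
    train_blr_laplace,
    train_linear_svm,
)
from homacut.feature_select import (
    FeatureRanking,
    FeatureSelectError,
    blr_objective,
    rank_auroc,
)


def _toy(n=100, p=4, informative=None, effect=1.5, seed=0):
    """Class-shifted Gaussian features; `informative` columns shift by
    `effect` standard deviations with the binary class."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    x = rng.standard_normal((n, p))
    for j in informative or []:
        x[:, j] += effect * y
    if y.all() or not y.any():
        raise AssertionError("degenerate toy draw")
    return SupervisedDataset.from_raw(x, y, [f"v{j}" for j in range(p)]), y


class TestDichotomize:
    def test_median_split(self):
        assert dichotomize_outcome([1, 2, 3, 4]).tolist() == [0, 0, 1, 1]

    def test_threshold_rule(self):
        out = dichotomize_outcome([3.7, 3.9], rule="threshold", threshold=3.80)
        assert out.tolist() == [0, 1]

    def test_constant_vector_rejected(self):
        with pytest.raises(FeatureSelectError, match="degenerate"):
            dichotomize_outcome([2.0, 2.0, 2.0])


class TestLinearSvm:
    def test_separable_feature_dominates(self):
        rng = np.random.default_rng(1)
        n = 100
        y = np.repeat([0, 1], n // 2)
        x = np.column_stack([np.where(y == 1, 2.0, -2.0) + 0.1 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        data = SupervisedDataset.from_raw(x, y, ["signal", "noise"])
        fit = train_linear_svm(data, seed=0)
        assert abs(fit.weights[0]) > abs(fit.weights[1])
        assert fit.order[0] == "signal"

    def test_duplicated_column_symmetry(self):
        # L2 regularization splits weight equally between identical columns
        rng = np.random.default_rng(7)
        n = 100
        y = (rng.random(n) < 0.5).astype(int)
        base = rng.standard_normal(n) + 1.2 * y
        noise = rng.standard_normal(n)
        x = np.column_stack([base, base.copy(), noise])
        data = SupervisedDataset.from_raw(x, y, ["a", "a_dup", "b"])
        fit = train_linear_svm(data, seed=0)
        assert abs(abs(fit.weights[0]) - abs(fit.weights[1])) < 1e-3

    def test_invalid_c(self):
        data, _ = _toy()
        with pytest.raises(FeatureSelectError):
            train_linear_svm(data, C=0.0)


class TestBlrLaplace:
    def test_huge_prior_zeroes_all_weights(self):
        data, y = _toy(seed=3)
        fit = train_blr_laplace(data, prior_scale=1e6)
        assert (fit.weights == 0.0).all()
        prevalence = y.mean()
        assert fit.intercept == pytest.approx(
            np.log(prevalence / (1 - prevalence)), abs=1e-6
        )

    def test_tiny_prior_matches_unpenalized_mle(self):
        # independent oracle: generic optimizer on the same likelihood
        data, _ = _toy(n=50, p=3, informative=[0], seed=5)
        fit = train_blr_laplace(data, prior_scale=1e-4)

        def nll(params):
            b, c = params[:3], params[3]
            s = (2 * data.y - 1) * (data.x @ b + c)
            return np.logaddexp(0, -s).sum()

        res = minimize(nll, np.zeros(4), method="BFGS", options={"gtol": 1e-10})
        assert np.max(np.abs(fit.weights - res.x[:3])) < 1e-3
        assert abs(fit.intercept - res.x[3]) < 1e-3

    def test_informative_ranked_above_noise(self):
        data, _ = _toy(n=500, p=10, informative=[0, 1, 2], effect=1.5, seed=11)
        fit = train_blr_laplace(data, prior_scale=1.0)
        ranks = {v: i for i, v in enumerate(fit.order)}
        worst_informative = max(ranks[f"v{j}"] for j in (0, 1, 2))
        best_noise = min(ranks[f"v{j}"] for j in range(3, 10))
        assert worst_informative < best_noise

    def test_zero_count_monotone_in_prior_scale(self):
        data, _ = _toy(n=80, p=6, informative=[0, 1], seed=13)
        zero_counts = [
            int((train_blr_laplace(data, prior_scale=lam).weights == 0.0).sum())
            for lam in (0.01, 0.1, 1.0, 5.0, 20.0, 200.0)
        ]
        assert zero_counts == sorted(zero_counts)
        assert zero_counts[-1] == 6

    def test_objective_non_increasing_enforced(self):
        # the solver raises if any sweep raises the penalized objective;
        # a normal run completing implies monotone descent
        data, _ = _toy(n=60, p=5, informative=[0], seed=17)
        fit = train_blr_laplace(data, prior_scale=0.5)
        loose = blr_objective(data.x, data.y, np.zeros(5), 0.0, 0.5)
        tight = blr_objective(data.x, data.y, fit.weights, fit.intercept, 0.5)
        assert tight <= loose


class TestSvmBlrRecovery:
    @pytest.mark.parametrize("trainer_name", ["svm", "blr"])
    def test_class_shifted_above_noise_across_replicates(self, trainer_name):
        # both screens put every shifted variable above every noise variable
        # in at least 95% of seeded replicates
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            data, _ = _toy(n=300, p=6, informative=[0, 1], effect=1.5, seed=seed)
            if trainer_name == "svm":
                fit = train_linear_svm(data, seed=seed)
            else:
                fit = train_blr_laplace(data, prior_scale=1.0)
            ranks = {v: i for i, v in enumerate(fit.order)}
            if max(ranks["v0"], ranks["v1"]) < min(ranks[f"v{j}"] for j in range(2, 6)):
                wins += 1
        assert wins >= 95


class TestAuroc:
    def test_perfect_ranking(self):
        assert rank_auroc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert rank_auroc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_reversed_ranking(self):
        assert rank_auroc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200)
        assert rank_auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_cv_requires_two_folds(self):
        data, _ = _toy()
        with pytest.raises(FeatureSelectError):
            cv_auroc(data, lambda d: train_linear_svm(d), k_folds=1)

    def test_permutation_null_calibration(self):
        # mean CV AUROC over label permutations of a pure-noise problem
        rng = np.random.default_rng(23)
        x = rng.standard_normal((100, 3))
        y = np.repeat([0, 1], 50)
        aucs = []
        for _ in range(200):
            yp = rng.permutation(y)
            data = SupervisedDataset.from_raw(x, yp, ["a", "b", "c"])
            aucs.append(
                cv_auroc(data, lambda d: train_linear_svm(d, seed=0), k_folds=5, seed=0)
            )
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)


class TestSelectFeatures:
    RANK = FeatureRanking(("v1", "v2", "v3"), np.array([0.9, 0.0, -0.4]), 0.0, "blr")

    def test_nonzero_rule(self):
        assert select_features(self.RANK, "nonzero") == ["v1", "v3"]

    def test_top_m_rule(self):
        assert select_features(self.RANK, "top_m", m=1) == ["v1"]

    def test_weight_floor_empty_selection_errors(self):
        with pytest.raises(FeatureSelectError, match="empty"):
            select_features(self.RANK, "weight_floor", floor=1.0)
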