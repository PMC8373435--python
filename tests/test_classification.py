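import itertools

import numpy as np
import pytest
from scipy import optimize

from brs_eeg.classification import (
    ClassificationError,
    CVResult,
    ParamGrid,
    grid_search_svm,
    lda_decide,
    lda_fit,
    lda_predict,
    lopo_cv,
    sfs_select,
    svm_decide,
    svm_fit,
    svm_predict,
)


def two_clusters(n_per=10, sep=5.0, d=2, seed=0):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(loc=sep / 2, size=(n_per, d))
    Xn = rng.normal(loc=-sep / 2, size=(n_per, d))
    X = np.vstack([Xp, Xn])
    y = np.array(["pos"] * n_per + ["neg"] * n_per)
    return X, y


class TestLDA:
    def test_midpoint_scores_zero_with_equal_priors(self):
        X, y = two_clusters(seed=1)
        model = lda_fit(X, y, positive="pos", priors="equal")
        mid = (model.mu_p + model.mu_n) / 2
        assert lda_decide(model, mid) == pytest.approx(0.0, abs=1e-10)

    def test_one_dimensional_closed_form_score_2x(self):
        # mu_P = 1, mu_N = -1, pooled covariance 1, equal priors -> score = 2x.
        # Each class contributes centered sum of squares 2; pooled divisor is
        # n - 2 = 4, so the pooled covariance is exactly 1.
        base = np.array([0.0, 1.0, -1.0])
        Xp = (1.0 + base).reshape(-1, 1)
        Xn = (-1.0 + base).reshape(-1, 1)
        X = np.vstack([Xp, Xn])
        y = np.array(["P"] * 3 + ["N"] * 3)
        model = lda_fit(X, y, positive="P", priors="equal")
        assert model.mu_p[0] == pytest.approx(1.0)
        assert model.cov[0, 0] == pytest.approx(1.0)
        assert lda_decide(model, np.array([0.5])) == pytest.approx(1.0, rel=1e-10)
        assert lda_decide(model, np.array([2.0])) == pytest.approx(4.0, rel=1e-10)

    def test_log_term_vanishes_with_equal_priors_and_penalties(self):
        X, y = two_clusters(seed=2)
        m_eq = lda_fit(X, y, positive="pos", priors="equal", penalties=(1, 1))
        m_cc = lda_fit(X, y, positive="pos", priors="equal", penalties=(3.5, 3.5))
        x = np.zeros(2)
        assert lda_decide(m_eq, x) == pytest.approx(lda_decide(m_cc, x), rel=1e-12)

    def test_affine_invariance_of_decisions(self):
        X, y = two_clusters(n_per=15, sep=2.0, d=3, seed=3)
        rng = np.random.default_rng(4)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        Xt = X @ A.T + b
        test = rng.normal(size=(20, 3))
        s1 = lda_decide(lda_fit(X, y, positive="pos"), test)
        s2 = lda_decide(lda_fit(Xt, y, positive="pos"), test @ A.T + b)
        np.testing.assert_allclose(s1, s2, rtol=1e-8)

    def test_singular_covariance_without_shrinkage_errors(self):
        # 5 points in 10 dimensions: rank-deficient pooled covariance
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 10))
        y = np.array(["a", "a", "b", "b", "b"])
        with pytest.raises(ClassificationError, match="shrinkage"):
            lda_fit(X, y, shrinkage=0)
        model = lda_fit(X, y)  # auto shrinkage succeeds
        assert model.shrinkage > 0
        assert np.all(np.isfinite(lda_decide(model, X)))

    def test_one_class_input_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ClassificationError):
            lda_fit(X, ["a", "a", "a", "a"])

    def test_predictions_match_score_sign(self):
        X, y = two_clusters(seed=6)
        model = lda_fit(X, y, positive="pos")
        scores = lda_decide(model, X)
        preds = lda_predict(model, X)
        np.testing.assert_array_equal(preds == "pos", scores > 0)


def qp_rbf_svm_decision(X, y_signed, C, gamma, X_test):
    """Brute-force dual QP oracle for the soft-margin RBF SVM."""
    n = len(y_signed)
    sq = np.sum(X**2, axis=1)
    K = np.exp(-gamma * (sq[:, None] + sq[None, :] - 2 * X @ X.T))
    Q = (y_signed[:, None] * y_signed[None, :]) * K

    def objective(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    cons = {"type": "eq", "fun": lambda a: a @ y_signed, "jac": lambda a: y_signed}
    res = optimize.minimize(
        objective, x0=np.full(n, min(C, 1.0) / 2), jac=grad,
        bounds=[(0, C)] * n, constraints=[cons],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    sv = a > 1e-8
    on_margin = sv & (a < C - 1e-8)
    # bias from the KKT conditions at on-margin support vectors
    idx = np.where(on_margin if on_margin.any() else sv)[0]
    b = np.mean([y_signed[i] - (a * y_signed) @ K[:, i] for i in idx])
    sq_t = np.sum(X_test**2, axis=1)
    Kt = np.exp(-gamma * (sq[:, None] + sq_t[None, :] - 2 * X @ X_test.T))
    return (a * y_signed) @ Kt + b


class TestSVM:
    def test_separable_pair_signs(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]] * 2)
        y = np.array([-1, 1, -1, 1])
        model = svm_fit(X, y, C=1e6, gamma=1.0)
        assert svm_decide(model, np.array([-1.0, 0.0])) < 0
        assert svm_decide(model, np.array([1.0, 0.0])) > 0
        assert list(svm_predict(model, X)) == [-1, 1, -1, 1]

    def test_decision_matches_qp_oracle_on_separable_set(self):
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.normal(loc=2.0, scale=0.5, size=(10, 2)),
            rng.normal(loc=-2.0, scale=0.5, size=(10, 2)),
        ])
        y = np.array([1] * 10 + [-1] * 10)
        C, gamma = 1e3, 1.0
        model = svm_fit(X, y, C=C, gamma=gamma)
        test = rng.normal(scale=2.0, size=(8, 2))
        ours = svm_decide(model, test)
        oracle = qp_rbf_svm_decision(X, y.astype(float), C, gamma, test)
        np.testing.assert_allclose(ours, oracle, atol=1e-4)

    def test_kernel_diagonal_is_one(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.0], [0.0, 0.7]])
        y = [1, 1, -1, -1]
        model = svm_fit(X, y, C=10, gamma=2.0)
        sv = model.support_vectors
        k_self = np.exp(-2.0 * np.sum((sv - sv) ** 2, axis=1))
        np.testing.assert_array_equal(k_self, 1.0)

    def test_non_finite_features_rejected(self):
        X = np.array([[0.0], [np.nan], [1.0], [2.0]])
        with pytest.raises(ClassificationError):
            svm_fit(X, [0, 0, 1, 1])

    def test_invalid_hyperparameters_rejected(self):
        X, y = two_clusters(n_per=3)
        with pytest.raises(ClassificationError):
            svm_fit(X, y, C=0.0)
        with pytest.raises(ClassificationError):
            svm_fit(X, y, gamma=-1.0)


class TestLopoCV:
    def test_well_separated_clusters_perfect_accuracy(self):
        for seed in range(10):
            X, y = two_clusters(n_per=10, sep=10.0, seed=seed)
            cv = lopo_cv(X, y, "lda")
            assert cv.accuracy == 1.0

    def test_accuracy_granularity_one_over_n(self):
        X, y = two_clusters(n_per=25, sep=1.0, seed=8)
        cv = lopo_cv(X, y, "lda")
        assert cv.n == 50
        # one fold flip changes accuracy by exactly 1/50 = 2%
        assert (cv.accuracy * 50) == pytest.approx(round(cv.accuracy * 50))

    def test_permuted_labels_accuracy_near_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 3))
        accs = []
        for _ in range(100):
            y = rng.permutation(["a"] * 10 + ["b"] * 10)
            accs.append(lopo_cv(X, y, "lda").accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_fold_train_standardization(self):
        rng = np.random.default_rng(10)
        raw = np.vstack([
            rng.normal(loc=1.0, scale=0.1, size=(8, 2)),   # HC raw similarities
            rng.normal(loc=0.5, scale=0.1, size=(8, 2)),   # patients
        ])
        y = np.array(["HC"] * 8 + ["MCI"] * 8)
        hc_mask = y == "HC"
        cv = lopo_cv(raw, y, "lda", std_mode="fold-train", hc_mask=hc_mask)
        assert cv.accuracy > 0.8

    def test_fold_train_needs_enough_hcs(self):
        X, y = two_clusters(n_per=3, seed=11)
        hc_mask = np.zeros(6, dtype=bool)
        hc_mask[0] = True
        with pytest.raises(ClassificationError, match="HC"):
            lopo_cv(X, y, "lda", std_mode="fold-train", hc_mask=hc_mask)

    def test_small_or_one_class_inputs_rejected(self):
        with pytest.raises(ClassificationError):
            lopo_cv(np.zeros((2, 1)), ["a", "b"], "lda")
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ClassificationError):
            lopo_cv(X, ["a", "a", "a", "a", "b"], "lda")


class TestGridSearch:
    def test_default_grid_is_30_by_30(self):
        grid = ParamGrid.default()
        assert len(grid.Cs) == len(grid.gammas) == 30
        assert len(grid) == 900
        assert min(grid.Cs) == 2.0**-29 and max(grid.Cs) == 2.0**29

    def test_alternative_31_by_31_grid(self):
        grid = ParamGrid.from_exponents(range(-30, 31, 2))
        assert len(grid) == 961

    def test_single_point_grid_returned_as_is(self):
        X, y = two_clusters(n_per=5, sep=8.0, seed=12)
        grid = ParamGrid(Cs=(2.0,), gammas=(0.5,))
        res = grid_search_svm(X, y, grid)
        assert (res.C, res.gamma) == (2.0, 0.5)
        assert res.accuracy == lopo_cv(
            X, y, "svm", params={"C": 2.0, "gamma": 0.5}
        ).accuracy

    def test_tie_broken_toward_smallest_c_then_gamma(self):
        X, y = two_clusters(n_per=5, sep=10.0, seed=13)
        grid = ParamGrid(Cs=(8.0, 1024.0), gammas=(0.125, 1.0))
        res = grid_search_svm(X, y, grid)
        # separable data: many points reach accuracy 1; smallest C/gamma wins
        assert res.accuracy == 1.0
        assert res.C == 8.0
        assert res.gamma == 0.125


class TestSFS:
    @staticmethod
    def _planted(n_per=10, n_features=6, informative=2, seed=14):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(2 * n_per, n_features))
        y = np.array(["a"] * n_per + ["b"] * n_per)
        X[:n_per, informative] += 8.0  # only this feature separates
        return X, y

    def test_single_candidate_feature(self):
        X, y = self._planted(n_features=1, informative=0)
        trace = sfs_select(X, y, "lda")
        assert trace.order == (0,)
        assert trace.best_subset == (0,)

    def test_planted_feature_found_first_with_perfect_accuracy(self):
        X, y = self._planted()
        trace = sfs_select(X, y, "lda", feature_names=list("ABCDEF"))
        assert trace.order[0] == 2
        assert trace.best_score == 1.0
        assert trace.best_subset == (2,)
        assert trace.best_feature_names == ("C",)

    def test_agrees_with_exhaustive_subset_oracle(self):
        X, y = self._planted(n_per=8)
        trace = sfs_select(X, y, "lda")
        best_exhaustive = max(
            lopo_cv(X[:, s], y, "lda").accuracy
            for r in range(1, 7)
            for s in itertools.combinations(range(6), r)
        )
        assert trace.best_score == best_exhaustive == 1.0

    def test_chain_is_permutation_and_best_dominates_steps(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(16, 5))
        y = np.array(["a"] * 8 + ["b"] * 8)
        trace = sfs_select(X, y, "lda")
        assert sorted(trace.order) == list(range(5))
        assert trace.best_score == max(trace.step_scores)
        assert trace.best_score >= trace.step_scores[0]

    def test_svm_sfs_reports_grid_params(self):
        X, y = self._planted(n_per=6)
        grid = ParamGrid(Cs=(1.0, 16.0), gammas=(0.1, 1.0))
        trace = sfs_select(X, y, "svm", grid=grid)
        assert trace.params in [(c, g) for c in (1.0, 16.0) for g in (0.1, 1.0)]
        assert trace.best_score == 1.0
        assert trace.order[0] == 2


class TestCVResult:
    def test_accuracy_definition(self):
        cv = CVResult(folds=(("p1", "a", "a"), ("p2", "a", "b"), ("p3", "b", "b")))
        assert cv.accuracy == pytest.approx(2 / 3)
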