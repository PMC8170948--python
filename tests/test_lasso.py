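"""Penalized-model contracts: null limit, oracle agreement, KKT
stationarity, CV curve definition, and the composite lambda rule."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from prevmap.errors import InputError
from prevmap.lasso import (
    CvCurve,
    LassoPath,
    SelectedFit,
    cv_misclassification,
    fit_lasso_logit_path,
    kkt_violations,
    lasso_logit_cv,
    predict_probabilities,
    select_lambda,
)


def _toy(n=500, p=3, seed=0, beta=None, intercept=-1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    beta = np.array([1.0, -0.5, 0.25][:p]) if beta is None else beta
    eta = intercept + X.to_numpy() @ beta
    y = (rng.random(n) < expit(eta)).astype(float)
    return X, y


class TestPathFit:
    def test_null_model_at_largest_lambda(self):
        X, y = _toy()
        path = fit_lasso_logit_path(X, y)
        assert path.nnz[0] == 0
        assert np.allclose(path.coefs[0], 0.0)
        assert path.intercepts[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)

    def test_grid_strictly_decreasing(self):
        X, y = _toy()
        path = fit_lasso_logit_path(X, y)
        assert (np.diff(path.lambda_grid) < 0).all()

    def test_unpenalized_mle_limit(self):
        X, y = _toy(n=500, p=3)
        path = fit_lasso_logit_path(X, y, n_lambda=100, lambda_min_ratio=1e-5)
        mle = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        ours = np.r_[path.intercepts[-1], path.coefs[-1]]
        rel = np.max(np.abs(ours - mle.params) / np.abs(mle.params))
        assert rel < 1e-3

    def test_kkt_holds_along_path(self):
        X, y = _toy(n=600, p=12, beta=np.r_[1.0, -0.7, 0.4, np.zeros(9)])
        path = fit_lasso_logit_path(X, y)
        assert kkt_violations(path, X, y).max() < 1e-6

    def test_matches_statsmodels_l1_oracle_mid_path(self):
        X, y = _toy(n=400, p=6, beta=np.r_[1.2, -0.8, 0.5, 0, 0, 0])
        path = fit_lasso_logit_path(X, y, n_lambda=30, lambda_min_ratio=0.05)
        sd = X.to_numpy().std(axis=0)
        n = len(y)
        for k in (10, 20):
            lam = path.lambda_grid[k]
            alpha = np.r_[0.0, lam * sd * n]
            oracle = sm.Logit(y, sm.add_constant(X.to_numpy())).fit_regularized(
                method="l1", alpha=alpha, disp=0, acc=1e-12, maxiter=2000
            )
            ours = np.r_[path.intercepts[k], path.coefs[k]]
            assert np.max(np.abs(ours - oracle.params)) < 1e-4

    def test_coefficients_on_original_scale(self):
        # rescaling a column by c rescales its coefficient by 1/c
        X, y = _toy(n=800, p=3, seed=4)
        X2 = X.copy()
        X2["x0"] = X2["x0"] * 10
        grid = fit_lasso_logit_path(X, y).lambda_grid
        a = fit_lasso_logit_path(X, y, lambda_grid=grid)
        b = fit_lasso_logit_path(X2, y, lambda_grid=grid)
        np.testing.assert_allclose(b.coefs[:, 0] * 10, a.coefs[:, 0], atol=1e-6)

    def test_single_class_rejected(self):
        X, _ = _toy()
        with pytest.raises(InputError):
            fit_lasso_logit_path(X, np.zeros(len(X)))

    def test_nonfinite_rejected(self):
        X, y = _toy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(InputError):
            fit_lasso_logit_path(X, y)


class TestCvCurve:
    def test_perfect_separator_reaches_zero_error(self):
        rng = np.random.default_rng(1)
        y = (rng.random(300) < 0.4).astype(float)
        X = pd.DataFrame({"s": y + rng.normal(0, 0.01, 300), "n": rng.normal(size=300)})
        cv = cv_misclassification(X, y, k=5, seed=2)
        assert cv.mean_error.min() == 0.0

    def test_pure_noise_error_near_prevalence(self):
        rng = np.random.default_rng(3)
        y = (rng.random(2000) < 0.3).astype(float)
        X = pd.DataFrame(rng.normal(size=(2000, 5)), columns=list("abcde"))
        cv = cv_misclassification(X, y, k=5, seed=4)
        se = np.sqrt(0.3 * 0.7 / 2000)
        assert abs(cv.mean_error.min() - 0.3) < 4 * se

    def test_se_is_sd_over_sqrt_k(self):
        X, y = _toy(n=300)
        cv = cv_misclassification(X, y, k=6, seed=5)
        np.testing.assert_allclose(
            cv.se_error,
            cv.fold_errors.std(axis=0, ddof=1) / np.sqrt(6),
            rtol=1e-12,
        )

    def test_fold_count_validated(self):
        X, y = _toy(n=30)
        with pytest.raises(InputError):
            cv_misclassification(X, y, k=1)


def _fixture_pair(lambdas, mean, se, nnz):
    """Hand-constructed CV-curve/path pair for exercising the rule."""
    K = len(lambdas)
    path = LassoPath(
        lambda_grid=np.asarray(lambdas, float),
        coefs=np.array([[1.0] * c + [0.0] * (max(nnz) - c) for c in nnz]),
        intercepts=np.zeros(K),
        nnz=np.asarray(nnz),
        columns=[f"c{i}" for i in range(max(nnz))],
        kkt_viol=np.zeros(K),
    )
    cv = CvCurve(
        lambda_grid=np.asarray(lambdas, float),
        mean_error=np.asarray(mean, float),
        se_error=np.asarray(se, float),
        k=10,
        seed=0,
    )
    return cv, path


class TestSelectLambda:
    def test_one_se_branch_when_it_keeps_more(self):
        # min at index 3 (err .10, se .02) -> 1-SE lambda is index 1 (.11 <= .12)
        cv, path = _fixture_pair(
            [1.0, 0.5, 0.25, 0.125, 0.0625],
            [0.20, 0.11, 0.115, 0.10, 0.12],
            [0.02] * 5,
            [0, 15, 18, 20, 25],
        )
        fit = select_lambda(cv, path, min_predictors=10)
        assert fit.branch == "one_se" and fit.lambda_ == 0.5 and fit.nnz == 15

    def test_min_predictor_branch_when_one_se_too_sparse(self):
        cv, path = _fixture_pair(
            [1.0, 0.5, 0.25, 0.125, 0.0625],
            [0.20, 0.11, 0.115, 0.10, 0.12],
            [0.02] * 5,
            [0, 4, 8, 10, 12],
        )
        fit = select_lambda(cv, path, min_predictors=10)
        assert fit.branch == "min_predictors" and fit.lambda_ == 0.125
        assert fit.nnz >= 10

    def test_identical_candidates_tie(self):
        cv, path = _fixture_pair(
            [1.0, 0.5, 0.25],
            [0.20, 0.10, 0.15],
            [0.001] * 3,
            [0, 10, 12],
        )
        fit = select_lambda(cv, path, min_predictors=10)
        assert fit.lambda_ == 0.5

    def test_equal_nnz_takes_larger_lambda(self):
        cv, path = _fixture_pair(
            [1.0, 0.5, 0.25, 0.125],
            [0.20, 0.10, 0.12, 0.13],
            [0.001] * 4,
            [0, 12, 11, 12],
        )
        fit = select_lambda(cv, path, min_predictors=12)
        assert fit.lambda_ == 0.5

    def test_fallback_when_grid_never_reaches_min(self):
        cv, path = _fixture_pair(
            [1.0, 0.5], [0.2, 0.1], [0.001] * 2, [0, 3]
        )
        with pytest.warns(UserWarning, match="falling back"):
            fit = select_lambda(cv, path, min_predictors=10)
        assert fit.lambda_ == 0.5

    def test_invariant_to_duplicated_grid_points(self):
        lambdas = [1.0, 0.5, 0.25, 0.125, 0.0625]
        mean = [0.20, 0.11, 0.115, 0.10, 0.12]
        nnz = [0, 15, 18, 20, 25]
        cv, path = _fixture_pair(lambdas, mean, [0.02] * 5, nnz)
        dup_idx = [0, 1, 1, 2, 3, 3, 4]
        cv2, path2 = _fixture_pair(
            [lambdas[i] for i in dup_idx],
            [mean[i] for i in dup_idx],
            [0.02] * 7,
            [nnz[i] for i in dup_idx],
        )
        a = select_lambda(cv, path, min_predictors=10)
        b = select_lambda(cv2, path2, min_predictors=10)
        assert a.lambda_ == b.lambda_ and a.nnz == b.nnz

    def test_mismatched_grids_rejected(self):
        cv, path = _fixture_pair([1.0, 0.5], [0.2, 0.1], [0.01] * 2, [0, 5])
        cv.lambda_grid = cv.lambda_grid * 2
        with pytest.raises(InputError):
            select_lambda(cv, path)


class TestPredict:
    def test_zero_model_gives_half(self):
        fit = SelectedFit(0.1, "one_se", 0.0, pd.Series({"a": 0.0, "b": 0.0}), 0)
        X = pd.DataFrame({"a": [1.0, -2.0], "b": [0.5, 3.0]})
        np.testing.assert_allclose(predict_probabilities(fit, X), [0.5, 0.5])

    def test_inverse_logit_closed_form(self):
        fit = SelectedFit(0.1, "one_se", 0.0, pd.Series({"a": 1.0}), 1)
        p = predict_probabilities(fit, pd.DataFrame({"a": [1.0]}))
        assert p[0] == pytest.approx(0.7311, abs=5e-5)

    def test_roundtrip_matches_path_fitted_values(self):
        X, y = _toy(n=400, p=5, beta=np.r_[1.0, -0.5, 0.25, 0, 0])
        fit, path, cv = lasso_logit_cv(X, y, k=5, seed=6, n_lambda=40)
        p1 = predict_probabilities(fit, X)
        k = int(np.nonzero(path.lambda_grid == fit.lambda_)[0][0])
        eta = path.intercepts[k] + X.to_numpy() @ path.coefs[k]
        np.testing.assert_allclose(p1, expit(eta), rtol=1e-12)

    def test_column_mismatch_lists_names(self):
        fit = SelectedFit(0.1, "one_se", 0.0, pd.Series({"a": 1.0, "b": 2.0}), 2)
        with pytest.raises(InputError, match="missing.*'b'"):
            predict_probabilities(fit, pd.DataFrame({"a": [1.0], "c": [2.0]}))


class TestSelectedFitSerialization:
    def test_csv_roundtrip_exact(self, tmp_path):
        X, y = _toy(n=300, p=4, beta=np.r_[1.0, -0.5, 0.25, 0])
        fit, _, _ = lasso_logit_cv(X, y, k=4, seed=7, n_lambda=30)
        path = tmp_path / "fit.csv"
        fit.to_csv(path)
        back = SelectedFit.from_csv(path)
        assert back.lambda_ == fit.lambda_
        assert back.branch == fit.branch
        assert back.intercept == fit.intercept
        assert back.nnz == fit.nnz
        pd.testing.assert_series_equal(back.coefficients, fit.coefficients)


def test_informative_predictors_recovered():
    """With a few strong predictors among noise, the selected active set
    contains the informative ones in nearly all replicates."""
    hits = 0
    reps = 8
    for r in range(reps):
        rng = np.random.default_rng(100 + r)
        n, p = 4000, 40
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)]
        )
        informative = [0, 1, 2, 3, 4]
        beta = np.zeros(p)
        beta[informative] = [1.0, -1.0, 0.8, -0.8, 0.6]
        y = (rng.random(n) < expit(-2.0 + X.to_numpy() @ beta)).astype(float)
        fit, _, _ = lasso_logit_cv(X, y, k=5, seed=r, n_lambda=60)
        active = set(np.nonzero(fit.coefficients.to_numpy())[0])
        hits += set(informative) <= active
    assert hits >= int(0.9 * reps)
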