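"""Preprocessing: EM imputation, transforms, factor analysis, composites."""

import numpy as np
import pytest
from scipy import stats as sps

from twinace import (
    bartlett_scores,
    composite_scores,
    cronbach_alpha,
    cronbach_alpha_from_cov,
    em_impute,
    fit_single_factor,
    log_transform,
    moment_screen,
    preprocess_cohort,
    residualize,
    simulate_cohort,
)
from twinace.preprocess import FactorSolution, clip_items


class TestEMImpute:
    def test_complete_data_returned_unchanged(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        out, rep = em_impute(X)
        assert np.array_equal(out, X)
        assert rep["n_iter"] == 0

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 5))
        M = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[M] = np.nan
        out, _ = em_impute(Xm)
        assert np.array_equal(out[~M], X[~M])
        assert not np.isnan(out).any()

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(800, 3))
        X = Z @ np.linalg.cholesky(
            np.array([[1, 0.6, 0.3], [0.6, 1, 0.5], [0.3, 0.5, 1.0]])
        ).T
        X[rng.random(X.shape) < 0.15] = np.nan
        _, rep = em_impute(X, tol=1e-10, max_iter=50)
        ll = np.array(rep["loglik"])
        assert np.all(np.diff(ll) > -1e-6)

    def test_conditional_mean_slope_recovered(self):
        # bivariate normal r=0.9, MCAR on column 2: imputed values regress on
        # column 1 with the complete-data slope
        rng = np.random.default_rng(3)
        n = 5000
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        slope_full = np.polyfit(x1, x2, 1)[0]
        X = np.column_stack([x1, x2])
        miss = rng.random(n) < 0.10
        X[miss, 1] = np.nan
        out, _ = em_impute(X)
        slope_imp = np.polyfit(x1[miss], out[miss, 1], 1)[0]
        assert slope_imp == pytest.approx(slope_full, abs=0.05)

    def test_single_cell_equals_conditional_expectation_oracle(self):
        # brute-force oracle: conditional expectation from the converged
        # moments, computed by hand
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(300, 3))
        L = np.linalg.cholesky(
            np.array([[1, 0.7, 0.4], [0.7, 1, 0.5], [0.4, 0.5, 1.0]])
        )
        X = Z @ L.T
        X[7, 2] = np.nan
        out, rep = em_impute(X, tol=1e-12, max_iter=500)
        mu, S = rep["mu"], rep["Sigma"]
        beta = np.linalg.solve(S[:2, :2], S[:2, 2])
        pred = mu[2] + (X[7, :2] - mu[:2]) @ beta
        assert out[7, 2] == pytest.approx(pred, abs=1e-8)

    def test_sparse_column_rejected(self):
        X = np.ones((5, 2))
        X[1:, 1] = np.nan
        with pytest.raises(ValueError, match="observed"):
            em_impute(X)


class TestTransforms:
    @pytest.mark.parametrize(
        "value,expected", [(1.0, 0.0), (5.0, 0.69897), (10.0, 1.0)]
    )
    def test_log10_values(self, value, expected):
        assert log_transform(np.array([value])).item() == pytest.approx(
            expected, abs=1e-5
        )

    def test_constant_column_zero_variance(self):
        out = log_transform(np.full((10, 1), 3.0))
        assert np.allclose(out, np.log10(3.0))
        assert out.var() == 0.0

    def test_values_below_one_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([0.5]))
        assert log_transform(clip_items(np.array([0.5]))).item() == 0.0


class TestMomentScreen:
    def test_normal_sample_unflagged(self):
        x = np.random.default_rng(5).standard_normal((100000, 1))
        rep = moment_screen(x)
        assert not rep["flag_skew"].any() and not rep["flag_kurtosis"].any()

    def test_constant_column_degenerate(self):
        rep = moment_screen(np.ones((10, 1)))
        assert rep["degenerate"].all()

    def test_exponential_skewness_near_two(self):
        x = np.random.default_rng(6).exponential(size=(100000, 1))
        rep = moment_screen(x)
        assert rep["skewness"].iloc[0] == pytest.approx(2.0, abs=0.1)
        assert not rep["flag_skew"].iloc[0]


class TestResidualize:
    def test_exact_linear_function_residuals_zero(self):
        age = np.linspace(18, 49, 200)
        y = (2 * age)[:, None]
        res = residualize(y, age)
        assert np.abs(res).max() < 1e-10

    def test_residual_variance_after_removing_covariates(self):
        rng = np.random.default_rng(7)
        n = 10000
        age = rng.uniform(18, 49, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = (age + sex + rng.standard_normal(n))[:, None]
        res = residualize(y, np.column_stack([age, sex]))
        assert res.var(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(8)
        C = rng.normal(size=(500, 2))
        Y = rng.normal(size=(500, 3))
        res = residualize(Y, C)
        Cc = C - C.mean(axis=0)
        dots = np.abs(Cc.T @ res) / (
            np.linalg.norm(Cc, axis=0)[:, None] * np.linalg.norm(res, axis=0)
        )
        assert dots.max() < 1e-8

    def test_collinear_covariates_rejected(self):
        age = np.linspace(18, 49, 100)
        with pytest.raises(ValueError, match="rank deficient"):
            residualize(np.random.default_rng(0).normal(size=(100, 1)),
                        np.column_stack([age, 2 * age]))


class TestFactorAnalysis:
    def test_one_factor_loading_recovery(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])
        rng = np.random.default_rng(9)
        n = 50000
        f = rng.standard_normal(n)
        X = f[:, None] * lam + rng.standard_normal((n, 5)) * np.sqrt(1 - lam**2)
        sol = fit_single_factor(X)
        assert np.allclose(sol.loadings, lam, atol=0.02)

    def test_perfectly_correlated_items_rejected(self):
        x = np.random.default_rng(10).standard_normal(1000)
        X = np.column_stack([x, x, np.random.default_rng(11).standard_normal(1000)])
        with pytest.raises(ValueError, match="singular"):
            fit_single_factor(X)

    def test_independent_items_null_factor(self):
        # ML loadings on null data scale like the fourth root of 1/n (they
        # absorb the largest sampling correlation), so assert that the fitted
        # factor explains a trivial share of every item's variance
        X = np.random.default_rng(12).standard_normal((50000, 5))
        sol = fit_single_factor(X)
        assert (sol.loadings**2).max() < 0.05
        assert sol.uniqueness.min() > 0.9

    def test_bartlett_slope_unbiased_vs_regression_method_shrunk(self):
        lam = np.array([0.7, 0.7, 0.7, 0.7, 0.7])
        rng = np.random.default_rng(13)
        n = 50000
        f = rng.standard_normal(n)
        X = f[:, None] * lam + rng.standard_normal((n, 5)) * np.sqrt(1 - lam**2)
        sol = fit_single_factor(X)
        scores = bartlett_scores(X, sol)
        slope = np.polyfit(f, scores, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)
        # regression-method comparison: shrunk toward 0 by the communality
        lamh, psih = sol.loadings, sol.uniqueness
        Sigma = np.outer(lamh, lamh) + np.diag(psih)
        w_reg = np.linalg.solve(Sigma, lamh)
        reg_scores = (X - X.mean(axis=0)) @ w_reg
        slope_reg = np.polyfit(f, reg_scores, 1)[0]
        assert slope_reg < slope and slope_reg < 0.95

    def test_single_item_score_proportional_to_centered_item(self):
        x = np.random.default_rng(14).standard_normal((1000, 1))
        sol = FactorSolution(
            loadings=np.array([1.0]), uniqueness=np.array([0.005]),
            mean=x.mean(axis=0),
        )
        s = bartlett_scores(x, sol)
        assert abs(np.corrcoef(s, x[:, 0])[0, 1]) > 0.999

    def test_mean_vector_scores_zero(self):
        sol = FactorSolution(
            loadings=np.array([0.8, 0.6]), uniqueness=np.array([0.36, 0.64]),
            mean=np.array([2.0, 3.0]),
        )
        assert bartlett_scores(np.array([[2.0, 3.0]]), sol).item() == 0.0


class TestAlphaAndComposites:
    def test_spearman_brown_closed_form(self):
        # 5 parallel items, inter-item r = 0.45: alpha = 5*.45/(1+4*.45)
        C = np.full((5, 5), 0.45)
        np.fill_diagonal(C, 1.0)
        assert cronbach_alpha_from_cov(C) == pytest.approx(
            5 * 0.45 / (1 + 4 * 0.45), abs=1e-12
        )

    def test_uncorrelated_items_alpha_zero(self):
        assert cronbach_alpha_from_cov(np.eye(2)) == pytest.approx(0.0)

    def test_duplicated_item_alpha_one(self):
        assert cronbach_alpha_from_cov(np.ones((2, 2))) == pytest.approx(1.0)

    def test_sample_alpha_matches_population_formula(self):
        rng = np.random.default_rng(15)
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        X = rng.multivariate_normal(np.zeros(4), C, size=100000)
        assert cronbach_alpha(X) == pytest.approx(
            cronbach_alpha_from_cov(C), abs=0.01
        )

    def test_composites_equal_when_items_constant_within_person(self):
        rng = np.random.default_rng(16)
        v = rng.standard_normal(100)
        X = np.tile(v[:, None], (1, 6))
        zs, zu = composite_scores(X, {0, 1, 2})
        assert np.allclose(zs, zu)

    def test_two_sample_z_pins_sd_convention(self):
        # composites (1, 3) -> z = (-1/sqrt(2), +1/sqrt(2)) under ddof=1
        X = np.array([[1.0, 1.0], [3.0, 3.0]])
        zs, zu = composite_scores(X, {0})
        assert zs == pytest.approx([-0.7071067811865475, 0.7071067811865475])

    def test_output_standardized(self):
        rng = np.random.default_rng(17)
        X = rng.uniform(1, 5, size=(500, 25))
        zs, zu = composite_scores(X, set(range(15)))
        for z in (zs, zu):
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            composite_scores(np.ones((5, 3)), set())


class TestPipeline:
    def test_full_preprocess_is_pure_and_complete(self):
        cohort = simulate_cohort(
            seed=21, n_per_group={"MZf": 300, "DZf": 300, "DZos": 200}
        )
        s1, r1 = preprocess_cohort(cohort)
        s2, _ = preprocess_cohort(cohort)
        assert s1.equals(s2)
        assert not s1.isna().any().any()
        for comp in ("family_specific", "family_unspecific"):
            assert s1[comp].mean() == pytest.approx(0.0, abs=1e-8)
            assert s1[comp].std(ddof=1) == pytest.approx(1.0, abs=1e-8)
        assert r1["pipeline_order"][0] == "reverse_code"

    def test_sex_covariate_removed_only_when_requested(self):
        cohort = simulate_cohort(
            seed=22, n_per_group={"MZf": 400, "MZm": 400, "DZf": 300,
                                  "DZm": 300}
        )
        s_sexadj, _ = preprocess_cohort(cohort, covariates=("age", "sex"))
        male = (s_sexadj["sex"] == "M").to_numpy()
        col = s_sexadj["emotional_abuse"].to_numpy()
        # after residualizing on sex, group means are equal
        assert abs(col[male].mean() - col[~male].mean()) < 1e-8
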