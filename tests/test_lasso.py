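"""Solver, penalty grid, tuning and pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lassoval as lv
from lassoval.lasso import pool_models
from lassoval.solver import lambda_max, standardize


def l1_objective(X, y, model, lam):
    """(1/2n)*RSS + lam*||beta_std||_1 on the standardised problem."""
    n = X.shape[0]
    Xs, _, scale, _ = standardize(X)
    beta = model.coefficients * scale
    resid = (y - y.mean()) - Xs @ beta
    return 0.5 * resid @ resid / n + lam * np.abs(beta).sum()


def oracle_objective(X, y, lam):
    """Convex-programming oracle: minimise the same objective via the smooth
    positive/negative-part split with L-BFGS-B (bound-constrained QP)."""
    from scipy.optimize import minimize

    n, p = X.shape
    Xs, _, _, _ = standardize(X)
    yc = y - y.mean()
    G = Xs.T @ Xs / n
    b = Xs.T @ yc / n
    c = 0.5 * yc @ yc / n

    def f(z):
        beta = z[:p] - z[p:]
        Gb = G @ beta
        val = c - b @ beta + 0.5 * beta @ Gb + lam * z.sum()
        g = Gb - b
        return val, np.concatenate([g + lam, -g + lam])

    res = minimize(f, np.zeros(2 * p), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * p,
                   options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12})
    return res.fun


def random_instance(rng, n=20, p=5):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * (rng.random(p) < 0.7)
    y = X @ beta + rng.standard_normal(n)
    return X, y


class TestFitLasso:
    def test_full_shrinkage_above_lambda_max(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng, 40, 6)
        lmax = lambda_max(X, y)
        for lam in (lmax, 1.5 * lmax):
            m = lv.fit_lasso(X, y, lam)
            assert np.all(m.coefficients == 0.0)
            assert m.intercept == pytest.approx(y.mean())

    def test_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng, 50, 5)
        m = lv.fit_lasso(X, y, 0.0)
        ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(50), X]), y, rcond=None)
        assert m.intercept == pytest.approx(ols[0], abs=1e-7)
        assert np.allclose(m.coefficients, ols[1:], atol=1e-7)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_convex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng)
        lam = 0.3 * lambda_max(X, y) * rng.random()
        m = lv.fit_lasso(X, y, lam)
        assert l1_objective(X, y, m, lam) == pytest.approx(oracle_objective(X, y, lam), abs=1e-6)

    def test_matches_sklearn(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(5)
        X, y = random_instance(rng, 80, 8)
        lam = 0.1
        m = lv.fit_lasso(X, y, lam)
        Xs, center, scale, _ = standardize(X)
        sk = Lasso(alpha=lam, fit_intercept=True, tol=1e-12).fit(Xs, y)
        assert np.allclose(m.coefficients * scale, sk.coef_, atol=1e-7)

    def test_constant_outcome_gives_intercept_only(self):
        X = np.random.default_rng(2).standard_normal((10, 3))
        m = lv.fit_lasso(X, np.full(10, 3.5), 0.1)
        assert np.all(m.coefficients == 0)
        assert m.intercept == 3.5

    def test_zero_variance_covariate_gets_zero_coefficient(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 3))
        X[:, 1] = 2.0
        y = X[:, 0] + rng.standard_normal(30) * 0.1
        m = lv.fit_lasso(X, y, 0.01)
        assert m.coefficients[1] == 0.0

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            lv.fit_lasso(np.ones((3, 1)), np.arange(3.0), -0.1)

    def test_l1_norm_monotone_along_path(self, cohort):
        grid = lv.make_penalty_grid(cohort, n_lambda=25)
        norms = [np.abs(lv.fit_lasso(cohort, lam).coefficients_std).sum() for lam in grid]
        # grid is descending, so the L1 norm grows along the list
        assert all(hi <= lo + 1e-10 for hi, lo in zip(norms, norms[1:]))


class TestPenaltyGrid:
    def test_default_length_and_shape(self, cohort):
        grid = lv.make_penalty_grid(cohort)
        assert grid.size == 40
        assert np.all(np.diff(grid) < 0)
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0])
        assert grid[0] / grid[-1] == pytest.approx(1000.0)

    def test_top_of_grid_shrinks_everything(self, cohort):
        grid = lv.make_penalty_grid(cohort)
        m = lv.fit_lasso(cohort, grid[0])
        assert np.all(m.coefficients == 0.0)

    def test_all_constant_covariates_rejected(self):
        with pytest.raises(ValueError):
            lv.make_penalty_grid(np.ones((10, 3)), np.arange(10.0))


class TestTunePenalty:
    def test_single_lambda_grid(self, cohort):
        grid = np.array([0.05])
        tr = lv.tune_penalty(cohort, grid, n_boot=5, seed=0)
        assert tr.best_lambda == tr.tolerance_lambda == 0.05

    def test_invariants_by_exhaustive_scan(self, cohort):
        tr = lv.tune_penalty(cohort, n_boot=20, seed=1, n_lambda=25)
        best_i = np.argmin(tr.mean_boot_mse)
        assert tr.best_lambda == tr.grid[best_i]
        assert tr.tolerance_lambda >= tr.best_lambda
        cutoff = 1.03 * tr.mean_boot_mse[best_i]
        assert tr.mean_boot_mse[list(tr.grid).index(tr.tolerance_lambda)] <= cutoff
        # no stronger penalty also satisfies the band
        for lam, mse_val in zip(tr.grid, tr.mean_boot_mse):
            if lam > tr.tolerance_lambda:
                assert mse_val > cutoff

    def test_deterministic_under_seed(self, cohort):
        a = lv.tune_penalty(cohort, n_boot=10, seed=3, n_lambda=15)
        b = lv.tune_penalty(cohort, n_boot=10, seed=3, n_lambda=15)
        assert np.array_equal(a.mean_boot_mse, b.mean_boot_mse)

    def test_n_boot_must_be_positive(self, cohort):
        with pytest.raises(ValueError):
            lv.tune_penalty(cohort, n_boot=0, seed=0)


class TestPooling:
    def test_hand_pooled_coefficients(self):
        mk = lambda c: lv.LassoModel(0.0, np.array(c, float), 0.1, np.zeros(2), np.ones(2))
        pooled = pool_models([mk([1, 0]), mk([0, 1]), mk([1, 1])])
        assert np.allclose(pooled.coefficients, [2 / 3, 2 / 3])
        assert np.array_equal(pooled.selection_counts, [2, 2])

    def test_single_selection_divided_by_m(self):
        models = [lv.LassoModel(0.0, np.array([0.5 if i == 0 else 0.0]), 0.1,
                                np.zeros(1), np.ones(1)) for i in range(10)]
        pooled = pool_models(models)
        assert pooled.coefficients[0] == pytest.approx(0.05)
        assert pooled.selection_counts[0] == 1

    @given(c=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pooling_commutes_with_scaling(self, c):
        rng = np.random.default_rng(7)
        models = [lv.LassoModel(0.0, rng.standard_normal(4), 0.1, np.zeros(4), np.ones(4))
                  for _ in range(3)]
        scaled = [lv.LassoModel(m.intercept, m.coefficients * c, m.penalty, m.center, m.scale)
                  for m in models]
        assert np.allclose(pool_models(scaled).coefficients,
                           c * pool_models(models).coefficients)

    def test_identical_sets_pool_to_single_fit(self, cohort):
        sets = lv.ImputedSets([cohort, cohort, cohort], cohort.mask.copy())
        pooled = lv.fit_pooled(sets, "best", n_lambda=10, n_boot=10, seed=11)
        single = lv.fit_pooled(cohort, "best", n_lambda=10, n_boot=10, seed=11)
        assert np.allclose(pooled.coefficients, single.coefficients)

    def test_modes_share_one_tuning_pass(self, imputed_small):
        both = lv.fit_pooled(imputed_small, ("best", "tolerance"),
                             n_lambda=12, n_boot=10, seed=13)
        solo = lv.fit_pooled(imputed_small, "tolerance", n_lambda=12, n_boot=10, seed=13)
        assert np.allclose(both["tolerance"].coefficients, solo.coefficients)
        # tolerance penalty is never weaker than the best penalty
        for t in both["best"].tunings:
            assert t.tolerance_lambda >= t.best_lambda
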