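"""Regression core: design validation, residualization, batched fits, p-values."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from ecpg import (CovariateTable, ModelError, batched_mlr, gaussian_two_sided_p,
                  pearson_block, residualize, validate_design)
from ecpg.regress import T_SATURATION

from conftest import make_covariates


def ols_oracle(y, X, m_row):
    """Independent per-pair fit of y on [1 | X | m]; returns (est, se, t).

    Uses lstsq plus the classical covariance formula, sharing no code
    with the batched path.
    """
    n = len(y)
    design = np.column_stack([np.ones(n), X, m_row])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - design.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return beta[-1], np.sqrt(cov[-1, -1]), beta[-1] / np.sqrt(cov[-1, -1])


class TestValidateDesign:
    def test_intercept_only(self, rng):
        d = validate_design(make_covariates(rng, 10, 0))
        assert d.base.shape == (10, 1)
        assert d.rank == 1
        np.testing.assert_array_equal(d.base[:, 0], 1.0)

    def test_collinear_covariate_named(self, rng):
        cov = make_covariates(rng, 12, 2)
        values = cov.values.copy()
        values[:, 1] = 2.0 * values[:, 0]
        bad = CovariateTable(cov.sample_ids, cov.covariate_names, values)
        with pytest.raises(ModelError, match="collinear"):
            validate_design(bad)

    def test_nonpositive_df_rejected(self, rng):
        with pytest.raises(ModelError, match="df"):
            validate_design(make_covariates(rng, 4, 3))


class TestResidualize:
    def test_orthogonal_row_unchanged(self, rng):
        d = validate_design(make_covariates(rng, 8, 0))
        row = rng.standard_normal((1, 8))
        row -= row.mean()
        np.testing.assert_allclose(residualize(row, d), row, atol=1e-12)

    def test_design_combination_goes_to_zero(self, rng):
        cov = make_covariates(rng, 8, 2)
        d = validate_design(cov)
        row = (3.0 + 2.0 * cov.values[:, 0] - cov.values[:, 1])[None, :]
        np.testing.assert_allclose(residualize(row, d), 0.0, atol=1e-12)

    def test_matches_per_row_least_squares(self, rng):
        cov = make_covariates(rng, 8, 2)
        d = validate_design(cov)
        y = rng.standard_normal((6, 8))
        res = residualize(y, d)
        # residuals orthogonal to every design column
        np.testing.assert_allclose(res @ d.base, 0.0, atol=1e-10)
        for i in range(6):
            beta, _, _, _ = np.linalg.lstsq(d.base, y[i], rcond=None)
            expected = y[i] - d.base @ beta
            np.testing.assert_allclose(res[i], expected, rtol=1e-10, atol=1e-12)


class TestBatchedMlr:
    def test_noiseless_fit_is_exact(self, rng):
        n = 20
        cov = make_covariates(rng, n, 0)
        d = validate_design(cov)
        m = rng.random((1, n))
        y = 2.0 * m + 3.0
        blk = batched_mlr(y, m, d, ["g"], ["cg"])
        np.testing.assert_allclose(blk.est[0, 0], 2.0, rtol=1e-9)
        assert blk.p[0, 0] < 1e-12

    def test_matches_full_model_ols(self, rng):
        """FWL shortcut == per-pair full-design OLS (statsmodels cross-check)."""
        n, m, G, C = 50, 3, 20, 30
        cov = make_covariates(rng, n, m)
        d = validate_design(cov)
        Y = rng.standard_normal((G, n))
        M = rng.random((C, n))
        blk = batched_mlr(Y, M, d, [f"g{i}" for i in range(G)],
                          [f"cg{j}" for j in range(C)])
        assert blk.df == n - m - 2
        for k in range(G):
            for j in range(C):
                est, se, t = ols_oracle(Y[k], cov.values, M[j])
                np.testing.assert_allclose(blk.est[k, j], est, rtol=1e-8)
                np.testing.assert_allclose(blk.se[k, j], se, rtol=1e-8)
                np.testing.assert_allclose(blk.t[k, j], t, rtol=1e-8)
        # spot-check a few pairs against statsmodels as a second opinion
        for k, j in [(0, 0), (5, 7), (19, 29)]:
            fit = sm.OLS(Y[k], np.column_stack([np.ones(n), cov.values, M[j]])).fit()
            np.testing.assert_allclose(blk.est[k, j], fit.params[-1], rtol=1e-10)
            np.testing.assert_allclose(blk.se[k, j], fit.bse[-1], rtol=1e-10)

    def test_covariate_statistics_match_full_model(self, rng):
        n, m = 40, 2
        cov = make_covariates(rng, n, m)
        d = validate_design(cov)
        Y = rng.standard_normal((3, n))
        M = rng.random((4, n))
        blk = batched_mlr(Y, M, d, list("abc"), list("wxyz"),
                          with_covariate_stats=True)
        names = ["intercept"] + [f"cov_{c}" for c in cov.covariate_names]
        for k in range(3):
            for j in range(4):
                fit = sm.OLS(Y[k], np.column_stack([np.ones(n), cov.values,
                                                    M[j]])).fit()
                for idx, nm in enumerate(names):
                    np.testing.assert_allclose(blk.extra[f"{nm}_est"][k, j],
                                               fit.params[idx], rtol=1e-8)
                    np.testing.assert_allclose(blk.extra[f"{nm}_se"][k, j],
                                               fit.bse[idx], rtol=1e-8)

    def test_constant_methylation_row_is_sentinel(self, rng):
        n = 25
        d = validate_design(make_covariates(rng, n, 1))
        M = rng.random((3, n))
        M[1] = 0.42  # constant Beta
        Y = rng.standard_normal((4, n))
        blk = batched_mlr(Y, M, d, list("abcd"), list("xyz"))
        assert np.isnan(blk.est[:, 1]).all()
        assert np.isnan(blk.p[:, 1]).all()
        assert np.isfinite(blk.est[:, [0, 2]]).all()
        assert np.isfinite(blk.p[:, [0, 2]]).all()

    def test_covariate_rescaling_invariance(self, rng):
        n, m = 60, 3
        cov = make_covariates(rng, n, m)
        Y = rng.standard_normal((2, n))
        M = rng.random((2, n))
        d1 = validate_design(cov)
        scaled = cov.values.copy()
        scaled[:, 0] = 7.0 * scaled[:, 0] - 3.0  # affine rescale
        d2 = validate_design(CovariateTable(cov.sample_ids,
                                            cov.covariate_names, scaled))
        b1 = batched_mlr(Y, M, d1, list("ab"), list("xy"))
        b2 = batched_mlr(Y, M, d2, list("ab"), list("xy"))
        np.testing.assert_allclose(b1.est, b2.est, rtol=1e-10)
        np.testing.assert_allclose(b1.t, b2.t, rtol=1e-10)

    def test_scale_equivariance(self, rng):
        n = 40
        d = validate_design(make_covariates(rng, n, 0))
        Y = rng.standard_normal((2, n))
        M = rng.random((2, n))
        base = batched_mlr(Y, M, d, list("ab"), list("xy"))
        # est scales inversely with M; t and p invariant under joint rescale
        half = batched_mlr(Y, 2.0 * M, d, list("ab"), list("xy"))
        np.testing.assert_allclose(half.est, base.est / 2.0, rtol=1e-10)
        joint = batched_mlr(5.0 * Y, 2.0 * M, d, list("ab"), list("xy"))
        np.testing.assert_allclose(joint.t, base.t, rtol=1e-10)
        np.testing.assert_allclose(joint.p, base.p, rtol=1e-10)

    def test_float32_path_agrees_within_tolerance(self, rng):
        """Single precision (the accelerator contract) tracks double to 1e-4."""
        n, m = 100, 2
        cov = make_covariates(rng, n, m)
        d = validate_design(cov)
        Y = rng.standard_normal((10, n))
        M = rng.random((15, n))
        b64 = batched_mlr(Y, M, d, [str(i) for i in range(10)],
                          [str(j) for j in range(15)])
        b32 = batched_mlr(Y, M, d, [str(i) for i in range(10)],
                          [str(j) for j in range(15)], dtype=np.float32)
        np.testing.assert_allclose(b32.est, b64.est, rtol=1e-4)


class TestPearson:
    def test_perfect_correlation_saturates(self, rng):
        n = 12
        m = rng.random((1, n))
        for sign in (1.0, -1.0):
            blk = pearson_block(sign * m, m, ["g"], ["cg"])
            np.testing.assert_allclose(blk.est[0, 0], sign, atol=1e-12)
            assert blk.t[0, 0] == sign * T_SATURATION
            assert blk.p[0, 0] == 0.0

    def test_r_matches_covariance_formula(self, rng):
        n = 30
        Y = rng.standard_normal((5, n))
        M = rng.random((6, n))
        blk = pearson_block(Y, M, [str(i) for i in range(5)],
                            [str(j) for j in range(6)])
        for k in range(5):
            for j in range(6):
                yc, mc = Y[k] - Y[k].mean(), M[j] - M[j].mean()
                r = (yc @ mc) / np.sqrt((yc @ yc) * (mc @ mc))
                np.testing.assert_allclose(blk.est[k, j], r, rtol=1e-12)

    def test_t_equals_simple_regression_t(self, rng):
        """With no covariates, the correlation t and the regression t coincide."""
        n = 45
        d = validate_design(make_covariates(rng, n, 0))
        Y = rng.standard_normal((3, n))
        M = rng.random((3, n))
        mlr = batched_mlr(Y, M, d, list("abc"), list("xyz"))
        cor = pearson_block(Y, M, list("abc"), list("xyz"))
        np.testing.assert_allclose(cor.t, mlr.t, rtol=1e-10)

    def test_zero_variance_rows_flagged(self, rng):
        n = 10
        Y = rng.standard_normal((2, n))
        Y[0] = 3.0
        M = rng.random((2, n))
        blk = pearson_block(Y, M, list("ab"), list("xy"))
        assert np.isnan(blk.p[0]).all()
        assert np.isfinite(blk.p[1]).all()


class TestGaussianP:
    def test_reference_values(self):
        assert gaussian_two_sided_p(0.0) == 1.0
        assert abs(gaussian_two_sided_p(1.959963985) - 0.05) < 1e-6
        # matches the standard-normal survival function across the range
        for t in (0.5, 2.0, 8.0, 20.0):
            np.testing.assert_allclose(gaussian_two_sided_p(t),
                                       2.0 * stats.norm.sf(t), rtol=1e-12)

    def test_far_tail_has_no_catastrophic_behavior(self):
        p = gaussian_two_sided_p(40.0)
        assert 0.0 < p < 1e-300
        assert not np.isnan(gaussian_two_sided_p(400.0))
        assert np.isnan(gaussian_two_sided_p(np.inf))
        assert np.isnan(gaussian_two_sided_p(np.nan))

    def test_strictly_decreasing_in_abs_t(self):
        grid = np.linspace(0.0, 35.0, 2000)
        p = np.asarray(gaussian_two_sided_p(grid))
        assert (np.diff(p) < 0).all()
        assert (p >= 0).all() and (p <= 1).all()
        # symmetric in the sign of t
        np.testing.assert_array_equal(np.asarray(gaussian_two_sided_p(-grid)), p)

    def test_converges_to_student_t(self):
        grid = np.linspace(-5.0, 5.0, 501)
        gauss = np.asarray(gaussian_two_sided_p(grid))
        for df, bound, should_exceed in [(996, 1e-3, False), (6, 1e-2, True)]:
            t_p = 2.0 * stats.t.sf(np.abs(grid), df)
            gap = np.max(np.abs(gauss - t_p))
            if should_exceed:
                assert gap > bound
            else:
                assert gap <= bound
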