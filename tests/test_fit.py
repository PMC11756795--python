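"""Full EM fits: OLS agreement, null model, ascent, KKT, Gaussian limit,
offset equivalence, and cross-validated lambda selection."""

import warnings

import numpy as np
import pytest

from transptlr import (
    Dataset,
    EMConfig,
    cv_select_lambda,
    default_lambda_grid,
    fit_ptlr,
    lambda_max,
)
from transptlr.gaussian import fit_pnlr


class TestFitPtlr:
    def test_unpenalized_matches_ols_on_gaussian_data(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((200, 5))
        beta = np.array([1.0, -2.0, 0.0, 0.5, 3.0])
        y = X @ beta + rng.standard_normal(200)
        fit = fit_ptlr(Dataset(X, y), 0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(fit.beta - ols)) < 0.05

    def test_lambda_max_gives_null_model(self, medium_t_data):
        d, _ = medium_t_data
        fit = fit_ptlr(d, lambda_max(d) * 1.05)
        np.testing.assert_array_equal(fit.beta, 0.0)
        # null-model scale tracks the marginal spread of y
        assert fit.sigma2 == pytest.approx(np.mean(d.y**2), rel=0.5)

    def test_offset_shifts_the_model(self, medium_t_data):
        d, _ = medium_t_data
        rng = np.random.default_rng(0)
        off = rng.standard_normal(d.n)
        shifted = Dataset(d.X, d.y + off)
        f_off = fit_ptlr(shifted, 3.0, offset=off)
        f_ref = fit_ptlr(d, 3.0)
        np.testing.assert_allclose(f_off.beta, f_ref.beta, atol=1e-8)

    def test_fix_support_freezes_excluded_coefficients(self, medium_t_data):
        d, _ = medium_t_data
        mask = np.zeros(d.p, dtype=bool)
        mask[:3] = True
        fit = fit_ptlr(d, 1.0, fix_support=mask)
        np.testing.assert_array_equal(fit.beta[3:], 0.0)
        assert np.any(fit.beta[:3] != 0)

    def test_em_ascent_with_fixed_nuisance(self, medium_t_data):
        # with (sigma2, nu) held fixed the loop is exact EM on the penalized
        # observed objective, which must be monotone
        d, _ = medium_t_data
        cfg = EMConfig(estimate_scale=False, estimate_nu=False, cd_passes=1)
        warm = fit_ptlr(d, 5.0, EMConfig())
        from transptlr.ptlr import TModelFit

        start = TModelFit(beta=np.zeros(d.p), sigma2=2.0, nu=5.0, lam=5.0,
                          loglik=0.0, penalized_obj=0.0, n_iter=0,
                          converged=True)
        fit = fit_ptlr(d, 5.0, cfg, warm=start)
        tr = fit.obj_trace
        assert tr is not None and len(tr) >= 2
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_unpenalized_ascent_full_updates(self, medium_t_data):
        # at lambda = 0 every update is an exact (EC)M(E) step on the observed
        # log-likelihood, so the trace must ascend
        d, _ = medium_t_data
        fit = fit_ptlr(d, 0.0, EMConfig(cd_passes=1))
        tr = fit.obj_trace
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_kkt_certificate_at_solution(self, medium_t_data):
        from transptlr import _engine
        from transptlr.ptlr import _e_step_resid

        d, _ = medium_t_data
        for lam in [0.5, 3.0, 10.0]:
            fit = fit_ptlr(d, lam)
            r = d.y - d.X @ fit.beta
            w = _e_step_resid(r, fit.sigma2, fit.nu).tau_hat
            viol = _engine._kkt_max_violation(
                np.asfortranarray(d.X), r, w, fit.beta, lam,
                np.ones(d.p), np.ones(d.p, dtype=np.bool_))
            scale = max(1.0, lam)
            assert viol <= 1e-6 * scale

    def test_gaussian_limit_agrees_with_pnlr(self, medium_t_data):
        d, _ = medium_t_data
        cfg = EMConfig(estimate_nu=False, nu_bounds=(1.0, 1e7))
        from transptlr.ptlr import TModelFit

        warm = TModelFit(beta=np.zeros(d.p), sigma2=float(np.mean(d.y**2)),
                         nu=1e6, lam=2.0, loglik=0.0, penalized_obj=0.0,
                         n_iter=0, converged=True)
        ft = fit_ptlr(d, 2.0, cfg, warm=warm)
        fg = fit_pnlr(d, 2.0)
        assert np.max(np.abs(ft.beta - fg.beta)) < 1e-4

    def test_parameter_recovery_t5(self):
        rng = np.random.default_rng(77)
        X = rng.standard_normal((1000, 20))
        beta = np.zeros(20)
        beta[:5] = 0.5
        y = X @ beta + rng.standard_t(5, 1000)
        fit = fit_ptlr(Dataset(X, y), 0.0)
        assert np.max(np.abs(fit.beta - beta)) < 0.1
        assert abs(fit.sigma2 - 1.0) < 0.2
        assert 3.5 <= fit.nu <= 7.5

    def test_nonconvergence_warns(self, medium_t_data):
        d, _ = medium_t_data
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_ptlr(d, 1.0, EMConfig(max_iter=2))
        assert not fit.converged

    def test_standardize_intercept_roundtrip(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 4)) * np.array([1.0, 10.0, 0.1, 2.0]) + 3.0
        beta = np.array([1.0, 0.2, 0.0, -0.5])
        y = 2.0 + X @ beta + 0.3 * rng.standard_normal(120)
        cfg = EMConfig(standardize=True, fit_intercept=True)
        fit = fit_ptlr(Dataset(X, y), 0.5, cfg)
        pred = fit.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.98
        assert abs(fit.intercept) > 0.1  # intercept actually estimated


class TestCVSelectLambda:
    def test_single_value_grid(self, medium_t_data):
        d, _ = medium_t_data
        cfg = EMConfig(lambda_grid=np.array([2.5]))
        lam, fit, table = cv_select_lambda(d, cfg)
        assert lam == 2.5 and len(table) == 1

    def test_duplicate_grid_idempotent(self, medium_t_data):
        d, _ = medium_t_data
        a = cv_select_lambda(d, EMConfig(lambda_grid=np.array([1.0, 4.0])))
        b = cv_select_lambda(d, EMConfig(lambda_grid=np.array([4.0, 1.0, 4.0])))
        assert a[0] == b[0]
        np.testing.assert_allclose(a[1].beta, b[1].beta)

    def test_strong_signal_rejects_null_model(self, fast_em):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 30))
        beta = np.zeros(30)
        beta[:3] = 2.0
        y = X @ beta + 0.5 * rng.standard_normal(100)
        d = Dataset(X, y)
        lam, fit, _ = cv_select_lambda(d, fast_em)
        assert lam < lambda_max(d)
        assert (fit.beta != 0).any()

    def test_grid_is_descending_from_lambda_max(self, medium_t_data):
        d, _ = medium_t_data
        grid = default_lambda_grid(d, EMConfig(n_lambda=10, lambda_min_ratio=0.1))
        assert grid[0] == pytest.approx(lambda_max(d))
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] == pytest.approx(0.1 * lambda_max(d))

    def test_tiny_folds_error(self):
        d = Dataset(np.random.default_rng(0).standard_normal((5, 2)),
                    np.random.default_rng(1).standard_normal(5))
        with pytest.raises(ValueError, match="folds"):
            cv_select_lambda(d, EMConfig(cv_folds=5))

    def test_seeded_folds_reproducible(self, small_data, fast_em):
        d, _ = small_data
        r1 = cv_select_lambda(d, fast_em)
        r2 = cv_select_lambda(d, fast_em)
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[1].beta, r2[1].beta)
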