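"""Lag basis, penalized fitting, effective df, effects and the refit rule."""

import numpy as np
import pytest

import leadlag as ll
from leadlag.dlm import (DLMFit, LagBasis, ModelSpec, build_lag_basis,
                         fit_penalized_dlm, fit_with_refit_rule, lag_effects)


def iid_design(n, L, seed=0, med=0.5, sd=0.6):
    rng = np.random.default_rng(seed)
    return rng.lognormal(np.log(med), sd, size=(n, L)), rng


class TestLagBasis:
    def test_every_lag_cr_basis_is_identity_with_rank_deficient_penalty(self):
        b = build_lag_basis(144, "every-lag")
        np.testing.assert_allclose(b.basis_matrix, np.eye(144))
        eig = np.linalg.eigvalsh(b.penalty_matrix)
        assert np.sum(eig > eig[-1] * 1e-10) == 142  # curvature penalty: rank K-2

    @pytest.mark.parametrize("dialect", ["cr", "ps"])
    def test_straight_line_has_zero_curvature_penalty(self, dialect):
        b = build_lag_basis(60, "every-lag", dialect=dialect)
        # coefficient vector representing the line f(j) = 2 + 0.1 j
        if dialect == "cr":
            theta = 2.0 + 0.1 * b.knots
        else:
            theta, *_ = np.linalg.lstsq(b.basis_matrix,
                                        2.0 + 0.1 * np.arange(1, 61), rcond=None)
        q = theta @ b.penalty_matrix @ theta
        scale = np.abs(b.penalty_matrix).max() * theta @ theta
        assert abs(q) < 1e-8 * scale

    def test_equally_spaced_knot_positions(self):
        b = build_lag_basis(144, "equally-spaced", max_knots=20)
        np.testing.assert_allclose(b.knots, np.linspace(1, 144, 20))
        assert b.basis_matrix.shape == (144, 20)

    def test_basis_columns_linearly_independent(self):
        b = build_lag_basis(144, "equally-spaced", max_knots=20)
        assert np.linalg.matrix_rank(b.basis_matrix) == 20

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            build_lag_basis(3)

    def test_cr_and_ps_dialects_agree_on_a_smooth_truth(self):
        X, rng = iid_design(400, 48, seed=5)
        j = np.arange(1, 49)
        beta = np.exp(-0.5 * ((j - 20) / 6.0) ** 2)
        y = 5 + X @ beta + 0.5 * rng.standard_normal(400)
        curves = {}
        for d in ("cr", "ps"):
            spec = ModelSpec(n_lags=48, dialect=d, adjusted=False)
            curves[d] = lag_effects(fit_penalized_dlm(X, y, spec=spec)).beta
        assert np.max(np.abs(curves["cr"] - curves["ps"])) < 0.1
        assert np.corrcoef(curves["cr"], curves["ps"])[0, 1] > 0.99


class TestPenalizedFit:
    def test_zero_lambda_equals_ols_on_transformed_design(self):
        X, rng = iid_design(200, 144, seed=3)
        basis = build_lag_basis(144, "equally-spaced", max_knots=10)
        theta_true = rng.normal(0, 0.5, 10)
        y = 50 + X @ (basis.basis_matrix @ theta_true) + rng.standard_normal(200)
        spec = ModelSpec(n_lags=144, basis_kind="equally-spaced", max_knots=10,
                         lam=0.0, adjusted=False)
        fit = fit_penalized_dlm(X, y, spec=spec)
        Z = np.column_stack([np.ones(200), X @ basis.basis_matrix])
        b_ols = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(fit.theta, b_ols[1:], rtol=1e-8)

    def test_huge_lambda_gives_affine_curve_and_edf_two(self):
        X, rng = iid_design(200, 144, seed=4)
        y = 50 + 0.5 * X.sum(axis=1) + rng.standard_normal(200)
        fit = fit_penalized_dlm(X, y, spec=ModelSpec(lam=1e12, adjusted=False))
        beta = lag_effects(fit).beta
        assert np.abs(np.diff(beta, 2)).max() < 1e-6
        assert fit.edf == pytest.approx(2.0, abs=0.05)

    def test_noiseless_representable_curve_recovered_exactly(self, bump_cohort,
                                                             bump_curve):
        """A spline-space truth with no noise is interpolated to ~machine
        precision at small lambda."""
        X = bump_cohort.exposure.values
        y = 10.0 + X @ bump_curve.values
        fit = fit_penalized_dlm(X, y, spec=ModelSpec(lam=1e-6, adjusted=False))
        beta = lag_effects(fit).beta
        assert np.abs(beta - bump_curve.values).max() < 1e-6

    def test_edf_nonincreasing_in_lambda(self):
        X, rng = iid_design(150, 36, seed=6)
        y = 3 + X @ np.linspace(0.5, 0, 36) + rng.standard_normal(150)
        grid = np.logspace(-4, 10, 20)
        edfs = [fit_penalized_dlm(X, y, spec=ModelSpec(n_lags=36, lam=l,
                                                       adjusted=False)).edf
                for l in grid]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))
        edf0 = fit_penalized_dlm(X, y, spec=ModelSpec(n_lags=36, lam=0.0,
                                                      adjusted=False)).edf
        assert edf0 == pytest.approx(36, abs=1e-6)  # unpenalized trace = K

    def test_collinear_covariates_named_in_error(self):
        X, rng = iid_design(100, 24, seed=7)
        import pandas as pd
        cov = pd.DataFrame({"a": rng.normal(size=100)})
        cov["b"] = 2 * cov["a"]
        y = rng.normal(size=100)
        spec = ModelSpec(n_lags=24, covariate_names=("a", "b"))
        with pytest.raises(ValueError, match="b"):
            fit_penalized_dlm(X, y, cov, spec=spec)

    def test_complete_case_exclusions_are_ledgered(self):
        X, rng = iid_design(50, 24, seed=8)
        X[3, 10] = np.nan
        y = rng.normal(50, 1, size=50)
        y[7] = np.nan
        fit = fit_penalized_dlm(X, y, spec=ModelSpec(n_lags=24, adjusted=False))
        assert fit.n_used == 48
        assert fit.exclusions["missing monthly exposure"] == ["3"]
        assert fit.exclusions["missing outcome"] == ["7"]

    def test_reml_matches_mgcv_parapen_fit(self):
        """Frozen external oracle: the same design and curvature penalty
        fitted by mgcv's REML (gam with paraPen) gives lambda 117.1938,
        edf 5.46496, beta_5 0.2916923, se_5 0.1305583."""
        rng = np.random.default_rng(2024)
        n, L = 120, 24
        X = rng.lognormal(np.log(0.5), 0.5, size=(n, L))
        j = np.arange(1, L + 1)
        beta = 0.8 * np.exp(-0.5 * ((j - 10) / 4.0) ** 2)
        y = 10 + X @ beta + rng.standard_normal(n)
        fit = fit_penalized_dlm(X, y, spec=ModelSpec(n_lags=L, adjusted=False))
        cur = lag_effects(fit)
        assert fit.lam == pytest.approx(117.1938263, rel=1e-4)
        assert fit.edf == pytest.approx(5.46495584, abs=1e-4)
        assert cur.beta[4] == pytest.approx(0.29169234, abs=1e-5)
        assert cur.se[4] == pytest.approx(0.13055831, abs=1e-5)


class TestLagEffects:
    def test_zero_theta_gives_zero_curve_with_symmetric_cis(self, bump_cohort):
        basis = build_lag_basis(144, "equally-spaced", max_knots=10)
        K = 10
        V = np.zeros((K + 1, K + 1))
        V[1:, 1:] = 0.04 * np.eye(K)
        fit = DLMFit(intercept=0.0, theta=np.zeros(K), gamma={}, lam=1.0,
                     edf=2.0, edf_total=3.0, coef_covariance=V,
                     residual_sd=1.0, n_used=100, exclusions={}, basis=basis,
                     spec=ModelSpec())
        cur = lag_effects(fit)
        np.testing.assert_allclose(cur.beta, 0.0)
        np.testing.assert_allclose(cur.ci_low, -cur.ci_high)

    def test_constant_basis_propagates_theta_variance(self):
        basis = LagBasis(basis_matrix=np.ones((6, 1)),
                         penalty_matrix=np.zeros((1, 1)),
                         knots=np.array([1.0]), kind="constant", dialect="cr")
        v = 0.49
        V = np.diag([0.0, v])
        fit = DLMFit(intercept=0.0, theta=np.array([1.5]), gamma={}, lam=0.0,
                     edf=1.0, edf_total=2.0, coef_covariance=V,
                     residual_sd=1.0, n_used=50, exclusions={}, basis=basis,
                     spec=ModelSpec())
        cur = lag_effects(fit)
        np.testing.assert_allclose(cur.se, np.sqrt(v))
        np.testing.assert_allclose(cur.beta, 1.5)

    def test_se_matches_parametric_bootstrap(self):
        X, rng = iid_design(150, 24, seed=9)
        y = 5 + X @ np.linspace(0.4, 0, 24) + rng.standard_normal(150)
        fit = fit_penalized_dlm(X, y, spec=ModelSpec(n_lags=24, adjusted=False))
        cur = lag_effects(fit)
        draws = rng.multivariate_normal(fit.theta, fit.theta_covariance,
                                        size=10_000)
        boot = draws @ fit.basis.basis_matrix.T
        boot_se = boot.std(axis=0)
        np.testing.assert_allclose(cur.se, boot_se, rtol=0.05)
        np.testing.assert_allclose(cur.beta, fit.basis.basis_matrix @ fit.theta)

    def test_invalid_level_rejected(self, bump_cohort_fit):
        with pytest.raises(ValueError, match="level"):
            lag_effects(bump_cohort_fit, level=1.0)


class TestRefitRule:
    def test_high_frequency_truth_triggers_twenty_knot_refit(self):
        X, rng = iid_design(500, 144, seed=10)
        wig = ll.TrueLagCurve.wiggle(144, amplitude=1.0, period=6.0)
        y = 50 + X @ wig.values + 0.1 * rng.standard_normal(500)
        fit = fit_with_refit_rule(X, y, spec=ModelSpec(adjusted=False))
        assert fit.refit
        assert fit.basis.n_coef <= 20
        assert fit.edf <= 20 + 0.1

    def test_smooth_truth_keeps_every_lag_fit(self, bump_cohort_fit):
        assert not bump_cohort_fit.refit
        assert bump_cohort_fit.edf <= 20

    def test_covariate_orthogonal_noise_barely_moves_curve(self, bump_cohort):
        """A covariate independent of exposure and outcome leaves the lag
        curve essentially unchanged."""
        import pandas as pd
        X = bump_cohort.exposure.values
        y = bump_cohort.outcomes["score"].values
        rng = np.random.default_rng(1)
        junk = pd.DataFrame({"junk": rng.standard_normal(len(y))})
        base = lag_effects(fit_penalized_dlm(X, y, spec=ModelSpec(adjusted=False)))
        plus = lag_effects(fit_penalized_dlm(
            X, y, junk, spec=ModelSpec(covariate_names=("junk",))))
        assert np.max(np.abs(base.beta - plus.beta)) < 0.05
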