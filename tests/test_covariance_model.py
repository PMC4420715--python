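import numpy as np
import pytest

from pacfcov.covariance_model import (
    ConstraintViolation,
    CovarianceParams,
    build_subject_covariance,
    build_thin_plate_basis,
    default_knots,
    evaluate_pacf,
    evaluate_variance,
)
from pacfcov.pacf_core import banded_precision, corr_to_pacf


@pytest.fixture(scope="module")
def paper_basis():
    # 10 equally spaced knots at t = 5, 10, ..., 50 with time scaled by 50
    return build_thin_plate_basis(56, np.arange(5, 51, 5), 50.0)


class TestThinPlateBasis:
    def test_dimensions(self, paper_basis):
        assert paper_basis.fixed_design.shape == (56, 2)
        assert paper_basis.random_design.shape == (56, 10)
        assert paper_basis.penalty.shape == (10, 10)

    def test_penalty_diagonal_zero(self, paper_basis):
        np.testing.assert_array_equal(np.diag(paper_basis.penalty), 0.0)
        np.testing.assert_allclose(paper_basis.penalty, paper_basis.penalty.T)

    def test_reparameterization_reproduces_smoother(self, paper_basis):
        # Z Z' must equal T2 Omega~^-1 T2' where Omega~ is the positive
        # symmetrization of the (indefinite) cubic radial penalty; the oracle
        # goes through an SVD, independent of the eigh-based implementation
        T2 = paper_basis.raw_radial
        U, s, _ = np.linalg.svd(paper_basis.penalty)
        target = T2 @ (U / s) @ U.T @ T2.T
        Z = paper_basis.random_design
        np.testing.assert_allclose(Z @ Z.T, target, atol=1e-8 * np.abs(target).max())
        # and the smoother is positive semidefinite, as a covariance must be
        assert np.linalg.eigvalsh(Z @ Z.T)[0] > -1e-8

    def test_nonincreasing_knots_error(self):
        with pytest.raises(ValueError, match="increasing"):
            build_thin_plate_basis(20, [5, 5, 10], 20.0)

    def test_knots_out_of_range(self):
        with pytest.raises(ValueError):
            build_thin_plate_basis(20, [5, 25], 20.0)

    def test_default_knots_interior(self):
        k = default_knots(56, 10)
        assert len(k) == 10
        assert k[0] > 0 and k[-1] <= 56


class TestEvaluatePacf:
    def test_beyond_band_zero(self):
        params = CovarianceParams(
            family="stationary", a=2, gamma0=[1.0], gamma1=[-0.2], alpha=[0, 0]
        )
        p = evaluate_pacf(params, None, 10)
        assert p.pi(1, 5) == 0.0

    def test_zero_coefficients(self):
        params = CovarianceParams(
            family="stationary", a=3, gamma0=[0.0], gamma1=[0.0], alpha=[0, 0]
        )
        p = evaluate_pacf(params, None, 8)
        np.testing.assert_array_equal(p.table, 0.0)

    def test_lag1_value(self):
        # z = 1 - 0.5*1 = 0.5 -> pi = tanh(0.5)
        params = CovarianceParams(
            family="stationary", a=2, gamma0=[1.0], gamma1=[-0.5], alpha=[0, 0]
        )
        p = evaluate_pacf(params, None, 6)
        assert p.pi(1, 1) == pytest.approx(0.4621171572600098, abs=1e-12)

    def test_stationary_positive_slope_rejected(self):
        with pytest.raises(ConstraintViolation):
            CovarianceParams(
                family="stationary", a=2, gamma0=[1.0], gamma1=[0.1], alpha=[0, 0]
            )

    def test_nonstationary_constraint_violation(self):
        basis = build_thin_plate_basis(12, default_knots(12, 3), 10.0)
        params = CovarianceParams(
            family="nonstationary",
            a=2,
            gamma0=np.zeros(5),
            gamma1=np.concatenate([[0.2, 0.0], np.zeros(3)]),  # g1 > 0
            alpha=[0, 0],
        )
        with pytest.raises(ConstraintViolation):
            evaluate_pacf(params, basis, 12)

    def test_reduces_to_stationary(self):
        T = 12
        basis = build_thin_plate_basis(T, default_knots(T, 3), 10.0)
        ns = CovarianceParams(
            family="nonstationary",
            a=2,
            gamma0=np.concatenate([[0.8, 0.0], np.zeros(3)]),
            gamma1=np.concatenate([[-0.3, 0.0], np.zeros(3)]),
            alpha=[0, 0],
        )
        st = CovarianceParams(
            family="stationary", a=2, gamma0=[0.8], gamma1=[-0.3], alpha=[0, 0]
        )
        np.testing.assert_allclose(
            evaluate_pacf(ns, basis, T).table,
            evaluate_pacf(st, None, T).table,
            atol=1e-12,
        )

    def test_monotone_in_lag_within_band(self):
        T = 15
        basis = build_thin_plate_basis(T, default_knots(T, 4), 13.0)
        rng = np.random.default_rng(8)
        # keep g0 + g1*j nonnegative across the band so |pi| decay is monotone
        params = CovarianceParams(
            family="nonstationary",
            a=4,
            gamma0=np.concatenate([[1.6, -0.3], 0.02 * rng.standard_normal(4)]),
            gamma1=np.concatenate([[-0.1, 0.0], np.zeros(4)]),
            alpha=[0, 0],
        )
        p = evaluate_pacf(params, basis, T)
        for t in range(1, T - 4):
            vals = [abs(p.pi(t, j)) for j in range(1, 5)]
            assert np.all(np.diff(vals) <= 1e-12)


class TestQuadraticLag:
    def test_quadratic_term_applied(self):
        import numpy as _np

        params = CovarianceParams(
            family="stationary", a=3, gamma0=[1.0], gamma1=[-0.2], alpha=[0, 0],
            quadratic_lag=True, gamma2=[-0.05],
        )
        p = evaluate_pacf(params, None, 8)
        assert p.pi(1, 2) == pytest.approx(_np.tanh(1.0 - 0.4 - 0.2), abs=1e-12)

    def test_missing_gamma2_rejected(self):
        with pytest.raises(ValueError, match="gamma2"):
            CovarianceParams(
                family="stationary", a=2, gamma0=[1.0], gamma1=[-0.2], alpha=[0, 0],
                quadratic_lag=True,
            )


class TestEvaluateVariance:
    def test_zero_alpha_unit_variance(self):
        params = CovarianceParams(
            family="stationary", a=1, gamma0=[0], gamma1=[0], alpha=[0, 0], var_scale=56
        )
        np.testing.assert_array_equal(
            evaluate_variance(params, np.arange(1, 57)), 1.0
        )

    def test_negative_slope_decreasing(self):
        params = CovarianceParams(
            family="stationary", a=1, gamma0=[0], gamma1=[0], alpha=[1.0, -2.0],
            var_scale=56,
        )
        v = evaluate_variance(params, np.arange(1, 57))
        assert np.all(np.diff(v) < 0)

    def test_reported_scale_medians(self):
        # posterior-median alpha values used as inputs
        params = CovarianceParams(
            family="stationary", a=1, gamma0=[0], gamma1=[0],
            alpha=[4.65, -1.76], var_scale=56,
        )
        v1 = evaluate_variance(params, 1)
        v56 = evaluate_variance(params, 56)
        assert v1 > v56 > 0


class TestSubjectCovariance:
    def test_single_time_no_intercept(self):
        params = CovarianceParams(
            family="stationary", a=1, gamma0=[0.5], gamma1=[0], alpha=[1.0, -0.5],
            sigma_b=0.0, var_scale=10,
        )
        S = build_subject_covariance(params, None, [4], T=10)
        assert S.shape == (1, 1)
        assert S[0, 0] == pytest.approx(float(evaluate_variance(params, 4)))

    def test_random_intercept_offdiagonal(self):
        params = CovarianceParams(
            family="stationary", a=1, gamma0=[0.0], gamma1=[0.0], alpha=[0, 0],
            sigma_b=2.0, var_scale=10,
        )
        S = build_subject_covariance(params, None, [2, 7], T=10)
        np.testing.assert_allclose(S, [[5.0, 4.0], [4.0, 5.0]], atol=1e-12)

    def test_positive_definite_random_draws(self):
        rng = np.random.default_rng(21)
        T = 20
        for _ in range(100):
            params = CovarianceParams(
                family="stationary",
                a=2,
                gamma0=[rng.uniform(0, 2)],
                gamma1=[rng.uniform(-1, 0)],
                alpha=rng.uniform(-1, 1, 2),
                sigma_b=rng.uniform(0, 3),
                var_scale=T,
            )
            times = np.sort(rng.choice(np.arange(1, T + 1), size=8, replace=False))
            S = build_subject_covariance(params, None, times, T=T)
            assert np.linalg.eigvalsh(S)[0] > 0

    def test_serial_precision_banded_but_marginal_not(self):
        # banding holds for R^-1 only; sigma_b^2 J destroys it in Sigma^-1
        params = CovarianceParams(
            family="stationary", a=1, gamma0=[1.0], gamma1=[-0.2], alpha=[0, 0],
            sigma_b=2.0, var_scale=8,
        )
        pacf = evaluate_pacf(params, None, 8)
        P, _ = banded_precision(pacf)
        k, l = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        assert np.all(P[np.abs(k - l) > 1] == 0.0)
        S = build_subject_covariance(params, None, np.arange(1, 9), T=8)
        Pfull = np.linalg.inv(S)
        assert np.max(np.abs(Pfull[np.abs(k - l) > 1])) > 1e-6

    def test_roundtrip_through_corr(self):
        # generated partials recovered from the induced correlation matrix
        params = CovarianceParams(
            family="stationary", a=2, gamma0=[1.1], gamma1=[-0.4], alpha=[0, 0],
            var_scale=12,
        )
        pacf = evaluate_pacf(params, None, 12)
        from pacfcov.pacf_core import pacf_to_corr

        back = corr_to_pacf(pacf_to_corr(pacf), 2)
        np.testing.assert_allclose(back.table, pacf.table, atol=1e-10)
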