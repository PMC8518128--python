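import numpy as np
import pytest
from scipy import integrate

from spatmetrics import theory
from spatmetrics.theory import (
    GaussianLambda2,
    PowerLawTL,
    covariance_from_lambda2,
    gaussian_cov,
    gaussian_omega,
    gaussian_var,
    omega_from_lambda2,
    powerlaw_cov_1d,
    powerlaw_cov_2d,
    powerlaw_omega_1d,
    powerlaw_omega_2d,
    powerlaw_var,
    square_pair_distance_pdf,
    variance_from_lambda2,
    variance_from_lambda2_1d,
)

# median Gaussian second-order-intensity parameters across the census species
ALPHA, BETA = 2.30, 0.71


class TestSquareLinePicking:
    @pytest.mark.parametrize("side", [1.0, 2.5])
    def test_density_normalises_with_correct_moment(self, side):
        pdf = lambda r: float(square_pair_distance_pdf(r, side))
        norm, _ = integrate.quad(pdf, 0, side * np.sqrt(2), points=[side])
        m2, _ = integrate.quad(lambda r: r**2 * pdf(r), 0, side * np.sqrt(2), points=[side])
        assert norm == pytest.approx(1.0, abs=1e-9)
        assert m2 == pytest.approx(side**2 / 3.0, rel=1e-9)  # E|X1-X2|^2 = L^2/3


class TestCSRBranch:
    """alpha = 0 (equivalently a = b = 1) must give the Poisson forms exactly."""

    def test_gaussian_family(self):
        A = np.array([0.01, 1.0, 25.0])
        np.testing.assert_array_equal(gaussian_var(0.0, BETA, A), A)
        assert gaussian_cov(0.0, BETA, 4.0, 1.0) == 0.0
        np.testing.assert_array_equal(gaussian_omega(0.0, BETA, np.array([0.0, 2.0])), 1.0)

    def test_powerlaw_family(self):
        assert powerlaw_var(1.0, 1.0, 7.0) == 7.0
        assert powerlaw_omega_1d(1.0, 1.0, 0.5) == 1.0
        assert powerlaw_cov_1d(1.0, 1.0, 2.0, 1.0) == 0.0
        assert float(powerlaw_omega_2d(1.0, 1.0, 0.5)) == 1.0
        assert powerlaw_cov_2d(1.0, 1.0, 2.0, 1.0) == 0.0

    def test_csr_numeric_integral(self):
        """lambda2 = 1 integrates to sigma2 = A and C = 0 for any geometry."""
        one = lambda r: np.ones_like(r)
        assert variance_from_lambda2(one, 3.7) == pytest.approx(3.7, rel=1e-9)
        assert covariance_from_lambda2(one, 2.0, 0.5) == pytest.approx(0.0, abs=1e-12)


class TestGaussianClosedForms:
    def test_omega_at_zero(self):
        """Omega(0) = alpha + 1 for the Gaussian family."""
        assert gaussian_omega(ALPHA, BETA, 0.0) == pytest.approx(3.30)

    def test_omega_decays_to_one(self):
        assert gaussian_omega(ALPHA, BETA, 50.0) == pytest.approx(1.0)

    def test_variance_reference_value(self):
        # frozen from the quadrature reduction of the moment integral
        assert gaussian_var(ALPHA, BETA, 1.0) == pytest.approx(2.8487604790, rel=1e-9)
        assert gaussian_var(ALPHA, BETA, 1.0) == pytest.approx(2.85, abs=0.005)

    @pytest.mark.parametrize("A", [0.04, 0.5, 1.0, 4.0, 16.0])
    def test_variance_matches_numerical_oracle(self, A):
        model = GaussianLambda2(ALPHA, BETA)
        num = variance_from_lambda2(model.lambda2, A)
        assert float(model.variance(A)) == pytest.approx(num, rel=1e-8)

    @pytest.mark.parametrize("A", [0.25, 1.0, 4.0])
    @pytest.mark.parametrize("D", [0.0, 0.3, 1.0, 3.0])
    def test_covariance_matches_numerical_oracle(self, A, D):
        model = GaussianLambda2(ALPHA, BETA)
        num = covariance_from_lambda2(model.lambda2, A, D)
        assert float(model.covariance(A, D)) == pytest.approx(num, rel=1e-8, abs=1e-12)

    def test_mc_integration_agrees_with_quadrature(self):
        model = GaussianLambda2(ALPHA, BETA)
        q = covariance_from_lambda2(model.lambda2, 1.0, 0.5)
        mc = covariance_from_lambda2(model.lambda2, 1.0, 0.5, method="mc", seed=1)
        assert mc == pytest.approx(q, rel=0.02)

    def test_small_area_orderliness_limit(self):
        """sigma2/A -> 1 as A -> 0: at tiny scales counts are Bernoulli-like."""
        assert gaussian_var(ALPHA, BETA, 1e-8) / 1e-8 == pytest.approx(1.0, rel=1e-4)

    def test_covariance_monotone_in_gap(self):
        D = np.linspace(0, 5, 40)
        c = gaussian_cov(ALPHA, BETA, 1.0, D)
        assert np.all(np.diff(c) <= 1e-12)
        assert c[-1] == pytest.approx(0.0, abs=1e-6)

    def test_excess_variance_monotone_in_alpha(self):
        av = [gaussian_var(a, BETA, 2.0) - 2.0 for a in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(av) > 0)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            gaussian_var(-1.0, BETA, 1.0)
        with pytest.raises(ValueError):
            gaussian_var(ALPHA, 0.0, 1.0)
        with pytest.raises(ValueError):
            gaussian_cov(ALPHA, BETA, 1.0, -0.5)


class TestPowerLaw1D:
    def test_omega_pointwise_values(self):
        assert powerlaw_omega_1d(1.0, 2.0, 0.7) == pytest.approx(2.0)
        assert powerlaw_omega_1d(1.0, 1.5, 1.0) == pytest.approx(1.375)

    @pytest.mark.parametrize("b", [1.2, 1.5, 1.8, 2.0])
    @pytest.mark.parametrize("A", [0.5, 1.0, 3.0])
    def test_variance_round_trip_is_exact(self, b, A):
        """Pushing the 1D O-ring back through the 1D moment integral gives a A^b."""
        a = 0.88
        model = PowerLawTL(a, b, dim=1)
        num = variance_from_lambda2_1d(model.lambda2, A, delta_coeff=model.delta_coeff)
        assert num == pytest.approx(a * A**b, rel=1e-9)

    def test_cov_second_difference_values(self):
        assert powerlaw_cov_1d(1.0, 2.0, 1.0, 0.0) == pytest.approx(1.0)  # = a A^2
        # large-gap decay follows the second derivative, ~ (a b (b-1)/2) A^2 D^(b-2)
        a, b = 0.88, 1.51
        assert powerlaw_cov_1d(a, b, 1.0, 1e4) == pytest.approx(
            0.5 * a * b * (b - 1) * 1e4 ** (b - 2), rel=1e-3
        )
        ds = np.array([1.0, 10.0, 100.0, 1e4])
        assert np.all(np.diff(powerlaw_cov_1d(a, b, 1.0, ds)) < 0)

    def test_cov_matches_triangular_integral(self):
        """Second-difference closed form equals the cross-pair integral in 1D."""
        a, b, A, D = 0.88, 1.51, 1.0, 0.5
        f = lambda u: 0.5 * a * b * (b - 1) * u ** (b - 2)
        val, _ = integrate.quad(lambda u: (A - abs(u - (A + D))) * f(u), D, 2 * A + D)
        assert powerlaw_cov_1d(a, b, A, D) == pytest.approx(val, rel=1e-9)


class TestPowerLaw2D:
    A_GRID = [0.5, 1.0, 4.0, 16.0]

    def test_validity_range_enforced(self):
        with pytest.raises(ValueError, match="1 < b < 2"):
            powerlaw_omega_2d(1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            theory.powerlaw_c2d(1.0, 0.5)

    def test_csr_limit_of_constant(self):
        assert theory.powerlaw_c2d(1.0, 1.0 + 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_omega_positive_and_decreasing(self):
        r = np.linspace(0.05, 5, 50)
        om = powerlaw_omega_2d(0.88, 1.51, r)
        assert np.all(om > 1.0)
        assert np.all(np.diff(om) < 0)

    @pytest.mark.parametrize("A", A_GRID)
    def test_variance_round_trip_within_documented_error(self, A):
        """The approximate 2D O-ring reproduces a A^b to ~5% (flagged approximation)."""
        a, b = 0.88, 1.51
        model = PowerLawTL(a, b, dim=2)
        num = variance_from_lambda2(model.lambda2, A, delta_coeff=model.delta_coeff)
        assert num == pytest.approx(a * A**b, rel=0.06)

    @pytest.mark.parametrize("D", [1.0, 2.0, 4.0])
    def test_cov_tracks_numerical_oracle_at_moderate_gaps(self, D):
        """Quasi-1D expansion is accurate once the gap exceeds the plot side."""
        a, b, A = 0.88, 1.51, 1.0
        model = PowerLawTL(a, b, dim=2)
        num = covariance_from_lambda2(model.lambda2, A, D)
        assert float(model.covariance(A, D)) == pytest.approx(num, rel=0.05)


class TestGenericDispatch:
    def test_omega_from_lambda2_passthrough(self):
        model = GaussianLambda2(ALPHA, BETA)
        r = np.array([0.0, 0.5, 2.0])
        np.testing.assert_allclose(omega_from_lambda2(model.lambda2, r), model.omega(r))

    def test_model_occupancy_and_turnover_bounds(self):
        model = GaussianLambda2(ALPHA, BETA)
        A = np.array([0.1, 1.0, 10.0])
        psi = np.asarray(model.occupancy(A))
        assert np.all((psi > 0) & (psi < 1))
        assert np.all(np.diff(psi) > 0)
        t = np.asarray(model.turnover(1.0, np.array([0.0, 1.0, 5.0])))
        psi1 = float(model.occupancy(1.0))
        assert np.all((t >= psi1 - 1e-12) & (t <= 1.0))
        assert np.all(np.diff(t) < 0)  # turnover decays with gap

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            variance_from_lambda2(lambda r: np.ones_like(r), -1.0)
        with pytest.raises(ValueError):
            covariance_from_lambda2(lambda r: np.ones_like(r), 1.0, 0.5, method="nope")
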