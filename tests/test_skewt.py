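"""Skew-t density, CDF, moments and the CP<->DP conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from aeroyield.exceptions import (
    DegenerateSampleError,
    FeasibilityError,
    InsufficientSampleError,
    ParameterDomainError,
    UndefinedMomentError,
)
from aeroyield.skewt import (
    INF_DF,
    MomentSummary,
    SkewTDirectParams,
    cp_to_dp,
    dp_to_cp,
    sample_moments,
    st_cdf,
    st_pdf,
    st_ppf,
    st_rvs,
)


class TestDensity:
    def test_normal_limit_at_origin(self):
        dp = SkewTDirectParams(0, 1, 0, INF_DF)
        assert st_pdf(0.0, dp) == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-12)

    def test_cauchy_limit_at_origin(self):
        dp = SkewTDirectParams(0, 1, 0, 1)
        assert st_pdf(0.0, dp) == pytest.approx(1 / math.pi, abs=1e-12)

    def test_integrates_to_one(self):
        dp = SkewTDirectParams(2, 3, 4, 8)
        total, _ = integrate.quad(
            lambda x: st_pdf(x, dp), 2 - 150, 2 + 150, limit=300
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterDomainError):
            SkewTDirectParams(0, -1, 0, 5)
        with pytest.raises(ParameterDomainError):
            SkewTDirectParams(0, 1, 0, 0)

    def test_reduces_to_student_t_when_symmetric(self):
        dp = SkewTDirectParams(1.5, 2.0, 0.0, 7.0)
        grid = np.linspace(-20, 25, 101)
        expected = stats.t.pdf((grid - 1.5) / 2.0, 7.0) / 2.0
        np.testing.assert_allclose(st_pdf(grid, dp), expected, atol=1e-10)


class TestCdf:
    def test_half_mass_at_location_when_symmetric(self):
        assert st_cdf(5.0, SkewTDirectParams(5, 2, 0, 10)) == pytest.approx(0.5)

    def test_limits(self):
        dp = SkewTDirectParams(0, 1, 3, 6)
        assert st_cdf(1e9, dp) == pytest.approx(1.0, abs=1e-9)
        assert st_cdf(-1e9, dp) == pytest.approx(0.0, abs=1e-9)

    def test_matches_quadrature_of_density(self):
        dp = SkewTDirectParams(0, 1, 3, 6)
        oracle, _ = integrate.quad(lambda t: st_pdf(t, dp), -np.inf, 1.0, limit=300)
        assert st_cdf(1.0, dp) == pytest.approx(oracle, abs=1e-8)

    def test_monotone_and_quantile_identity(self):
        dp = SkewTDirectParams(1, 2, 4, 9)
        grid = np.linspace(-5, 15, 41)
        cdf = st_cdf(grid, dp)
        assert np.all(np.diff(cdf) >= 0)
        for p in (0.1, 0.5, 0.9):
            assert st_cdf(st_ppf(p, dp), dp) == pytest.approx(p, abs=1e-6)


class TestDpToCp:
    def test_standard_normal(self):
        cp = dp_to_cp(SkewTDirectParams(0, 1, 0, INF_DF))
        assert (cp.mean, cp.sd) == pytest.approx((0.0, 1.0))
        assert (cp.skewness, cp.excess_kurtosis) == pytest.approx((0.0, 0.0))

    def test_student_t_closed_form(self):
        cp = dp_to_cp(SkewTDirectParams(0, 1, 0, 10))
        assert cp.skewness == pytest.approx(0.0, abs=1e-12)
        assert cp.excess_kurtosis == pytest.approx(6.0 / (10 - 4), abs=1e-12)

    def test_matches_moment_quadrature(self):
        dp = SkewTDirectParams(1, 2, 5, 8)
        cp = dp_to_cp(dp)

        def raw(k):
            val, _ = integrate.quad(
                lambda x: x**k * st_pdf(x, dp), -np.inf, np.inf, limit=500
            )
            return val

        m1 = raw(1)
        var = raw(2) - m1**2
        mu3 = raw(3) - 3 * m1 * raw(2) + 2 * m1**3
        mu4 = raw(4) - 4 * m1 * raw(3) + 6 * m1**2 * raw(2) - 3 * m1**4
        assert cp.mean == pytest.approx(m1, rel=1e-6)
        assert cp.sd == pytest.approx(math.sqrt(var), rel=1e-6)
        assert cp.skewness == pytest.approx(mu3 / var**1.5, rel=1e-6)
        assert cp.excess_kurtosis == pytest.approx(mu4 / var**2 - 3, rel=1e-6)

    @pytest.mark.parametrize("nu,moment", [(3.0, "skewness"), (4.0, "kurtosis")])
    def test_undefined_moments_named(self, nu, moment):
        with pytest.raises(UndefinedMomentError, match=moment):
            dp_to_cp(SkewTDirectParams(0, 1, 1, nu))


class TestCpToDp:
    def test_normal_case(self):
        dp = cp_to_dp(MomentSummary(10, 3, 0, 0))
        assert dp.alpha == 0
        assert math.isinf(dp.nu)
        assert dp.omega == pytest.approx(3.0)
        assert dp.xi == pytest.approx(10.0)

    def test_round_trip_inverse_identity(self):
        dp = SkewTDirectParams(1, 2, 5, 8)
        back = cp_to_dp(dp_to_cp(dp))
        assert back.xi == pytest.approx(1, rel=1e-5)
        assert back.omega == pytest.approx(2, rel=1e-5)
        assert back.alpha == pytest.approx(5, rel=1e-5)
        assert back.nu == pytest.approx(8, rel=1e-5)

    def test_against_independent_2d_root_finder(self):
        cp = MomentSummary(18.1, 12.0, 1.5, 4.5)
        dp = cp_to_dp(cp)

        # independent oracle: simultaneous 2-D solve on (log alpha, log(nu-4))
        def resid(theta):
            a, nu = math.exp(theta[0]), 4.0 + math.exp(theta[1])
            m = dp_to_cp(SkewTDirectParams(0, 1, a, nu))
            return [m.skewness - cp.skewness, m.excess_kurtosis - cp.excess_kurtosis]

        sol = optimize.root(resid, x0=[0.0, 2.0], tol=1e-12)
        assert sol.success
        assert dp.alpha == pytest.approx(math.exp(sol.x[0]), rel=1e-6)
        assert dp.nu == pytest.approx(4.0 + math.exp(sol.x[1]), rel=1e-6)
        back = dp_to_cp(dp)
        assert back.skewness == pytest.approx(1.5, abs=1e-6)
        assert back.excess_kurtosis == pytest.approx(4.5, abs=1e-6)

    @pytest.mark.parametrize(
        "g1,g2", [(1.5, 2.0), (2.0, 3.0), (0.0, -1.0), (0.8, 0.1)]
    )
    def test_infeasible_moments_rejected_with_boundary(self, g1, g2):
        with pytest.raises(FeasibilityError, match="attainable|boundary"):
            cp_to_dp(MomentSummary(18, 12, g1, g2))

    def test_negative_skewness_mirrored(self):
        dp = cp_to_dp(MomentSummary(0, 1, -1.0, 3.0))
        assert dp.alpha < 0
        back = dp_to_cp(dp)
        assert back.skewness == pytest.approx(-1.0, abs=1e-7)

    def test_zero_sd_rejected(self):
        with pytest.raises(ParameterDomainError):
            cp_to_dp(MomentSummary(1, 0, 0, 0))


@given(
    alpha=st.floats(-10, 10),
    nu=st.floats(4.5, 50),
    xi=st.floats(-5, 20),
    omega=st.floats(0.1, 30),
)
def test_roundtrip_property(alpha, nu, xi, omega):
    """dp -> cp -> dp is the identity across the parameter box."""
    dp = SkewTDirectParams(xi, omega, alpha, nu)
    back = cp_to_dp(dp_to_cp(dp))
    scale = max(1.0, abs(alpha))
    assert back.xi == pytest.approx(xi, rel=1e-5, abs=1e-5 * omega)
    assert back.omega == pytest.approx(omega, rel=1e-5)
    assert back.alpha == pytest.approx(alpha, rel=1e-4, abs=1e-5 * scale)
    assert back.nu == pytest.approx(nu, rel=1e-4)


@given(alpha=st.floats(-8, 8), nu=st.floats(1.0, 40))
def test_density_normalisation_property(alpha, nu):
    dp = SkewTDirectParams(0, 1, alpha, nu)
    total, _ = integrate.quad(lambda x: st_pdf(x, dp), -60, 60, limit=300)
    tail = stats.t.sf(60, nu) * 2  # symmetric-t envelope bounds the missed mass
    assert total == pytest.approx(1.0, abs=1e-6 + 2 * tail)


def test_parameter_recovery_from_large_sample(rng):
    """Moments of 1e6 draws invert back to the generating parameters."""
    dp = SkewTDirectParams(10, 3, 2, 12)
    y = st_rvs(dp, 1_000_000, rng)
    back = cp_to_dp(sample_moments(y))
    assert back.xi == pytest.approx(dp.xi, rel=0.05)
    assert back.omega == pytest.approx(dp.omega, rel=0.05)
    assert back.alpha == pytest.approx(dp.alpha, rel=0.05)
    assert back.nu == pytest.approx(dp.nu, rel=0.20)


class TestSampleMoments:
    def test_symmetric_sample(self):
        cp = sample_moments([1, 2, 3, 4, 5])
        assert cp.mean == pytest.approx(3.0)
        assert cp.skewness == pytest.approx(0.0, abs=1e-12)

    def test_population_moment_convention(self):
        # direct arithmetic oracle: m4/m2^2 - 3 with n denominators
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        d = x - x.mean()
        expected = (d**4).mean() / (d**2).mean() ** 2 - 3
        assert sample_moments(x).excess_kurtosis == pytest.approx(expected)
        assert sample_moments(x).sd == pytest.approx(np.std(x, ddof=1))

    def test_bias_adjusted_variant_differs(self):
        x = [1.0, 2.0, 4.0, 8.0, 16.0]
        g = sample_moments(x)
        ga = sample_moments(x, bias_adjusted=True)
        assert ga.skewness != pytest.approx(g.skewness)

    def test_small_and_degenerate_samples_rejected(self):
        with pytest.raises(InsufficientSampleError):
            sample_moments([1, 2, 3])
        with pytest.raises(DegenerateSampleError):
            sample_moments([5, 5, 5, 5])
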