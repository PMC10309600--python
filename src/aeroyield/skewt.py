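"""Azzalini skew-t distribution mathematics.

The univariate skew-t family used to model airborne-DNA yields. A member is
described either by its *direct parameters* (DP): location ``xi``, scale
``omega``, slant ``alpha`` and tail degrees of freedom ``nu`` — or by its
*centred parameters* (CP): mean, standard deviation, skewness ``gamma1`` and
excess kurtosis ``gamma2``. This module provides the density, the CDF, the
closed-form DP→CP moment map and its numerical inverse CP→DP, which is how a
moment summary of observed yields is turned into a fitted distribution.

Density (finite ``nu``)::

    f(x) = (2/omega) * t_nu(z) * T_{nu+1}( alpha * z * sqrt((nu+1)/(nu+z^2)) )

with ``z = (x - xi)/omega``, ``t_nu`` the Student-t density and ``T_{nu+1}``
the Student-t CDF. ``nu = inf`` (the sentinel :data:`INF_DF`) gives the
skew-normal member; ``alpha = 0`` gives the symmetric Student-t.

Conventions: ``gamma2`` is always *excess* kurtosis (normal = 0). Finite
skewness needs ``nu > 3``; finite kurtosis needs ``nu > 4``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

from .exceptions import (
    DegenerateSampleError,
    FeasibilityError,
    InsufficientSampleError,
    ParameterDomainError,
    UndefinedMomentError,
)

__all__ = [
    "INF_DF",
    "SkewTDirectParams",
    "MomentSummary",
    "st_pdf",
    "st_cdf",
    "st_ppf",
    "st_rvs",
    "dp_to_cp",
    "cp_to_dp",
    "sample_moments",
]

#: Sentinel tail df meaning "infinite", i.e. the skew-normal limit.
INF_DF = math.inf

# Relative slack within which a (gamma1, gamma2) pair epsilon-outside the
# attainable region is projected onto its boundary instead of rejected.
_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class SkewTDirectParams:
    """Direct parameters (DP) of a skew-t distribution.

    Attributes
    ----------
    xi : float
        Location (ng).
    omega : float
        Scale (ng); must be positive.
    alpha : float
        Slant; 0 gives the symmetric Student-t.
    nu : float
        Tail degrees of freedom; must be positive. ``math.inf`` (INF_DF)
        selects the skew-normal limit. Finite skewness requires nu > 3,
        finite kurtosis nu > 4.
    """

    xi: float
    omega: float
    alpha: float
    nu: float

    def __post_init__(self):
        if not self.omega > 0:
            raise ParameterDomainError(f"scale omega must be > 0, got {self.omega}")
        if not self.nu > 0:
            raise ParameterDomainError(f"tail df nu must be > 0, got {self.nu}")


@dataclass(frozen=True)
class MomentSummary:
    """Centred parameters (CP): mean, sd, skewness, excess kurtosis.

    ``excess_kurtosis`` follows the excess convention (normal = 0). For a
    valid skew-t CP the (skewness, excess_kurtosis) pair must lie in the
    attainable region of the family; :func:`cp_to_dp` checks this.
    """

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterDomainError(f"sd must be >= 0, got {self.sd}")


def _check_dp(dp: SkewTDirectParams) -> None:
    if not dp.omega > 0:
        raise ParameterDomainError(f"scale omega must be > 0, got {dp.omega}")
    if not dp.nu > 0:
        raise ParameterDomainError(f"tail df nu must be > 0, got {dp.nu}")


def st_pdf(x, dp: SkewTDirectParams):
    """Skew-t probability density at ``x`` (scalar or array)."""
    _check_dp(dp)
    x = np.asarray(x, dtype=float)
    z = (x - dp.xi) / dp.omega
    if math.isinf(dp.nu):
        out = stats.skewnorm.pdf(x, dp.alpha, loc=dp.xi, scale=dp.omega)
    else:
        w = dp.alpha * z * np.sqrt((dp.nu + 1.0) / (dp.nu + z * z))
        out = 2.0 / dp.omega * stats.t.pdf(z, dp.nu) * stats.t.cdf(w, dp.nu + 1.0)
    return out if out.ndim else float(out)


def st_cdf(x, dp: SkewTDirectParams):
    """Skew-t CDF at ``x``.

    Closed form in the symmetric and skew-normal limits; otherwise adaptive
    quadrature of :func:`st_pdf`, accurate to ~1e-10.
    """
    _check_dp(dp)
    if math.isinf(dp.nu):
        out = stats.skewnorm.cdf(x, dp.alpha, loc=dp.xi, scale=dp.omega)
        return float(out) if np.ndim(x) == 0 else out
    if dp.alpha == 0:
        out = stats.t.cdf((np.asarray(x, float) - dp.xi) / dp.omega, dp.nu)
        return float(out) if np.ndim(x) == 0 else out

    def _one(xv: float) -> float:
        if np.isposinf(xv):
            return 1.0
        if np.isneginf(xv):
            return 0.0
        z = (xv - dp.xi) / dp.omega
        # integrate over the standardized variable; split at 0 for accuracy
        f = lambda t: float(st_pdf(t, SkewTDirectParams(0.0, 1.0, dp.alpha, dp.nu)))
        if z <= 0:
            val, _ = integrate.quad(f, -np.inf, z, epsabs=1e-12, limit=200)
        else:
            tail, _ = integrate.quad(f, z, np.inf, epsabs=1e-12, limit=200)
            val = 1.0 - tail
        return min(max(val, 0.0), 1.0)

    if np.ndim(x) == 0:
        return _one(float(x))
    return np.array([_one(float(v)) for v in np.asarray(x, float)])


def st_ppf(p, dp: SkewTDirectParams, *, tol: float = 1e-10):
    """Skew-t quantile by bracketed root finding on :func:`st_cdf`."""
    _check_dp(dp)

    def _one(pv: float) -> float:
        if not 0.0 < pv < 1.0:
            raise ParameterDomainError(f"probability must be in (0, 1), got {pv}")
        lo, hi = dp.xi - dp.omega, dp.xi + dp.omega
        while st_cdf(lo, dp) > pv:
            lo -= 2.0 * (dp.xi - lo)
        while st_cdf(hi, dp) < pv:
            hi += 2.0 * (hi - dp.xi)
        return optimize.brentq(lambda x: st_cdf(x, dp) - pv, lo, hi, xtol=tol)

    if np.ndim(p) == 0:
        return _one(float(p))
    return np.array([_one(float(v)) for v in np.asarray(p, float)])


def st_rvs(dp: SkewTDirectParams, size: int, rng: np.random.Generator):
    """Draw ``size`` variates: skew-normal numerator over a chi-square mixing."""
    _check_dp(dp)
    z = stats.skewnorm.rvs(dp.alpha, size=size, random_state=rng)
    if not math.isinf(dp.nu):
        z = z / np.sqrt(rng.chisquare(dp.nu, size=size) / dp.nu)
    return dp.xi + dp.omega * z


def _standardized_moments(alpha: float, nu: float):
    """(mu_z, sigma_z, gamma1, gamma2) of the standardized (xi=0, omega=1) member.

    gamma1 requires nu > 3 and gamma2 requires nu > 4; entries that do not
    exist are returned as nan.
    """
    delta = alpha / math.sqrt(1.0 + alpha * alpha)
    # beyond ~1e8 the finite-nu corrections are O(1/nu), below double precision
    # of the gammaln difference; use the exact skew-normal limit instead
    if math.isinf(nu) or nu >= 1e8:
        b = math.sqrt(2.0 / math.pi)
        mu = b * delta
        s2 = 1.0 - mu * mu
        s = math.sqrt(s2)
        g1 = 0.5 * (4.0 - math.pi) * mu**3 / s2**1.5
        g2 = 2.0 * (math.pi - 3.0) * mu**4 / (s2 * s2)
        return mu, s, g1, g2
    if nu <= 1:
        return math.nan, math.nan, math.nan, math.nan
    b_nu = math.sqrt(nu / math.pi) * math.exp(
        special.gammaln(0.5 * (nu - 1.0)) - special.gammaln(0.5 * nu)
    )
    mu = b_nu * delta
    if nu <= 2:
        return mu, math.nan, math.nan, math.nan
    e2 = nu / (nu - 2.0)
    s2 = e2 - mu * mu
    s = math.sqrt(s2)
    g1 = math.nan
    g2 = math.nan
    if nu > 3:
        g1 = mu * (nu * (3.0 - delta * delta) / (nu - 3.0) - 3.0 * e2 + 2.0 * mu * mu) / s2**1.5
    if nu > 4:
        g2 = (
            3.0 * nu * nu / ((nu - 2.0) * (nu - 4.0))
            - 4.0 * mu * mu * nu * (3.0 - delta * delta) / (nu - 3.0)
            + 6.0 * mu * mu * e2
            - 3.0 * mu**4
        ) / (s2 * s2) - 3.0
    return mu, s, g1, g2


def dp_to_cp(dp: SkewTDirectParams) -> MomentSummary:
    """Closed-form moments (CP) of a skew-t member; requires ``nu > 4``."""
    _check_dp(dp)
    if not math.isinf(dp.nu):
        if dp.nu <= 3:
            raise UndefinedMomentError(
                f"skewness undefined for nu = {dp.nu} (requires nu > 3)"
            )
        if dp.nu <= 4:
            raise UndefinedMomentError(
                f"excess kurtosis undefined for nu = {dp.nu} (requires nu > 4)"
            )
    mu, s, g1, g2 = _standardized_moments(dp.alpha, dp.nu)
    return MomentSummary(
        mean=dp.xi + dp.omega * mu,
        sd=dp.omega * s,
        skewness=g1,
        excess_kurtosis=g2,
    )


# --- CP -> DP inversion ----------------------------------------------------

_DELTA_LO, _DELTA_HI = 1e-12, 1.0 - 1e-12


def _gamma1_of_delta(delta: float, nu: float) -> float:
    alpha = delta / math.sqrt(1.0 - delta * delta)
    return _standardized_moments(alpha, nu)[2]


def _gamma2_of_delta(delta: float, nu: float) -> float:
    alpha = delta / math.sqrt(1.0 - delta * delta)
    return _standardized_moments(alpha, nu)[3]


def _solve_delta(g1: float, nu: float):
    """delta in (0, 1) with gamma1(delta, nu) = g1 >= 0, or None if unattainable."""
    if g1 <= 0.0:
        return 0.0
    hi_val = _gamma1_of_delta(_DELTA_HI, nu)
    if g1 >= hi_val:
        return None
    return optimize.brentq(
        lambda d: _gamma1_of_delta(d, nu) - g1, _DELTA_LO, _DELTA_HI, xtol=1e-14
    )


def cp_to_dp(cp: MomentSummary, *, tol: float = 1e-9) -> SkewTDirectParams:
    """Invert the moment map: find the skew-t DP with the given CP.

    Solves (alpha, nu) from (gamma1, gamma2) by nested deterministic 1-D root
    finding — the inner bracket solves the slant from gamma1 at fixed nu, the
    outer bracket solves nu from the gamma2 residual — then omega from sd and
    xi from the mean. A (gamma1, gamma2) within ``_BOUNDARY_TOL`` (relative)
    of the attainable boundary is projected onto it with a warning.

    Raises
    ------
    FeasibilityError
        If (gamma1, gamma2) lies outside the attainable region, reporting the
        nearest attainable boundary value.
    ParameterDomainError
        If sd <= 0.
    """
    if not cp.sd > 0:
        raise ParameterDomainError(f"sd must be > 0 to invert moments, got {cp.sd}")
    g1 = abs(cp.skewness)
    sgn = -1.0 if cp.skewness < 0 else 1.0
    g2 = cp.excess_kurtosis

    alpha, nu = _solve_shape(g1, g2)
    alpha *= sgn
    mu, s, _, _ = _standardized_moments(alpha, nu)
    omega = cp.sd / s
    xi = cp.mean - omega * mu
    dp = SkewTDirectParams(xi=xi, omega=omega, alpha=alpha, nu=nu)
    # moment-residual sanity check (the solver is bracketed, so this is a guard)
    back = dp_to_cp(dp)
    resid = max(
        abs(back.skewness - cp.skewness), abs(back.excess_kurtosis - cp.excess_kurtosis)
    )
    if resid > max(tol, 1e3 * _BOUNDARY_TOL * (1.0 + abs(g2))):
        warnings.warn(
            f"cp_to_dp boundary projection: moment residual {resid:.3g} "
            "(input was outside or on the attainable boundary)",
            stacklevel=2,
        )
    return dp


def _solve_shape(g1: float, g2: float):
    """(alpha >= 0, nu) matching (g1 >= 0, g2), with boundary projection.

    Outer bracketed solve over the slant delta; the inner bracketed solve
    finds nu from gamma2 at fixed delta (gamma2 decreases monotonically in nu
    from +inf at nu->4 to the skew-normal value at nu->inf, so the feasible
    delta range is exactly where the skew-normal gamma2 stays below g2).
    """
    atol = _BOUNDARY_TOL * (1.0 + abs(g2))

    # symmetric axis: alpha = 0, gamma2 = 6/(nu - 4); skewness below double
    # resolution is treated as exactly symmetric
    if g1 <= 1e-12:
        if abs(g2) <= atol:
            return 0.0, INF_DF
        if g2 < 0.0:
            raise FeasibilityError(
                f"excess kurtosis {g2} below the symmetric skew-t minimum 0 "
                "(nearest attainable boundary: gamma2 = 0 at nu = inf)"
            )
        return 0.0, 4.0 + 6.0 / g2

    # skew-normal (nu = inf) lower boundary in gamma2 for this gamma1
    d_sn = _solve_delta(g1, INF_DF)
    if d_sn is not None:
        g2_sn = _gamma2_of_delta(d_sn, INF_DF)
        if abs(g2 - g2_sn) <= atol:
            return d_sn / math.sqrt(1.0 - d_sn * d_sn), INF_DF
        if g2 < g2_sn:
            raise FeasibilityError(
                f"(gamma1, gamma2) = ({g1}, {g2}) lies below the skew-normal "
                f"boundary (nearest attainable gamma2 = {g2_sn:.6g} at nu = inf)"
            )
    elif g2 <= atol:
        raise FeasibilityError(
            f"(gamma1, gamma2) = ({g1}, {g2}) outside the skew-t attainable "
            "region (excess kurtosis must be positive at this skewness)"
        )

    # largest delta for which nu is solvable: skew-normal gamma2 < g2 there
    if _gamma2_of_delta(_DELTA_HI, INF_DF) < g2:
        d_edge = _DELTA_HI
    else:
        d_edge = optimize.brentq(
            lambda d: _gamma2_of_delta(d, INF_DF) - g2, _DELTA_LO, _DELTA_HI,
            xtol=1e-15,
        ) * (1.0 - 1e-9)

    _U_LO, _U_HI = -30.0, 40.0

    def nu_of_delta(d: float) -> float:
        h = lambda u: _gamma2_of_delta(d, 4.0 + math.exp(u)) - g2
        if h(_U_HI) >= 0.0:  # numerically at the skew-normal edge already
            return INF_DF
        return 4.0 + math.exp(optimize.brentq(h, _U_LO, _U_HI, xtol=1e-13))

    def f(d: float) -> float:
        return _gamma1_of_delta(d, nu_of_delta(d)) - g1

    # scan on an atanh grid (dense near delta = 1), bracket the upcrossing;
    # seeded at delta = 0 where f = -g1 <= 0 so roots near zero slant bracket
    s_grid = np.linspace(0.0, math.atanh(d_edge), 121)[1:]
    prev_s, prev_f = 0.0, -g1
    best_f = -math.inf
    best_d = None
    for s in s_grid:
        d = math.tanh(float(s))
        fv = f(d)
        if fv > best_f:
            best_f, best_d = fv, d
        if prev_f is not None and prev_f < 0.0 <= fv:
            s_root = optimize.brentq(
                lambda ss: f(math.tanh(ss)), prev_s, float(s), xtol=1e-13
            )
            d_root = math.tanh(s_root)
            return d_root / math.sqrt(1.0 - d_root * d_root), nu_of_delta(d_root)
        prev_s, prev_f = float(s), fv

    if best_f >= -_BOUNDARY_TOL * (1.0 + g1):  # epsilon outside: project
        warnings.warn(
            "moment summary projected onto the skew-t attainable boundary "
            f"(gamma1 residual {best_f:.3g})",
            stacklevel=3,
        )
        return best_d / math.sqrt(1.0 - best_d * best_d), nu_of_delta(best_d)
    raise FeasibilityError(
        f"(gamma1, gamma2) = ({g1}, {g2}) outside the skew-t attainable region "
        f"(nearest attainable |gamma1| = {best_f + g1:.6g} at this gamma2)"
    )


def sample_moments(values, *, bias_adjusted: bool = False) -> MomentSummary:
    """Mean, sd, skewness and excess kurtosis of a sample of yields.

    The default estimator convention is population moments for shape:
    ``g1 = m3/m2**1.5`` and ``g2 = m4/m2**2 - 3`` with ``m_k`` the central
    moments with denominator ``n``; the sd uses the unbiased ``n - 1``
    denominator. ``bias_adjusted=True`` switches the shape estimators to the
    standard bias-adjusted (G1, G2) forms.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    n = x.size
    if n < 4:
        raise InsufficientSampleError(f"need at least 4 observations, got {n}")
    m2 = float(np.var(x))
    if m2 == 0.0:
        raise DegenerateSampleError("all observations identical: zero variance")
    g1 = float(stats.skew(x, bias=not bias_adjusted))
    g2 = float(stats.kurtosis(x, fisher=True, bias=not bias_adjusted))
    return MomentSummary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        skewness=g1,
        excess_kurtosis=g2,
    )
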