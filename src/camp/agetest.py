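"""Age-specific significance testing for CAMP fits.

The fitted effect trajectory is beta(t) = beta0 + beta1*(t - t0) with
variance Var(beta(t)) = var0 + (t-t0)^2 var1 + 2 (t-t0) cov01, giving the
Wald-type statistic

    chi2(t) = beta(t)^2 / Var(beta(t)).

chi2(t) has a closed-form global minimum (value 0) at t1* = -beta0/beta1 + t0
and a global maximum at

    t2* = (beta0*cov01 - beta1*var0) / (beta1*cov01 - beta0*var1) + t0,

and tends to the slope statistic beta1^2/var1 as t -> +/- infinity.  Under
the joint null (beta0 = beta1 = 0) the maximized statistic chi2(t2*) is
chi-squared with 2 degrees of freedom, so p-values for chi2(t) at *any* age
— and for the slope statistic — can be read off the chi2(df=2) survival
function p = exp(-chi2/2) without a multiple-testing penalty: the statistic
at any single age is dominated by the maximum, whose null law is exactly
chi2(df=2).  The slope test is compared against the same df=2 reference and
is therefore deliberately conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import CampFit
from .exceptions import DegenerateFit, InvalidCovariance, NegativeStatistic

#: ages (years) at which genome scans evaluate the statistic by default
GRID_AGES = (41.0, 43.0, 45.0, 47.0, 49.0, 51.0, 53.0, 55.0)

#: default clamping window for the maximum-evidence test
DEFAULT_WINDOW = (45.0, 52.0)

#: below this, |beta1| or the t2* denominator counts as degenerate
DEGENERACY_TOL = 1e-12

_LN10 = math.log(10.0)

GENOME_WIDE_P = 5e-8
NOMINAL_P = 0.05


@dataclass
class AgeTestResult:
    """One significance test of an age-varying marker effect.

    ``p_value`` underflows to 0.0 for chi2 beyond roughly 1480;
    ``log10_p`` is always finite and is what serialized output carries.
    """

    marker_id: str | None
    test_kind: str                    # grid_age | max_evidence | slope
    age_evaluated: float | None
    chi2: float
    p_value: float
    log10_p: float
    evidence_class: str | None = None


@dataclass
class ExtremeTimes:
    """Stationary ages of chi2(t) with at-infinity degeneracy flags."""

    t1: float
    t2: float
    t1_at_infinity: bool
    t2_at_infinity: bool


def beta_at(fit: CampFit, t) -> float | np.ndarray:
    """Linear effect trajectory beta0 + beta1*(t - t0)."""
    return fit.beta0 + fit.beta1 * (np.asarray(t, dtype=float) - fit.t0)


def variance_at(fit: CampFit, t) -> float | np.ndarray:
    """Variance of the estimated effect at age ``t`` (quadratic in t - t0)."""
    if fit.cov01 ** 2 > fit.var0 * fit.var1:
        raise InvalidCovariance(
            "cov01^2 exceeds var0*var1; the covariance block is not PSD"
        )
    dt = np.asarray(t, dtype=float) - fit.t0
    return fit.var0 + dt ** 2 * fit.var1 + 2.0 * dt * fit.cov01


def chi2_at(fit: CampFit, t) -> float | np.ndarray:
    """Wald statistic beta(t)^2 / Var(beta(t))."""
    return beta_at(fit, t) ** 2 / variance_at(fit, t)


def extreme_times(fit: CampFit, tol: float = DEGENERACY_TOL) -> ExtremeTimes:
    """Closed-form stationary ages of chi2(t).

    ``t1`` is the global minimum (chi2 = 0 when finite), ``t2`` the global
    maximum.  Either may be flagged at-infinity: t1 when |beta1| < tol (the
    trajectory never crosses zero), t2 when the denominator
    |beta1*cov01 - beta0*var1| < tol, in which case the supremum equals the
    limiting slope statistic beta1^2/var1.

    Raises
    ------
    DegenerateFit
        If beta0 = beta1 = 0 exactly (the statistic is identically zero).
    """
    b0, b1 = fit.beta0, fit.beta1
    if b0 == 0.0 and b1 == 0.0:
        raise DegenerateFit("beta0 = beta1 = 0: chi2(t) is identically zero")
    if abs(b1) < tol:
        t1, t1_inf = math.inf, True
    else:
        t1, t1_inf = -b0 / b1 + fit.t0, False
    denom = b1 * fit.cov01 - b0 * fit.var1
    if abs(denom) < tol:
        t2, t2_inf = math.inf, True
    else:
        t2 = (b0 * fit.cov01 - b1 * fit.var0) / denom + fit.t0
        t2_inf = False
    return ExtremeTimes(t1=t1, t2=t2, t1_at_infinity=t1_inf, t2_at_infinity=t2_inf)


def chi2_max(fit: CampFit, tol: float = DEGENERACY_TOL) -> tuple[float, float, bool]:
    """(chi2 at the global maximum, the age, at-infinity flag)."""
    ext = extreme_times(fit, tol=tol)
    if ext.t2_at_infinity:
        return fit.beta1 ** 2 / fit.var1, math.inf, True
    return float(chi2_at(fit, ext.t2)), ext.t2, False


def chi2_max_decomposition(fit: CampFit) -> float:
    """Algebraically equivalent closed form of chi2(t2*).

    chi2(t2*) = (b0^2 var1 - 2 b0 b1 cov01 + b1^2 var0)
                / (var0 var1 - cov01^2),

    the quadratic form of (b0, b1) in the inverse covariance block — i.e.
    the joint 2-df Wald statistic, which is why the maximized statistic is
    chi-squared(2) under the joint null.
    """
    num = (fit.beta0 ** 2 * fit.var1
           - 2.0 * fit.beta0 * fit.beta1 * fit.cov01
           + fit.beta1 ** 2 * fit.var0)
    det = fit.var0 * fit.var1 - fit.cov01 ** 2
    return num / det


def pvalue_chi2df2(chi2: float) -> float:
    """Survival function of chi-squared(df=2): p = exp(-chi2/2)."""
    if chi2 < 0:
        raise NegativeStatistic(f"chi2 = {chi2} is negative")
    return math.exp(-chi2 / 2.0)


def log10_pvalue_chi2df2(chi2: float) -> float:
    """log10 of the chi-squared(df=2) p-value; finite for any statistic."""
    if chi2 < 0:
        raise NegativeStatistic(f"chi2 = {chi2} is negative")
    return -chi2 / (2.0 * _LN10)


def _result(marker_id, kind, age, chi2) -> AgeTestResult:
    return AgeTestResult(
        marker_id=marker_id,
        test_kind=kind,
        age_evaluated=age,
        chi2=float(chi2),
        p_value=pvalue_chi2df2(chi2),
        log10_p=log10_pvalue_chi2df2(chi2),
    )


def max_evidence_test(fit: CampFit, window=DEFAULT_WINDOW,
                      marker_id=None) -> AgeTestResult:
    """Test at the age of maximum evidence, clamped to ``window``.

    If t2* lies inside the (open) window the statistic is evaluated there;
    otherwise chi2 is evaluated at both window endpoints and the larger
    value is taken (the lower age on an exact tie).  A degenerate fit
    (beta0 = beta1 = 0) yields chi2 = 0, p = 1.
    """
    lo, hi = float(window[0]), float(window[1])
    try:
        ext = extreme_times(fit)
    except DegenerateFit:
        return _result(marker_id, "max_evidence", None, 0.0)
    if not ext.t2_at_infinity and lo < ext.t2 < hi:
        return _result(marker_id, "max_evidence", ext.t2, chi2_at(fit, ext.t2))
    c_lo, c_hi = float(chi2_at(fit, lo)), float(chi2_at(fit, hi))
    if c_hi > c_lo:
        return _result(marker_id, "max_evidence", hi, c_hi)
    return _result(marker_id, "max_evidence", lo, c_lo)


def slope_test(fit: CampFit, marker_id=None) -> AgeTestResult:
    """Test H0: beta1 = 0 with chi2 = beta1^2/var1 (the t -> infinity limit
    of chi2(t)), referred to chi-squared(df=2) — conservative by design."""
    return _result(marker_id, "slope", None, fit.beta1 ** 2 / fit.var1)


def grid_test(fit: CampFit, ages=GRID_AGES, marker_id=None) -> list[AgeTestResult]:
    """Evaluate chi2(t) and its chi-squared(2) p-value on a grid of ages.

    Testing every grid age needs no multiplicity correction: each statistic
    is bounded by chi2(t2*), whose null law the reference distribution
    already is.
    """
    return [_result(marker_id, "grid_age", float(a), chi2_at(fit, float(a)))
            for a in ages]


def classify_evidence(discovery_slope_p: float,
                      replication_slope_p: float | None = None,
                      sign_concordant: bool = False) -> str:
    """Tier the evidence for an age-specific (slope) effect.

    none if p >= 0.05; weak if p < 0.05; moderate if p < 5e-8; strong if
    moderate and the replication slope has p < 0.05 with the same sign.
    """
    if not (0.0 < discovery_slope_p <= 1.0):
        raise ValueError("discovery p-value must lie in (0, 1]")
    if discovery_slope_p >= NOMINAL_P:
        return "none"
    if discovery_slope_p >= GENOME_WIDE_P:
        return "weak"
    if (replication_slope_p is not None
            and replication_slope_p < NOMINAL_P and sign_concordant):
        return "strong"
    return "moderate"
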