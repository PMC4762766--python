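"""Weibull and left-truncated Weibull distribution math for the illness-death model.

All times are measured in years since age 45, the time origin at which the
aging-related disease process is taken to start.  Delayed entry into a cohort
at age ``45 + l`` is handled by left truncation at ``l``: the subject is known
to be event-free at ``l``, and every distributional quantity is conditioned on
survival past ``l``.

A Weibull(scale ``lam``, shape ``rho``) waiting time has hazard
``q(t) = (rho/lam) (t/lam)^(rho-1)``; the hazard is unchanged by left
truncation, which is what makes the truncated family closed under delayed
entry.  The illness-death model composes two such cause-specific hazards
(healthy->diseased, healthy->dead) into state-occupancy probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "WeibullParams",
    "TransitionSet",
    "DegenerateTruncationError",
    "QuadratureError",
    "weibull_pdf",
    "weibull_cdf",
    "weibull_sf",
    "trunc_pdf",
    "trunc_cdf",
    "trunc_hazard",
    "trunc_quantile",
    "cumulative_hazard",
    "occupancy_probabilities",
]

#: survival probabilities below this at the truncation point are treated as
#: numerically degenerate (essentially no distribution mass left of infinity)
_DEGENERATE_SURVIVAL = 1e-12


class DegenerateTruncationError(ValueError):
    """Raised when truncation is applied beyond the numerical support."""


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to reach the requested tolerance."""


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape parameterisation of a Weibull waiting time.

    ``scale`` is in years since age 45; ``shape`` is dimensionless.  Shape > 1
    gives a hazard that increases with age, the typical situation for
    chronic-disease incidence and all-cause mortality in mid-to-late life.
    """

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be positive and finite, got {self.shape}")


@dataclass(frozen=True)
class TransitionSet:
    """Cause-specific Weibull parameters for the two transitions out of 'healthy'."""

    healthy_to_diseased: WeibullParams
    healthy_to_dead: WeibullParams


def _check_nonnegative(t, name: str = "t"):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"{name} must be non-negative")
    return t


def _check_truncation(p: WeibullParams, l: float) -> float:
    if not (l >= 0 and math.isfinite(l)):
        raise ValueError(f"truncation point must be finite and >= 0, got {l}")
    sf_l = float(np.exp(-((l / p.scale) ** p.shape)))
    if sf_l < _DEGENERATE_SURVIVAL:
        raise DegenerateTruncationError(
            f"survival past truncation point l={l} is {sf_l:.3e} "
            f"(below {_DEGENERATE_SURVIVAL}); the truncated distribution is degenerate"
        )
    return sf_l


def weibull_pdf(t, p: WeibullParams):
    """Weibull density f(t) = (rho/lam)(t/lam)^(rho-1) exp(-(t/lam)^rho)."""
    t = _check_nonnegative(t)
    lam, rho = p.scale, p.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        z = t / lam
        out = np.where(
            t == 0,
            0.0 if rho > 1 else (1.0 / lam if rho == 1 else np.inf),
            (rho / lam) * z ** (rho - 1) * np.exp(-(z**rho)),
        )
    return out if out.ndim else float(out)


def weibull_cdf(t, p: WeibullParams):
    """Weibull distribution function F(t) = 1 - exp(-(t/lam)^rho)."""
    t = _check_nonnegative(t)
    out = -np.expm1(-((t / p.scale) ** p.shape))
    return out if out.ndim else float(out)


def weibull_sf(t, p: WeibullParams):
    """Weibull survival function exp(-(t/lam)^rho)."""
    t = _check_nonnegative(t)
    out = np.exp(-((t / p.scale) ** p.shape))
    return out if out.ndim else float(out)


def trunc_pdf(t, p: WeibullParams, l: float = 0.0):
    """Density of the Weibull left-truncated at ``l``; zero for t < l."""
    sf_l = _check_truncation(p, l)
    t = np.asarray(t, dtype=float)
    out = np.where(t >= l, weibull_pdf(np.maximum(t, 0.0), p) / sf_l, 0.0)
    return out if out.ndim else float(out)


def trunc_cdf(t, p: WeibullParams, l: float = 0.0):
    """Distribution function of the left-truncated Weibull: (F(t)-F(l))/(1-F(l))."""
    sf_l = _check_truncation(p, l)
    t = np.asarray(t, dtype=float)
    if np.any(t < l):
        raise ValueError("trunc_cdf requires t >= l")
    # (F(t) - F(l)) / S(l) = 1 - S(t)/S(l), computed on the survival scale
    out = -np.expm1(-((t / p.scale) ** p.shape) + (l / p.scale) ** p.shape)
    return out if out.ndim else float(out)


def trunc_hazard(t, p: WeibullParams):
    """Hazard (rho/lam)(t/lam)^(rho-1); invariant under left truncation.

    Rejects t = 0 for shape < 1, where the hazard diverges.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if p.shape < 1 and np.any(t == 0):
        raise ValueError("hazard diverges at t=0 for shape < 1")
    lam, rho = p.scale, p.shape
    with np.errstate(divide="ignore"):
        out = np.where(
            t == 0,
            0.0 if rho > 1 else 1.0 / lam,  # shape==1: constant hazard
            (rho / lam) * (t / lam) ** (rho - 1),
        )
    return out if out.ndim else float(out)


def trunc_quantile(u, p: WeibullParams, l: float = 0.0):
    """Quantile of the left-truncated Weibull.

    Inverts the truncated CDF by conditional survival:
    ``t = lam * (H(l) - ln(1-u))^(1/rho)`` with ``H(l) = (l/lam)^rho`` the
    baseline cumulative hazard at the truncation point.  ``u=0`` maps to ``l``
    exactly.  Used to simulate delayed-entry waiting times by inversion of a
    Uniform(0,1) draw.
    """
    _check_truncation(p, l)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    lam, rho = p.scale, p.shape
    out = lam * ((l / lam) ** rho - np.log1p(-u)) ** (1.0 / rho)
    return out if out.ndim else float(out)


def cumulative_hazard(t1, t2, p: WeibullParams):
    """Integrated hazard over (t1, t2]: (t2/lam)^rho - (t1/lam)^rho."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 < 0) or np.any(t2 < t1):
        raise ValueError("require 0 <= t1 <= t2")
    out = (t2 / p.scale) ** p.shape - (t1 / p.scale) ** p.shape
    return out if out.ndim else float(out)


def occupancy_probabilities(
    t1: float,
    t2: float,
    ts: TransitionSet,
    hazard_multiplier_12: float = 1.0,
    epsabs: float = 1e-8,
) -> tuple[float, float, float]:
    """State-occupancy probabilities over (t1, t2] given healthy at t1.

    Returns ``(p11, p12, p13)``: still healthy, diseased, and dead without
    disease.  The 1->2 hazard is scaled by ``hazard_multiplier_12`` (covariate
    and frailty effects under proportional hazards).  Disease is treated as
    absorbing for counting purposes (no 2->3 hazard enters), so

        p11(t1,t2) = exp(-m*Q12(t1,t2) - Q13(t1,t2))
        p12(t1,t2) = int_{t1}^{t2} p11(t1,t) * m*q12(t) dt
        p13(t1,t2) = int_{t1}^{t2} p11(t1,t) * q13(t) dt

    evaluated by adaptive quadrature with absolute tolerance ``epsabs``.
    """
    if not 0 <= t1 <= t2:
        raise ValueError("require 0 <= t1 <= t2")
    if hazard_multiplier_12 < 0:
        raise ValueError("hazard_multiplier_12 must be >= 0")
    if t1 == t2:
        return 1.0, 0.0, 0.0
    m = hazard_multiplier_12
    p12w, p13w = ts.healthy_to_diseased, ts.healthy_to_dead

    def surv(t: float) -> float:
        return math.exp(
            -m * cumulative_hazard(t1, t, p12w) - cumulative_hazard(t1, t, p13w)
        )

    p11 = surv(t2)

    def run_quad(integrand, label: str) -> float:
        val, abserr = integrate.quad(integrand, t1, t2, epsabs=epsabs, limit=200)
        if abserr > max(epsabs * 10, 1e-10 * max(abs(val), 1.0)):
            raise QuadratureError(
                f"quadrature for {label} over ({t1}, {t2}) reached abserr={abserr:.2e}"
            )
        return val

    p12 = 0.0
    if m > 0:
        p12 = run_quad(lambda t: surv(t) * m * trunc_hazard(t, p12w), "p12")
    p13 = run_quad(lambda t: surv(t) * trunc_hazard(t, p13w), "p13")
    return p11, p12, p13
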