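"""Closed-form stationary theory of the SCG model.

The velocity/auxiliary subsystem of the SCG model admits an explicit
stationary density.  With the identity map on the auxiliary variable the
stationary law factorises into Gaussians in the velocity ``V`` and auxiliary
``Z`` and a symmetric non-Gaussian marginal in the acceleration ``U``:

* one-parameter family (exponent ``eta5``, scale group ``sigma``):
  ``p(u) ∝ |u|^(eta5-1) exp[-eta5 |u|^(1+eta5) / (sigma (1+eta5))]`` —
  a (possibly unbounded at zero, always integrable) stretched exponential,

* two-parameter family: the same tail glued to a Gaussian core for
  ``|u| <= eta6``, with all absolute moments expressible through the helper
  function ``F(kappa1, kappa2, alpha)`` built from unnormalized upper and
  lower incomplete gamma functions.

All dimensionless moment ratios (kurtosis, <U^2>/<|U|>^2) depend only on the
shape parameters, which is what makes the moment-based parametrization
procedures closed.  The scale group ``sigma = eta4^2/(2 eta2 eta3)`` carries
the physical units (nm^2 ps^-4 for an acceleration variable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import special as sc

from .errors import ValidationError

__all__ = [
    "MomentSummary",
    "KappaPair",
    "SigmaGroup",
    "abs_moment_one",
    "kurtosis_one",
    "ratio_one",
    "F_func",
    "log_F",
    "kurtosis_two",
    "ratio_two",
    "mean_abs_over_eta6",
    "density",
    "density_one",
    "density_two",
    "vz_moments",
    "generalN_moments",
]

# Below this the two-parameter formulas switch to their analytic eta6 -> 0
# limits: the two F-terms cancel catastrophically for smaller kappa1.
_SMALL_KAPPA1 = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MomentSummary:
    """Moment statistics linking trajectory estimation to SCG fitting.

    All fields are optional; each fitting procedure states which it needs.

    Attributes
    ----------
    D : float, optional
        Diffusion constant, nm^2 ps^-1.
    v2 : float, optional
        Velocity second moment <V^2>, nm^2 ps^-2.
    z2 : float, optional
        Auxiliary-variable second moment <Z^2>.
    absU, u2, u4 : float, optional
        First absolute, second and fourth moments of the acceleration,
        nm ps^-2 / nm^2 ps^-4 / nm^4 ps^-8.
    se : dict, optional
        Standard errors keyed by field name (filled by estimators).
    """

    D: Optional[float] = None
    v2: Optional[float] = None
    z2: Optional[float] = None
    absU: Optional[float] = None
    u2: Optional[float] = None
    u4: Optional[float] = None
    se: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("D", "v2", "z2", "absU", "u2", "u4"):
            val = getattr(self, name)
            if val is not None and not (val > 0):
                raise ValidationError(f"moment {name} must be positive, got {val}")
        # Jensen inequalities (allow a little slack for estimation noise
        # exactly at equality -- strict violation is a data error).
        if self.u2 is not None and self.u4 is not None and self.u4 < self.u2**2:
            raise ValidationError("u4 < u2^2 violates Jensen's inequality")
        if self.u2 is not None and self.absU is not None and self.u2 < self.absU**2:
            raise ValidationError("u2 < absU^2 violates Jensen's inequality")

    @property
    def kurtosis(self) -> float:
        """<U^4>/<U^2>^2."""
        if self.u2 is None or self.u4 is None:
            raise ValidationError("kurtosis requires u2 and u4")
        return self.u4 / self.u2**2

    @property
    def ratio(self) -> float:
        """<U^2>/<|U|>^2."""
        if self.u2 is None or self.absU is None:
            raise ValidationError("ratio requires u2 and absU")
        return self.u2 / self.absU**2


@dataclass(frozen=True)
class KappaPair:
    """Dimensionless reparametrization of the two-parameter model:
    ``kappa1 = eta2 eta3 eta5 eta6^(1+eta5) / eta4^2`` (>= 0) and
    ``kappa2 = 1/(1+eta5)`` in (0, 1)."""

    kappa1: float
    kappa2: float

    def __post_init__(self) -> None:
        if not (self.kappa1 >= 0):
            raise ValidationError(f"kappa1 must be >= 0, got {self.kappa1}")
        if not (0 < self.kappa2 < 1):
            raise ValidationError(f"kappa2 must be in (0, 1), got {self.kappa2}")

    @property
    def eta5(self) -> float:
        return (1.0 - self.kappa2) / self.kappa2


@dataclass(frozen=True)
class SigmaGroup:
    """The grouped constant ``sigma = eta4^2 / (2 eta2 eta3)`` (nm^2 ps^-4),
    the only combination of the bath rates the stationary acceleration
    distribution sees."""

    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValidationError(f"sigma must be positive, got {self.sigma}")


def _sigma_value(sigma: Union[float, SigmaGroup]) -> float:
    return sigma.sigma if isinstance(sigma, SigmaGroup) else float(sigma)


# ---------------------------------------------------------------------------
# one-parameter family
# ---------------------------------------------------------------------------


def abs_moment_one(alpha: float, eta5: float, sigma: Union[float, SigmaGroup]) -> float:
    """Absolute moment <|U|^alpha> of the one-parameter stationary density.

    ``(sigma (1+eta5)/eta5)^(alpha/(1+eta5)) * G((alpha+eta5)/(1+eta5)) /
    G(eta5/(1+eta5))`` with ``G`` the gamma function.  ``alpha = 0`` gives 1
    (normalization); ``eta5 = 1, alpha = 2`` gives ``sigma`` (Gaussian).
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    if not (eta5 > 0):
        raise ValidationError("eta5 must be positive")
    s = _sigma_value(sigma)
    op = 1.0 + eta5
    lg = math.lgamma((alpha + eta5) / op) - math.lgamma(eta5 / op)
    return (s * op / eta5) ** (alpha / op) * math.exp(lg)


def kurtosis_one(eta5: float) -> float:
    """Kurtosis of the one-parameter stationary acceleration distribution.

    Depends on ``eta5`` only; equals 3 at ``eta5 = 1``, is > 3 (leptokurtic)
    for ``eta5 < 1`` and < 3 (platykurtic) for ``eta5 > 1``, decreasing to 1
    as ``eta5 -> inf``.
    """
    if not (eta5 > 0):
        raise ValidationError("eta5 must be positive")
    op = 1.0 + eta5
    return math.exp(
        math.lgamma(eta5 / op)
        + math.lgamma((4.0 + eta5) / op)
        - 2.0 * math.lgamma((2.0 + eta5) / op)
    )


def ratio_one(eta5: float) -> float:
    """<U^2>/<|U|>^2 of the one-parameter family:
    ``pi / ((1+eta5) sin(pi/(1+eta5)))`` — pi/2 at ``eta5 = 1``, decreasing
    to 1 as ``eta5 -> inf``."""
    if not (eta5 > 0):
        raise ValidationError("eta5 must be positive")
    x = math.pi / (1.0 + eta5)
    return x / math.sin(x)


# ---------------------------------------------------------------------------
# two-parameter family: the incomplete-gamma helper F
# ---------------------------------------------------------------------------


def _log_upper_gamma_scaled(s: float, y: float) -> float:
    """log( e^y * Gamma(s, y) ) with Gamma the UNNORMALIZED upper incomplete
    gamma function, stable for large y.

    For moderate y the regularized scipy routine is rescaled; once it
    underflows, a Lentz continued fraction for ``e^y Gamma(s,y) = y^s / CF``
    takes over (valid and rapidly convergent for y >> s).
    """
    if y < 0:
        raise ValidationError("y must be >= 0")
    if y == 0.0:
        return math.lgamma(s)
    q = sc.gammaincc(s, y)
    if q > 1e-280:
        return y + math.lgamma(s) + math.log(q)
    # Modified Lentz on  Gamma(s,y) = e^{-y} y^s / (y+1-s - 1(1-s)/(y+3-s - ...))
    tiny = 1e-300
    b = y + 1.0 - s
    c = 1.0 / tiny
    d = 1.0 / b if b != 0 else 1.0 / tiny
    h = d
    for i in range(1, 300):
        an = -i * (i - s)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return s * math.log(y) + math.log(h)


def log_F(kappa1: float, kappa2: float, alpha: float) -> float:
    """log of the moment helper ``F(kappa1, kappa2, alpha)``.

    ``F = (2 k1 k2)^((1-a) k2) e^(2 k1 k2) Gamma(1+(a-1) k2, 2 k1 k2)
        + k1^((1-a)/2) e^(k1) gamma((a+1)/2, k1)``
    with unnormalized upper (Gamma) and lower (gamma) incomplete gamma
    functions.  Evaluated in log space so that values remain usable far past
    double overflow of F itself (kappa1 of order hundreds).
    """
    k1, k2, a = float(kappa1), float(kappa2), float(alpha)
    if k1 < 0 or not (0 < k2 < 1):
        raise ValidationError("need kappa1 >= 0 and kappa2 in (0,1)")
    if a < 0:
        raise ValidationError("alpha must be >= 0")
    s1 = 1.0 + (a - 1.0) * k2
    y = 2.0 * k1 * k2
    if k1 == 0.0:
        return _log_F_zero(a, k2)
    t1 = (1.0 - a) * k2 * math.log(y) + _log_upper_gamma_scaled(s1, y)
    s2 = (a + 1.0) / 2.0
    p = sc.gammainc(s2, k1)  # regularized lower
    t2 = (1.0 - a) / 2.0 * math.log(k1) + k1 + math.lgamma(s2) + math.log(p)
    return np.logaddexp(t1, t2)


def _log_F_zero(a: float, k2: float) -> float:
    """limit of log F as kappa1 -> 0+ (finite only for alpha <= 1; for
    alpha = 1 it is 0, for alpha < 1 it is -inf from the prefactor unless
    alpha = 1 -- callers use ratios where the divergences cancel)."""
    if a == 1.0:
        return 0.0
    if a < 1.0:
        return -math.inf
    return math.inf


def F_func(kappa: KappaPair, alpha: float) -> float:
    """The moment helper ``F`` itself (overflow-guarded via :func:`log_F`).
    ``F(kappa, 1) = exp(kappa1)`` exactly."""
    return float(math.exp(log_F(kappa.kappa1, kappa.kappa2, alpha)))


def kurtosis_two(kappa: KappaPair) -> float:
    """Kurtosis of the two-parameter stationary density,
    ``F(4) F(0) / F(2)^2``; reduces to :func:`kurtosis_one` as
    ``kappa1 -> 0``."""
    k1, k2 = kappa.kappa1, kappa.kappa2
    if k1 < _SMALL_KAPPA1:
        return kurtosis_one((1.0 - k2) / k2)
    return float(
        math.exp(log_F(k1, k2, 4.0) + log_F(k1, k2, 0.0) - 2.0 * log_F(k1, k2, 2.0))
    )


def ratio_two(kappa: KappaPair) -> float:
    """<U^2>/<|U|>^2 of the two-parameter family,
    ``F(2) F(0) / exp(2 kappa1)``; reduces to :func:`ratio_one` as
    ``kappa1 -> 0``."""
    k1, k2 = kappa.kappa1, kappa.kappa2
    if k1 < _SMALL_KAPPA1:
        return ratio_one((1.0 - k2) / k2)
    return float(math.exp(log_F(k1, k2, 2.0) + log_F(k1, k2, 0.0) - 2.0 * k1))


def mean_abs_over_eta6(kappa: KappaPair) -> float:
    """<|U|>/eta6 = exp(kappa1)/F(kappa1, kappa2, 0)."""
    k1, k2 = kappa.kappa1, kappa.kappa2
    return float(math.exp(k1 - log_F(k1, k2, 0.0)))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def density_one(u, eta5: float, sigma: Union[float, SigmaGroup]):
    """Normalized one-parameter stationary marginal of the acceleration.

    ``p(u) = C |u|^(eta5-1) exp[-eta5 |u|^(1+eta5)/(sigma (1+eta5))]``.
    For ``eta5 < 1`` the density is unbounded (but integrable) at zero;
    evaluation at ``u = 0`` returns ``inf`` there as a documented sentinel.
    """
    s = _sigma_value(sigma)
    if not (eta5 > 0):
        raise ValidationError("eta5 must be positive")
    op = 1.0 + eta5
    b = eta5 / (s * op)
    logC = (
        math.log(op / 2.0)
        + (eta5 / op) * math.log(b)
        - math.lgamma(eta5 / op)
    )
    u = np.asarray(u, dtype=float)
    au = np.abs(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(logC + (eta5 - 1.0) * np.log(au) - b * au**op)
    if eta5 < 1.0:
        out = np.where(au == 0.0, np.inf, out)
    elif eta5 > 1.0:
        out = np.where(au == 0.0, 0.0, out)
    else:
        out = np.where(au == 0.0, math.exp(logC), out)
    return out if out.ndim else float(out)


def _density_two_lognorm(eta5: float, eta6: float, sigma: float) -> float:
    """log normalization constant of the two-parameter marginal.

    Integrates the unnormalized density exactly: the Gaussian core in terms
    of the error function, the tail via the upper incomplete gamma function.
    """
    op = 1.0 + eta5
    b = eta5 / (sigma * op)  # tail exponent coefficient
    a_core = eta5 * eta6 ** (op - 2.0) / (2.0 * sigma)  # core: exp(-a u^2)
    # relative offset making the two branches continuous at |u| = eta6
    shift = b * eta6**op * (eta5 - 1.0) / 2.0
    # core integral: 2 eta6^(eta5-1) e^{shift- a eta6^2 ... } handled numerically
    # in log space using erf
    core = (
        eta6 ** (eta5 - 1.0)
        * math.exp(shift)
        * math.sqrt(math.pi / a_core)
        * math.erf(math.sqrt(a_core) * eta6)
    )
    # tail: 2 \int_eta6^inf u^{eta5-1} e^{-b u^{1+eta5}} du
    #     = (2/(op b^{eta5/op})) Gamma(eta5/op, b eta6^op)
    s = eta5 / op
    y = b * eta6**op
    tail = 2.0 / op * b ** (-s) * math.exp(_log_upper_gamma_scaled(s, y) - y)
    return -math.log(core + tail)


def density_two(u, eta5: float, eta6: float, sigma: Union[float, SigmaGroup]):
    """Normalized two-parameter stationary marginal: Gaussian for
    ``|u| <= eta6``, stretched-exponential power-law envelope beyond.
    Bounded for all ``u``."""
    s = _sigma_value(sigma)
    if eta6 == 0.0:
        return density_one(u, eta5, s)
    op = 1.0 + eta5
    b = eta5 / (s * op)
    a_core = eta5 * eta6 ** (op - 2.0) / (2.0 * s)
    shift = b * eta6**op * (eta5 - 1.0) / 2.0
    logC = _density_two_lognorm(eta5, eta6, s)
    u = np.asarray(u, dtype=float)
    au = np.abs(u)
    with np.errstate(divide="ignore"):
        core = np.exp(logC + (eta5 - 1.0) * math.log(eta6) + shift - a_core * u**2)
        tail = np.exp(logC + (eta5 - 1.0) * np.log(np.maximum(au, 1e-300)) - b * au**op)
    out = np.where(au <= eta6, core, tail)
    return out if out.ndim else float(out)


def density(u, spec, sigma: Union[float, SigmaGroup]):
    """Stationary acceleration marginal for a nonlinearity spec (dispatch)."""
    from .nonlinearity import NonlinearityTwoParam

    if isinstance(spec, NonlinearityTwoParam):
        return density_two(u, spec.eta5, spec.eta6, sigma)
    return density_one(u, spec.eta5, sigma)


# ---------------------------------------------------------------------------
# velocity / auxiliary moments and general N
# ---------------------------------------------------------------------------


def vz_moments(params) -> tuple:
    """Closed-form (D, <V^2>, <Z^2>) of the N = 1 model:

    ``D = eta4^2/(2 eta1^2 eta2^2)``, ``<V^2> = eta4^2/(2 eta1 eta2 eta3)``,
    ``<Z^2> = eta4^2/(2 eta2)``.  Exact inverse of the linear fit.
    """
    eta = np.asarray(params.eta, dtype=float) if hasattr(params, "eta") else np.asarray(params, dtype=float)
    eta = eta.reshape(-1, 4)
    if eta.shape[0] != 1:
        raise ValidationError("vz_moments is defined for N = 1 parameter sets")
    e1, e2, e3, e4 = eta[0]
    D = e4**2 / (2.0 * e1**2 * e2**2)
    v2 = e4**2 / (2.0 * e1 * e2 * e3)
    z2 = e4**2 / (2.0 * e2)
    return D, v2, z2


def generalN_moments(
    etas5: Sequence[float],
    sigmas: Sequence[Union[float, SigmaGroup]],
    alphas: Sequence[float] = (1.0, 2.0, 4.0),
) -> dict:
    """Stationary moments of the summed acceleration of an N-component model.

    Each component contributes an independent symmetric one-parameter
    marginal, so odd moments vanish and

    ``<U^2> = sum_j <U_j^2>``,
    ``<U^4> = 3 <U^2>^2 + sum_j (<U_j^4> - 3 <U_j^2>^2)``,
    ``Kurt[U] = 3 + sum_j (<U_j^4> - 3 <U_j^2>^2) / <U^2>^2``.

    Returns a dict with per-component moments (``per_component[alpha]``,
    arrays of length N) and totals ``u2``, ``u4``, ``kurtosis``.
    """
    etas5 = [float(e) for e in etas5]
    sig = [_sigma_value(s) for s in sigmas]
    if len(etas5) != len(sig) or not etas5:
        raise ValidationError("etas5 and sigmas must have equal positive length")
    per = {
        float(a): np.array([abs_moment_one(a, e, s) for e, s in zip(etas5, sig)])
        for a in alphas
    }
    m2 = np.array([abs_moment_one(2.0, e, s) for e, s in zip(etas5, sig)])
    m4 = np.array([abs_moment_one(4.0, e, s) for e, s in zip(etas5, sig)])
    u2 = float(m2.sum())
    u4 = float(3.0 * u2**2 + (m4 - 3.0 * m2**2).sum())
    return {
        "per_component": per,
        "u2": u2,
        "u4": u4,
        "kurtosis": u4 / u2**2,
    }
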