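"""Moment-based parametrization of SCG models.

Every procedure here turns a :class:`~scgmd.stationary.MomentSummary`
estimated from trajectories into a full SCG parameter set, exploiting the
closed stationary theory:

* linear N = 1: four moments (D, <V^2>, <U^2>, <Z^2>) -> four rates,
  algebraically exact;
* one-parameter nonlinearity: the exponent from either the kurtosis or the
  <U^2>/<|U|>^2 ratio (1-D bracketed root-finds), the scale group from
  <U^2>;
* two-parameter nonlinearity: (kurtosis, ratio) -> (kappa1, kappa2) by a
  damped multistart Newton-type solve, then (eta5, eta6) and the scale group
  from <|U|>;
* general N with fixed per-component exponents: the two moment equations in
  the kappa_j = sigma_j^(2/(1+eta_j5)) variables, exact for N <= 2 and
  minimum-norm nonnegative for larger N.

All fits are validated by forward evaluation — the returned parameters
reproduce their input moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .errors import InfeasibleError, UnattainableError, ValidationError
from .nonlinearity import NonlinearityOneParam, NonlinearitySpec, NonlinearityTwoParam
from .stationary import (
    KappaPair,
    MomentSummary,
    SigmaGroup,
    abs_moment_one,
    kurtosis_one,
    kurtosis_two,
    log_F,
    ratio_one,
    ratio_two,
)

__all__ = [
    "LinearSCGParams",
    "NonlinearSCGParams",
    "fit_linear_N1",
    "fit_eta5_from_kurtosis",
    "fit_eta5_from_ratio",
    "fit_kappa",
    "kappa_to_eta",
    "sigma_constraint",
    "complete_fit",
    "fit_generalN_kappas",
    "FitResult",
    "fit_scg",
]

# bracketing window for the 1-D exponent root-finds (log-spaced)
_ETA5_LO, _ETA5_HI = 1e-3, 1e3


@dataclass(frozen=True)
class LinearSCGParams:
    """The 4N positive rates of the linear bath, rows ``(eta1..eta4)`` per
    component.  ``eta1`` couples the velocity into the acceleration drift
    (ps^-2), ``eta2`` is the auxiliary damping rate (ps^-1), ``eta3`` the
    acceleration-to-auxiliary coupling (ps^-2) and ``eta4`` the noise
    amplitude."""

    eta: np.ndarray

    def __post_init__(self) -> None:
        eta = np.atleast_2d(np.asarray(self.eta, dtype=float))
        if eta.ndim != 2 or eta.shape[1] != 4:
            raise ValidationError("eta must be an (N, 4) array")
        if not np.all(eta > 0):
            raise ValidationError("all rates eta_{j,k} must be positive")
        object.__setattr__(self, "eta", eta)

    @property
    def N(self) -> int:
        return self.eta.shape[0]

    def sigma(self, j: int = 0) -> float:
        """Scale group sigma_j = eta4^2/(2 eta2 eta3) of component j."""
        e = self.eta[j]
        return float(e[3] ** 2 / (2.0 * e[1] * e[2]))


@dataclass(frozen=True)
class NonlinearSCGParams:
    """Linear rates plus one nonlinearity spec per component."""

    linear: LinearSCGParams
    nonlinearity: tuple

    def __post_init__(self) -> None:
        nl = self.nonlinearity
        if isinstance(nl, (NonlinearityOneParam, NonlinearityTwoParam)):
            nl = (nl,)
        object.__setattr__(self, "nonlinearity", tuple(nl))
        if len(self.nonlinearity) != self.linear.N:
            raise ValidationError("one nonlinearity spec required per component")


# ---------------------------------------------------------------------------
# linear N = 1
# ---------------------------------------------------------------------------


def fit_linear_N1(m: MomentSummary) -> LinearSCGParams:
    """Exact four-moment fit of the linear N = 1 model:

    ``eta1 = u2/v2``, ``eta2 = (z2/D)(v2/u2)^2``, ``eta3 = z2/u2``,
    ``eta4 = sqrt(2/D) v2 z2 / u2``.
    """
    for name in ("D", "v2", "u2", "z2"):
        if getattr(m, name) is None:
            raise ValidationError(f"linear fit requires moment {name}")
    D, v2, u2, z2 = m.D, m.v2, m.u2, m.z2
    eta = np.array(
        [
            [
                u2 / v2,
                (z2 / D) * (v2 / u2) ** 2,
                z2 / u2,
                math.sqrt(2.0 / D) * v2 * z2 / u2,
            ]
        ]
    )
    return LinearSCGParams(eta)


# ---------------------------------------------------------------------------
# one-parameter exponent fits
# ---------------------------------------------------------------------------


def _invert_monotone(func, target: float, what: str) -> float:
    """Bracketed root-find of func(eta5) = target on log eta5; func must be
    strictly decreasing in eta5."""
    hi_val = func(_ETA5_LO)  # largest attainable
    lo_val = func(_ETA5_HI)  # smallest attainable
    if not (lo_val < target < hi_val):
        raise UnattainableError(
            f"{what} = {target} outside the attainable interval "
            f"({lo_val:.6g}, {hi_val:.6g}) for eta5 in [{_ETA5_LO}, {_ETA5_HI}]"
        )
    res = optimize.brentq(
        lambda x: func(math.exp(x)) - target,
        math.log(_ETA5_LO),
        math.log(_ETA5_HI),
        xtol=1e-14,
        rtol=8.9e-16,
    )
    eta5 = math.exp(res)
    if abs(func(eta5) - target) > 1e-10 * max(1.0, abs(target)):
        raise UnattainableError(f"root-find for {what} did not converge")
    return eta5


def fit_eta5_from_kurtosis(kurt: float) -> float:
    """Exponent whose one-parameter stationary kurtosis equals ``kurt``.
    Kurtosis is strictly decreasing in the exponent (3 at 1)."""
    return _invert_monotone(kurtosis_one, kurt, "kurtosis")


def fit_eta5_from_ratio(ratio: float) -> float:
    """Exponent whose <U^2>/<|U|>^2 equals ``ratio`` (pi/2 at exponent 1)."""
    return _invert_monotone(ratio_one, ratio, "moment ratio")


# ---------------------------------------------------------------------------
# two-parameter (kappa) fit
# ---------------------------------------------------------------------------


def _kappa_residual(x: np.ndarray, kurt: float, ratio: float) -> np.ndarray:
    k1 = math.exp(x[0])
    k2 = 1.0 / (1.0 + math.exp(-x[1]))  # logit^-1
    kp = KappaPair(k1, k2)
    return np.array(
        [
            math.log(kurtosis_two(kp)) - math.log(kurt),
            math.log(ratio_two(kp)) - math.log(ratio),
        ]
    )


def fit_kappa(kurt: float, ratio: float) -> KappaPair:
    """Solve {kurtosis(kappa) = kurt, ratio(kappa) = ratio} for the
    dimensionless pair of the two-parameter model.

    Damped Newton (scipy hybr) on (log kappa1, logit kappa2) with multistart
    from the one-parameter solution.  Raises if the residual norm cannot be
    brought below 1e-9.
    """
    if not (kurt > 1.0 and ratio > 1.0):
        raise UnattainableError("kurtosis and ratio must both exceed 1")
    # one-parameter starting point for kappa2
    try:
        k2_0 = 1.0 / (1.0 + fit_eta5_from_ratio(ratio))
    except UnattainableError:
        k2_0 = 0.5
    starts = [(k1, k2_0) for k1 in (1e-3, 0.1, 1.0)]
    starts += [(0.1, 0.3), (0.1, 0.7), (1.0, 0.5)]
    best = None
    for k1_0, k2s in starts:
        x0 = np.array([math.log(k1_0), math.log(k2s / (1.0 - k2s))])
        sol = optimize.root(
            _kappa_residual, x0, args=(kurt, ratio), method="hybr", tol=1e-13
        )
        k1 = math.exp(sol.x[0])
        k2 = 1.0 / (1.0 + math.exp(-sol.x[1]))
        kp = KappaPair(k1, k2)
        resid = math.hypot(kurtosis_two(kp) - kurt, ratio_two(kp) - ratio)
        if best is None or resid < best[0]:
            best = (resid, kp)
        if resid < 1e-9:
            return kp
    raise UnattainableError(
        f"kappa fit did not converge for kurtosis={kurt}, ratio={ratio}; "
        f"best residual {best[0]:.3g} at {best[1]}"
    )


def kappa_to_eta(kappa: KappaPair, absU: float) -> NonlinearityTwoParam:
    """Map the dimensionless pair back to the physical nonlinearity:
    ``eta5 = (1-kappa2)/kappa2`` and
    ``eta6 = <|U|> F(kappa1, kappa2, 0) / exp(kappa1)``."""
    if not (absU > 0):
        raise ValidationError("absU must be positive")
    eta5 = (1.0 - kappa.kappa2) / kappa.kappa2
    if kappa.kappa1 == 0.0:
        return NonlinearityTwoParam(eta5, 0.0)
    eta6 = absU * math.exp(
        log_F(kappa.kappa1, kappa.kappa2, 0.0) - kappa.kappa1
    )
    return NonlinearityTwoParam(eta5, eta6)


# ---------------------------------------------------------------------------
# scale group and completion
# ---------------------------------------------------------------------------


def sigma_constraint(
    nonlinearity: NonlinearitySpec,
    m: MomentSummary,
    kappa: KappaPair = None,
) -> SigmaGroup:
    """Scale group sigma = eta4^2/(2 eta2 eta3) fixed by the moment the fit
    matched.

    One-parameter: sigma such that <U^2>(eta5, sigma) = m.u2 —
    ``sigma = eta5/(1+eta5) (u2 / R2)^((1+eta5)/2)`` with ``R2`` the gamma
    ratio of the second absolute moment.

    Two-parameter: from kappa1's definition,
    ``sigma = eta5 eta6^(1+eta5) / (2 kappa1)``, which makes the <|U|>
    relation exact by construction.
    """
    if isinstance(nonlinearity, NonlinearityTwoParam) and nonlinearity.eta6 > 0:
        if kappa is None:
            raise ValidationError("two-parameter sigma needs the fitted KappaPair")
        e5, e6 = nonlinearity.eta5, nonlinearity.eta6
        return SigmaGroup(e5 * e6 ** (1.0 + e5) / (2.0 * kappa.kappa1))
    if m.u2 is None:
        raise ValidationError("one-parameter sigma needs m.u2")
    e5 = nonlinearity.eta5
    r2 = abs_moment_one(2.0, e5, 1.0)  # second moment at unit sigma
    return SigmaGroup((m.u2 / r2) ** ((1.0 + e5) / 2.0))


def complete_fit(
    m: MomentSummary,
    sigma: Union[float, SigmaGroup],
    nonlinearity: NonlinearitySpec,
) -> NonlinearSCGParams:
    """Complete an N = 1 nonlinear fit: given (D, <V^2>, <Z^2>) and the
    scale group sigma, recover the four bath rates

    ``eta1 = sigma/v2``, ``eta2 = z2 v2^2/(D sigma^2)``, ``eta3 = z2/sigma``,
    ``eta4 = sqrt(2/D) z2 v2 / sigma``,

    which reproduce (D, v2, z2) exactly and satisfy
    eta4^2/(2 eta2 eta3) = sigma.  With exponent 1 and sigma = <U^2> this is
    the linear fit.
    """
    for name in ("D", "v2", "z2"):
        if getattr(m, name) is None:
            raise ValidationError(f"complete_fit requires moment {name}")
    s = sigma.sigma if isinstance(sigma, SigmaGroup) else float(sigma)
    D, v2, z2 = m.D, m.v2, m.z2
    eta = np.array(
        [
            [
                s / v2,
                z2 * v2**2 / (D * s**2),
                z2 / s,
                math.sqrt(2.0 / D) * z2 * v2 / s,
            ]
        ]
    )
    return NonlinearSCGParams(LinearSCGParams(eta), (nonlinearity,))


# ---------------------------------------------------------------------------
# general N
# ---------------------------------------------------------------------------


def fit_generalN_kappas(
    u2: float, u4: float, etas5: Sequence[float]
) -> np.ndarray:
    """Solve the two-moment system for the per-component scale variables
    ``kappa_j = sigma_j^(2/(1+eta_j5))``:

    ``sum_j c1_j kappa_j = u2`` and ``sum_j c2_j kappa_j^2 = u4 - 3 u2^2``,

    where ``c1_j``/``c2_j`` follow from the per-component absolute-moment
    formula at unit scale.  N = 1 uses the first equation (the second is the
    kurtosis-consistency condition); N = 2 is solved exactly (quadratic after
    elimination); N > 2 returns the minimum-Euclidean-norm nonnegative
    solution.
    """
    etas5 = [float(e) for e in etas5]
    if not etas5:
        raise ValidationError("need at least one component")
    if not (u2 > 0 and u4 > 0):
        raise ValidationError("u2 and u4 must be positive")
    c1 = np.array([abs_moment_one(2.0, e, 1.0) for e in etas5])
    c4 = np.array([abs_moment_one(4.0, e, 1.0) for e in etas5])
    c2 = c4 - 3.0 * c1**2  # sign of the per-component excess kurtosis
    # snap round-off residue of exactly-Gaussian components to zero
    c2[np.abs(c2) < 1e-12 * (c4 + 3.0 * c1**2)] = 0.0
    excess = u4 - 3.0 * u2**2
    if abs(excess) < 1e-12 * (u4 + 3.0 * u2**2):
        excess = 0.0
    n = len(etas5)
    if n == 1:
        return np.array([u2 / c1[0]])
    if excess > 0 and np.all(c2 <= 0):
        raise InfeasibleError(
            "positive excess kurtosis cannot be matched: all components are "
            "platykurtic (eta5 >= 1)"
        )
    if excess < 0 and np.all(c2 >= 0):
        raise InfeasibleError(
            "negative excess kurtosis cannot be matched: all components are "
            "leptokurtic (eta5 <= 1)"
        )
    if n == 2:
        # kappa2 = (u2 - c1[0] k) / c1[1]; substitute into the quadratic
        A = c2[0] + c2[1] * (c1[0] / c1[1]) ** 2
        B = -2.0 * c2[1] * c1[0] * u2 / c1[1] ** 2
        C = c2[1] * (u2 / c1[1]) ** 2 - excess
        sols = []
        if A == 0.0:
            if B != 0.0:
                sols = [-C / B]
        else:
            disc = B * B - 4.0 * A * C
            scale = B * B + abs(4.0 * A * C)
            if disc >= -1e-12 * scale:
                r = math.sqrt(max(disc, 0.0))
                sols = [(-B + r) / (2.0 * A), (-B - r) / (2.0 * A)]
        cands = []
        for k1 in sols:
            k2 = (u2 - c1[0] * k1) / c1[1]
            if k1 >= -1e-12 and k2 >= -1e-12:
                cands.append(np.maximum([k1, k2], 0.0))
        if not cands:
            raise InfeasibleError(
                f"no nonnegative solution for u2={u2}, u4={u4}, etas5={etas5}"
            )
        return min(cands, key=lambda k: float(np.dot(k, k)))
    # N > 2: minimum-norm nonnegative solution of the underdetermined system
    scale = u2 / c1.sum()
    x0 = np.full(n, scale)
    cons = [
        {"type": "eq", "fun": lambda k: c1 @ k - u2},
        {"type": "eq", "fun": lambda k: c2 @ (k * k) - excess},
    ]
    res = optimize.minimize(
        lambda k: float(np.dot(k, k)),
        x0,
        jac=lambda k: 2.0 * k,
        bounds=[(0.0, None)] * n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    k = np.maximum(res.x, 0.0)
    ok = (
        abs(c1 @ k - u2) < 1e-8 * max(1.0, abs(u2))
        and abs(c2 @ (k * k) - excess) < 1e-8 * max(1.0, abs(excess), u2**2)
    )
    if not ok:
        raise InfeasibleError(
            f"general-N kappa solve failed: residuals "
            f"({c1 @ k - u2:.3g}, {c2 @ (k * k) - excess:.3g})"
        )
    return k


# ---------------------------------------------------------------------------
# convenience pipelines
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of an end-to-end fit: the nonlinearity, the scale group,
    the dimensionless pair (two-parameter procedure only), and — when the
    velocity/diffusion moments were supplied — the completed parameter
    set."""

    procedure: str
    nonlinearity: object
    sigma: Optional[SigmaGroup] = None
    kappa: Optional[KappaPair] = None
    params: Optional[NonlinearSCGParams] = None


def fit_scg(m: MomentSummary, procedure: str) -> FitResult:
    """End-to-end N = 1 fit.

    procedure:
      ``"linear"``               — four-moment linear fit (exponent 1);
      ``"one-param-kurtosis"``   — exponent from Kurt[U];
      ``"one-param-ratio"``      — exponent from <U^2>/<|U|>^2;
      ``"two-param"``            — (eta5, eta6) from (Kurt[U], ratio, <|U|>).

    The bath rates are completed (via the scale-group identities) whenever
    D, <V^2> and <Z^2> are all present; otherwise only the nonlinearity and
    scale group are returned.
    """
    if procedure == "linear":
        lin = fit_linear_N1(m)
        return FitResult(
            procedure, NonlinearityOneParam(1.0), SigmaGroup(m.u2),
            params=NonlinearSCGParams(lin, (NonlinearityOneParam(1.0),)),
        )
    kappa = None
    if procedure == "one-param-kurtosis":
        spec = NonlinearityOneParam(fit_eta5_from_kurtosis(m.kurtosis))
    elif procedure == "one-param-ratio":
        spec = NonlinearityOneParam(fit_eta5_from_ratio(m.ratio))
    elif procedure == "two-param":
        kappa = fit_kappa(m.kurtosis, m.ratio)
        spec = kappa_to_eta(kappa, m.absU)
    else:
        raise ValidationError(f"unknown fitting procedure {procedure!r}")
    sigma = sigma_constraint(spec, m, kappa)
    result = FitResult(procedure, spec, sigma, kappa)
    if m.D is not None and m.v2 is not None and m.z2 is not None:
        result.params = complete_fit(m, sigma, spec)
    return result
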