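"""Force-nonlinearity families of the stochastic coarse-grained (SCG) model.

The SCG model feeds the acceleration equation through an increasing function
``g`` applied to an auxiliary Ornstein-Uhlenbeck-like bath.  Two concrete
families are implemented:

* a one-parameter power law ``g(y) = |y|^(1/eta5) sign(y)`` whose stationary
  acceleration distribution is a symmetric stretched-exponential with kurtosis
  controlled solely by ``eta5`` (Gaussian at ``eta5 = 1``, leptokurtic below,
  platykurtic above), and
* a two-parameter regularisation of the same power law which is linear inside
  an acceleration scale ``eta6``, removing both the singular drift (for
  ``eta5 > 1``) and the unbounded stationary density at zero (for
  ``eta5 < 1``).  At ``eta6 = 0`` it reduces to the one-parameter family.

The dynamics and the stationary theory never need ``g`` itself at arbitrary
arguments; they need the drift factor ``g'(g^{-1}(u))`` and the potential term
``G(g^{-1}(u))`` where ``G`` is the antiderivative of ``g``.  Both are
implemented as the explicit closed forms, continuous in ``u``.

The companion map ``h`` acting on the auxiliary variable is fixed to the
identity throughout the package; a non-identity ``h`` would enter only through
its antiderivative ``H(z)`` in the stationary density, replacing the Gaussian
``z``-factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import SingularDriftError, ValidationError

__all__ = [
    "NonlinearityOneParam",
    "NonlinearityTwoParam",
    "NonlinearitySpec",
    "eval_g_one",
    "eval_g_two",
    "eval_gprime_ginv_one",
    "eval_gprime_ginv_two",
    "eval_gprime_ginv",
    "eval_G_ginv",
]


@dataclass(frozen=True)
class NonlinearityOneParam:
    """Power-law nonlinearity ``g(y) = |y|^(1/eta5) sign(y)``.

    Parameters
    ----------
    eta5
        Dimensionless positive exponent.  ``eta5 = 1`` recovers the linear
        (Gaussian) model.
    """

    eta5: float

    def __post_init__(self) -> None:
        if not (self.eta5 > 0):
            raise ValidationError(f"eta5 must be positive, got {self.eta5}")

    @property
    def singular_drift(self) -> bool:
        """True when the drift factor |u|^(1-eta5)/eta5 diverges at u = 0."""
        return self.eta5 > 1


@dataclass(frozen=True)
class NonlinearityTwoParam:
    """Piecewise nonlinearity: linear inside, power law outside.

    Parameters
    ----------
    eta5
        Dimensionless positive exponent of the outer power-law branch.
    eta6
        Acceleration scale (nm ps^-2) separating the linear core
        (``|u| <= eta6``) from the power-law tail.  ``eta6 = 0`` collapses to
        :class:`NonlinearityOneParam`.
    """

    eta5: float
    eta6: float

    def __post_init__(self) -> None:
        if not (self.eta5 > 0):
            raise ValidationError(f"eta5 must be positive, got {self.eta5}")
        if not (self.eta6 >= 0):
            raise ValidationError(f"eta6 must be nonnegative, got {self.eta6}")


NonlinearitySpec = Union[NonlinearityOneParam, NonlinearityTwoParam]


def eval_g_one(y, spec: NonlinearityOneParam):
    """``g(y) = |y|^(1/eta5) sign(y)`` — odd, strictly increasing off zero."""
    y = np.asarray(y, dtype=float)
    out = np.abs(y) ** (1.0 / spec.eta5) * np.sign(y)
    return out if out.ndim else float(out)


def eval_g_two(y, spec: NonlinearityTwoParam):
    """Two-parameter ``g``: flat core, linear shoulder, power-law tail.

    The flat region ``|y| <= eta6^eta5 (1 - eta5)`` exists only for
    ``eta5 < 1``; the dynamics never evaluate ``g`` there (only the composed
    maps below are used), but the function is provided for completeness and
    for quadrature oracles.
    """
    e5, e6 = spec.eta5, spec.eta6
    if e6 == 0.0:
        return eval_g_one(y, NonlinearityOneParam(e5))
    y = np.asarray(y, dtype=float)
    ay = np.abs(y)
    t_flat = e6**e5 * (1.0 - e5)  # negative for eta5 > 1: flat region empty
    t_lin = e6**e5
    out = np.where(
        ay <= t_flat,
        0.0,
        np.where(
            ay <= t_lin,
            (e6 * (1.0 - 1.0 / e5) + e6 ** (1.0 - e5) / e5 * ay) * np.sign(y),
            ay ** (1.0 / e5) * np.sign(y),
        ),
    )
    return out if out.ndim else float(out)


def eval_gprime_ginv_one(u, spec: NonlinearityOneParam):
    """Drift factor ``g'(g^{-1}(u)) = |u|^(1-eta5) / eta5``.

    At ``u = 0`` the continuous limit is returned for ``eta5 <= 1``; for
    ``eta5 > 1`` the factor diverges and :class:`SingularDriftError` is
    raised, signalling that the two-parameter family must be used instead.
    """
    e5 = spec.eta5
    u = np.asarray(u, dtype=float)
    if e5 > 1 and np.any(u == 0.0):
        raise SingularDriftError(
            "drift factor |u|^(1-eta5)/eta5 diverges at u=0 for eta5 > 1; "
            "use NonlinearityTwoParam"
        )
    with np.errstate(divide="ignore"):
        out = np.abs(u) ** (1.0 - e5) / e5
    # |0|^0 == 1 in numpy, which is the right eta5 == 1 limit; for eta5 < 1
    # the power evaluates to 0 at u = 0 already.
    return out if out.ndim else float(out)


def eval_gprime_ginv_two(u, spec: NonlinearityTwoParam):
    """Drift factor of the two-parameter family, continuous for all ``u``:

    ``eta6^(1-eta5)/eta5`` for ``|u| <= eta6``, else ``|u|^(1-eta5)/eta5``.
    """
    e5, e6 = spec.eta5, spec.eta6
    if e6 == 0.0:
        return eval_gprime_ginv_one(u, NonlinearityOneParam(e5))
    u = np.asarray(u, dtype=float)
    au = np.abs(u)
    with np.errstate(divide="ignore"):
        out = np.where(au <= e6, e6 ** (1.0 - e5), au ** (1.0 - e5)) / e5
    return out if out.ndim else float(out)


def eval_gprime_ginv(u, spec: NonlinearitySpec):
    """Dispatch the drift factor on the nonlinearity family."""
    if isinstance(spec, NonlinearityTwoParam):
        return eval_gprime_ginv_two(u, spec)
    return eval_gprime_ginv_one(u, spec)


def eval_G_ginv(u, spec: NonlinearitySpec):
    """Potential term ``G(g^{-1}(u))`` with ``G(y) = int_0^y g``.

    One-parameter family: ``eta5/(1+eta5) |u|^(1+eta5)``.  Two-parameter
    family: quadratic core matched continuously to the shifted power-law
    tail.  Even, nonnegative, zero at ``u = 0``, increasing in ``|u|``.
    """
    e5 = spec.eta5
    u = np.asarray(u, dtype=float)
    au = np.abs(u)
    if isinstance(spec, NonlinearityTwoParam) and spec.eta6 > 0.0:
        e6 = spec.eta6
        inner = 0.5 * e5 * e6 ** (e5 - 1.0) * u**2
        outer = (
            e5 * (e5 - 1.0) * e6 ** (1.0 + e5) / (2.0 * (1.0 + e5))
            + e5 / (1.0 + e5) * au ** (1.0 + e5)
        )
        out = np.where(au <= e6, inner, outer)
    else:
        out = e5 / (1.0 + e5) * au ** (1.0 + e5)
    return out if out.ndim else float(out)
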