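"""Generalized-Langevin view of the linear SCG model.

Eliminating the auxiliary pair (U, Z) of each bath component turns the
velocity equation into a generalized Langevin equation (GLE) with an
explicit exponential/trigonometric memory kernel

``K_j(tau) = eta1 e^(-eta2 tau/2) (cosh(mu tau) + eta2/(2 mu) sinh(mu tau))``

with ``mu^2 = eta2^2/4 - eta3`` (oscillatory kernels for imaginary ``mu``),
a fluctuation-dissipation noise amplitude equal to the stationary velocity
variance, and — for N = 1 — a closed normalized velocity autocorrelation
function (VACF) obtained by partial-fraction inversion of the Laplace
transform:

``chi(tau)/chi(0) = sum_i c_i exp(a_i tau)``

where ``a_i`` are the roots of ``s^3 + eta2 s^2 + (eta1+eta3) s + eta1 eta2``
and ``sum_i c_i = 1``.  For N > 1 the kernel is the sum of component kernels;
the VACF is then obtained by simulation.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
import warnings

import numpy as np

from .errors import ValidationError

__all__ = [
    "KernelComponent",
    "VACFDecomposition",
    "memory_kernel",
    "kernel_sum",
    "fdt_amplitude",
    "vacf_decompose",
    "vacf_eval",
]

# below this (relative) size of mu^2 the degenerate-limit kernel is used
_MU2_TOL = 1e-12


@dataclass(frozen=True)
class KernelComponent:
    """One bath component (eta1, eta2, eta3) of the memory kernel."""

    eta1: float
    eta2: float
    eta3: float

    def __post_init__(self) -> None:
        if not (self.eta1 > 0 and self.eta2 > 0 and self.eta3 > 0):
            raise ValidationError("kernel rates must be positive")

    @property
    def mu2(self) -> float:
        """Discriminant eta2^2/4 - eta3 (mu real if positive)."""
        return self.eta2**2 / 4.0 - self.eta3

    @property
    def eigenvalues(self) -> tuple:
        """lambda_{1,2} = -eta2/2 +/- mu; real parts always negative."""
        mu = cmath.sqrt(complex(self.mu2))
        l1 = -self.eta2 / 2.0 + mu
        l2 = -self.eta2 / 2.0 - mu
        assert l1.real < 0 and l2.real < 0
        return l1, l2


def memory_kernel(tau, comp: KernelComponent):
    """Memory kernel K(tau) of one component, real for any sign of mu^2.

    ``K(0) = eta1``; decaying for real mu, oscillatory (sign-changing) for
    imaginary mu; the degenerate case eta2^2 = 4 eta3 is the analytic limit
    ``eta1 e^(-eta2 tau/2)(1 + eta2 tau/2)``.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValidationError("tau must be >= 0")
    e1, e2 = comp.eta1, comp.eta2
    m2 = comp.mu2
    envelope = np.exp(-e2 * tau / 2.0)
    if abs(m2) < _MU2_TOL * comp.eta3:
        out = e1 * envelope * (1.0 + e2 * tau / 2.0)
    elif m2 > 0:
        mu = math.sqrt(m2)
        out = e1 * envelope * (np.cosh(mu * tau) + e2 / (2.0 * mu) * np.sinh(mu * tau))
    else:
        w = math.sqrt(-m2)
        out = e1 * envelope * (np.cos(w * tau) + e2 / (2.0 * w) * np.sin(w * tau))
    return out if out.ndim else float(out)


def kernel_sum(tau, params):
    """Total memory kernel of an N-component linear model,
    ``K(tau) = sum_j K_j(tau)``; ``K(0) = sum_j eta_{j,1}``."""
    eta = np.atleast_2d(np.asarray(params.eta if hasattr(params, "eta") else params, dtype=float))
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau, dtype=float)
    for row in eta:
        out = out + memory_kernel(tau, KernelComponent(row[0], row[1], row[2]))
    return out if out.ndim else float(out)


def fdt_amplitude(comp: KernelComponent, eta4: float) -> float:
    """Fluctuation-dissipation amplitude ``eta4^2/(2 eta1 eta2 eta3)``:
    the noise autocorrelation is this amplitude times K(t2 - t1), and it
    equals the stationary velocity variance <V^2>."""
    if not (eta4 > 0):
        raise ValidationError("eta4 must be positive")
    return eta4**2 / (2.0 * comp.eta1 * comp.eta2 * comp.eta3)


@dataclass(frozen=True)
class VACFDecomposition:
    """Roots ``a_i`` and partial-fraction coefficients ``c_i`` of the
    normalized VACF ``chi(tau)/chi(0) = sum c_i exp(a_i tau)``."""

    roots: np.ndarray
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.roots, dtype=complex)
        c = np.asarray(self.coeffs, dtype=complex)
        if r.shape != (3,) or c.shape != (3,):
            raise ValidationError("expected exactly three roots/coefficients")
        object.__setattr__(self, "roots", r)
        object.__setattr__(self, "coeffs", c)


def vacf_decompose(eta1: float, eta2: float, eta3: float) -> VACFDecomposition:
    """Partial-fraction decomposition of the VACF Laplace transform
    ``(s^2 + eta2 s + eta3) / (s^3 + eta2 s^2 + (eta1+eta3) s + eta1 eta2)``.

    Roots are taken from the companion-matrix eigenvalues (robust for the
    well-separated cubics arising from positive rates); conjugate pairs are
    symmetrized so the evaluated VACF is exactly real.  Near-repeated roots
    are perturbed slightly with a warning.
    """
    if not (eta1 > 0 and eta2 > 0 and eta3 > 0):
        raise ValidationError("rates must be positive")
    poly = np.array([1.0, eta2, eta1 + eta3, eta1 * eta2])
    roots = np.roots(poly)  # companion-matrix eigenvalues
    if np.any(roots.real >= 0):
        raise ValidationError(
            f"VACF cubic has a root with nonnegative real part: {roots}"
        )
    # symmetrize conjugate pairs (order: real root first if unique)
    order = np.argsort(np.abs(roots.imag))
    roots = roots[order]
    if abs(roots[1].imag) > 0 or abs(roots[2].imag) > 0:
        re = 0.5 * (roots[1].real + roots[2].real)
        im = 0.5 * (abs(roots[1].imag) + abs(roots[2].imag))
        roots[1] = complex(re, im)
        roots[2] = complex(re, -im)
        roots[0] = complex(roots[0].real, 0.0)
    scale = np.max(np.abs(roots))
    for i in range(3):
        for k in range(i + 1, 3):
            if abs(roots[i] - roots[k]) < 1e-9 * scale:
                warnings.warn(
                    "near-repeated VACF roots; perturbing for partial fractions",
                    RuntimeWarning,
                )
                roots[k] += 1e-8 * scale
    dpoly = np.array([3.0, 2.0 * eta2, eta1 + eta3])
    coeffs = np.array(
        [
            (a**2 + eta2 * a + eta3) / np.polyval(dpoly, a)
            for a in roots
        ]
    )
    return VACFDecomposition(roots, coeffs)


def vacf_eval(decomp: VACFDecomposition, tau):
    """Normalized VACF ``sum_i c_i exp(a_i tau)``; real, equal to 1 at 0."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValidationError("tau must be >= 0")
    out = np.zeros(tau.shape, dtype=complex)
    for a, c in zip(decomp.roots, decomp.coeffs):
        out = out + c * np.exp(a * tau)
    assert np.max(np.abs(out.imag)) < 1e-10
    real = out.real
    return real if real.ndim else float(real)
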