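"""Time-stepping simulators and trajectory estimators for the SCG models.

Three coordinates are propagated with independent Wiener drives; noise enters
only the auxiliary (Z) equations with amplitude ``eta4``.  The integrator is
Euler-Maruyama (the noise is additive, so this is also Milstein); the linear
model additionally has an exact Ornstein-Uhlenbeck propagator used as a
validation oracle.  Estimators reproduce the moment-averaging convention used
for tagged-particle statistics: every acceleration moment is the average of
the three per-coordinate time averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numba import njit
from scipy.linalg import expm

from .errors import SingularDriftError, UnstableStepError, ValidationError
from .nonlinearity import NonlinearityOneParam, NonlinearityTwoParam
from .parametrize import LinearSCGParams, NonlinearSCGParams
from .stationary import MomentSummary

__all__ = [
    "SCGTrajectory",
    "simulate_bd",
    "simulate",
    "simulate_linear_exact",
    "estimate_moments",
    "estimate_vacf",
    "estimate_diffusion",
    "DiffusionEstimate",
]

_GUARD = 1e8  # overflow guard on any state component
_CHUNK = 1 << 20  # steps per noise block


@dataclass
class SCGTrajectory:
    """Recorded (thinned) SCG state history.

    Arrays are indexed ``[sample, coordinate]`` (X, V) and
    ``[sample, component, coordinate]`` (U, Z).  ``dt`` is the recording
    interval (integration step times the thinning factor)."""

    dt: float
    times: np.ndarray
    X: np.ndarray
    V: np.ndarray
    U: np.ndarray
    Z: np.ndarray
    seed: Optional[int]
    burn_in: int
    dt_step: float

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    @property
    def N(self) -> int:
        return self.U.shape[1]

    def total_acceleration(self) -> np.ndarray:
        """Particle acceleration U_i = sum_j U_{j,i}, shape (n, 3)."""
        return self.U.sum(axis=1)


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------


def simulate_bd(D: float, dt: float, n_steps: int, seed: int) -> np.ndarray:
    """Pure-diffusion (Brownian dynamics) path: positions (n_steps+1, 3).

    Increments are exact Gaussians sqrt(2 D dt) xi — no discretization error.
    """
    if D < 0 or dt <= 0:
        raise ValidationError("need D >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_steps, 3)) * math.sqrt(2.0 * D * dt)
    out = np.empty((n_steps + 1, 3))
    out[0] = 0.0
    np.cumsum(steps, axis=0, out=out[1:])
    return out


@njit(cache=True)
def _scg_chunk(
    x, v, u, z, eta, e5, e6, mode, dt, sqdt, noise,
    step0, burn_in, thin, outX, outV, outU, outZ,
):
    """Advance the (3-coordinate, N-component) SCG state over one noise
    block, recording every ``thin``-th post-burn-in step.  Returns -1 on
    success or the offending step index on overflow."""
    nsteps = noise.shape[0]
    N = eta.shape[0]
    for k in range(nsteps):
        for i in range(3):
            du_sum = 0.0
            for j in range(N):
                du_sum += u[j, i]
            # increments from the current state (Euler-Maruyama)
            x[i] += v[i] * dt
            vnew = v[i] + du_sum * dt
            for j in range(N):
                if mode[j] == 0:
                    gp = 1.0
                else:
                    au = abs(u[j, i])
                    if mode[j] == 2 and au <= e6[j]:
                        gp = e6[j] ** (1.0 - e5[j]) / e5[j]
                    else:
                        gp = au ** (1.0 - e5[j]) / e5[j]
                du = (-eta[j, 0] * v[i] + z[j, i]) * gp * dt
                dz = (
                    -(eta[j, 1] * z[j, i] + eta[j, 2] * u[j, i]) * dt
                    + eta[j, 3] * sqdt * noise[k, j, i]
                )
                u[j, i] += du
                z[j, i] += dz
                if abs(u[j, i]) > _GUARD or abs(z[j, i]) > _GUARD:
                    return step0 + k
            v[i] = vnew
            if abs(v[i]) > _GUARD:
                return step0 + k
        s = step0 + k
        if s >= burn_in and (s - burn_in) % thin == 0:
            idx = (s - burn_in) // thin
            if idx < outX.shape[0]:
                for i in range(3):
                    outX[idx, i] = x[i]
                    outV[idx, i] = v[i]
                    for j in range(N):
                        outU[idx, j, i] = u[j, i]
                        outZ[idx, j, i] = z[j, i]
    return -1


def _unpack_params(params):
    """(eta, e5, e6, mode) arrays from a Linear/NonlinearSCGParams."""
    if isinstance(params, NonlinearSCGParams):
        eta = params.linear.eta
        N = params.linear.N
        e5 = np.ones(N)
        e6 = np.zeros(N)
        mode = np.zeros(N, dtype=np.int64)
        for j, spec in enumerate(params.nonlinearity):
            if isinstance(spec, NonlinearityTwoParam) and spec.eta6 > 0:
                mode[j] = 2
                e5[j] = spec.eta5
                e6[j] = spec.eta6
            else:
                eta5 = spec.eta5
                if eta5 == 1.0:
                    mode[j] = 0
                else:
                    if eta5 > 1.0 and not (
                        isinstance(spec, NonlinearityTwoParam) and spec.eta6 > 0
                    ):
                        raise SingularDriftError(
                            "one-parameter nonlinearity with eta5 > 1 cannot be "
                            "simulated (drift diverges at U = 0); use the "
                            "two-parameter family"
                        )
                    mode[j] = 1
                    e5[j] = eta5
        return np.asarray(eta, float), e5, e6, mode
    if isinstance(params, LinearSCGParams):
        N = params.N
        return (
            np.asarray(params.eta, float),
            np.ones(N),
            np.zeros(N),
            np.zeros(N, dtype=np.int64),
        )
    raise ValidationError(f"unsupported parameter object {type(params)!r}")


def _relaxation_times(eta: np.ndarray) -> np.ndarray:
    """Characteristic times of the linear part of each component."""
    ts = []
    for e1, e2, e3, _ in eta:
        ts += [1.0 / e2, e3**-0.5, e1**-0.5, e3 / (e1 * e2)]
    return np.array(ts)


def default_dt(params) -> float:
    """Step heuristic: 1% of the fastest linear relaxation time."""
    eta, _, _, _ = _unpack_params(params)
    return 0.01 * float(np.min(_relaxation_times(eta)))


def simulate(
    params: Union[LinearSCGParams, NonlinearSCGParams],
    n_steps: int,
    dt: Optional[float] = None,
    seed: int = 0,
    burn_in: Optional[int] = None,
    thin: int = 1,
) -> SCGTrajectory:
    """Euler-Maruyama trajectory of the linear or nonlinear SCG model.

    Parameters
    ----------
    n_steps
        Post-burn-in integration steps.
    dt
        Integration step (ps); default 1% of the fastest linear relaxation
        time of the parameter set.  Steps above 20% of that time are refused
        as unstable.
    burn_in
        Steps discarded before recording; default spans ten times the
        slowest relaxation time.  Initial condition is the origin.
    thin
        Record every ``thin``-th step.
    """
    eta, e5, e6, mode = _unpack_params(params)
    times_relax = _relaxation_times(eta)
    if dt is None:
        dt = 0.01 * float(times_relax.min())
    if dt > 0.2 * float(times_relax.min()):
        raise ValidationError(
            f"dt={dt} exceeds the stability bound "
            f"{0.2 * float(times_relax.min()):.3g} ps"
        )
    if burn_in is None:
        burn_in = int(math.ceil(10.0 * float(times_relax.max()) / dt))
    if thin < 1:
        raise ValidationError("thin must be >= 1")
    N = eta.shape[0]
    total = burn_in + n_steps
    n_rec = (n_steps + thin - 1) // thin
    outX = np.empty((n_rec, 3))
    outV = np.empty((n_rec, 3))
    outU = np.empty((n_rec, N, 3))
    outZ = np.empty((n_rec, N, 3))
    x = np.zeros(3)
    v = np.zeros(3)
    # U starts at its typical stationary magnitude sqrt(sigma_j): the origin
    # is a degenerate (absorbing) point of the one-parameter drift, whose
    # factor |U|^(1-eta5) vanishes there.
    sig = eta[:, 3] ** 2 / (2.0 * eta[:, 1] * eta[:, 2])
    u = np.repeat(np.sqrt(sig)[:, None], 3, axis=1)
    z = np.zeros((N, 3))
    rng = np.random.default_rng(seed)
    sqdt = math.sqrt(dt)
    step0 = 0
    while step0 < total:
        nblk = min(_CHUNK, total - step0)
        noise = rng.standard_normal((nblk, N, 3))
        bad = _scg_chunk(
            x, v, u, z, eta, e5, e6, mode, dt, sqdt, noise,
            step0, burn_in, thin, outX, outV, outU, outZ,
        )
        if bad >= 0:
            raise UnstableStepError(f"state overflow at integration step {bad}")
        step0 += nblk
    times = (np.arange(n_rec) * thin) * dt
    return SCGTrajectory(
        dt=dt * thin, times=times, X=outX, V=outV, U=outU, Z=outZ,
        seed=seed, burn_in=burn_in, dt_step=dt,
    )


def simulate_linear_exact(
    params: LinearSCGParams,
    n_steps: int,
    dt: float,
    seed: int = 0,
    burn_in: int = 0,
) -> SCGTrajectory:
    """Exact Gaussian propagator for the linear N = 1 model (validation
    oracle for the Euler-Maruyama path; not the default integrator).

    The (V, U, Z) subsystem is an Ornstein-Uhlenbeck process; the one-step
    transition mean is ``e^(A dt)`` and its covariance comes from the Van
    Loan block-exponential construction.  Positions are accumulated with the
    trapezoidal velocity integral.
    """
    if params.N != 1:
        raise ValidationError("exact propagator implemented for N = 1 only")
    e1, e2, e3, e4 = params.eta[0]
    A = np.array([[0.0, 1.0, 0.0], [-e1, 0.0, 1.0], [0.0, -e3, -e2]])
    LLt = np.zeros((3, 3))
    LLt[2, 2] = e4**2
    # Van Loan: exp([[ -A, LLt ], [0, A^T]] dt) -> M12, M22; cov = M22^T M12
    blk = np.zeros((6, 6))
    blk[:3, :3] = -A
    blk[:3, 3:] = LLt
    blk[3:, 3:] = A.T
    eb = expm(blk * dt)
    Phi = eb[3:, 3:].T  # = e^{A dt}
    cov = Phi @ eb[:3, 3:]
    cov = 0.5 * (cov + cov.T)
    Lchol = np.linalg.cholesky(cov + 1e-300 * np.eye(3))
    rng = np.random.default_rng(seed)
    total = burn_in + n_steps
    y = np.zeros((3, 3))  # state rows (V,U,Z) x coordinates
    outX = np.zeros((n_steps, 3))
    outV = np.empty((n_steps, 3))
    outU = np.empty((n_steps, 1, 3))
    outZ = np.empty((n_steps, 1, 3))
    x = np.zeros(3)
    for s in range(total):
        xi = Lchol @ rng.standard_normal((3, 3))
        v_old = y[0].copy()
        y = Phi @ y + xi
        x = x + 0.5 * (v_old + y[0]) * dt
        if s >= burn_in:
            idx = s - burn_in
            outX[idx] = x
            outV[idx] = y[0]
            outU[idx, 0] = y[1]
            outZ[idx, 0] = y[2]
    times = np.arange(n_steps) * dt
    return SCGTrajectory(
        dt=dt, times=times, X=outX, V=outV, U=outU, Z=outZ,
        seed=seed, burn_in=burn_in, dt_step=dt,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _block_se(series: np.ndarray, n_blocks: int) -> float:
    """Block-bootstrap standard error of the mean of a (possibly
    multi-column) correlated series; columns are pooled."""
    n = series.shape[0]
    block = n // n_blocks
    means = np.array(
        [series[i * block : (i + 1) * block].mean() for i in range(n_blocks)]
    )
    rng = np.random.default_rng(12345)
    boot = rng.choice(means, size=(200, n_blocks), replace=True).mean(axis=1)
    return float(boot.std(ddof=1))


def estimate_moments(traj, n_blocks: int = 50) -> MomentSummary:
    """Time-averaged moment summary of a trajectory, pooling the three
    coordinates (the per-coordinate averages are averaged, which for equal
    sample counts equals the pooled mean).  Standard errors are block
    bootstrap over contiguous time blocks."""
    U = traj.total_acceleration() if hasattr(traj, "total_acceleration") else np.asarray(traj)
    V = getattr(traj, "V", None)
    Z = getattr(traj, "Z", None)
    n = U.shape[0]
    n_blocks = min(n_blocks, n)
    if n_blocks < 10:
        raise ValidationError("trajectory shorter than 10 blocks")
    absU = np.abs(U)
    m = MomentSummary(
        absU=float(absU.mean()),
        u2=float((U**2).mean()),
        u4=float((U**4).mean()),
        v2=float((V**2).mean()) if V is not None else None,
        z2=float((Z**2).mean()) if Z is not None else None,
    )
    m.se = {
        "absU": _block_se(absU.reshape(n, -1).mean(axis=1), n_blocks),
        "u2": _block_se((U**2).reshape(n, -1).mean(axis=1), n_blocks),
        "u4": _block_se((U**4).reshape(n, -1).mean(axis=1), n_blocks),
    }
    if V is not None:
        m.se["v2"] = _block_se((V**2).reshape(n, -1).mean(axis=1), n_blocks)
    if Z is not None:
        m.se["z2"] = _block_se((Z**2).reshape(n, -1).mean(axis=1), n_blocks)
    return m


def _acorr_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-normalized autocorrelation sum_t x_t x_{t+l} / (n - l)."""
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft, axis=0)
    acf = np.fft.irfft(f * np.conj(f), nfft, axis=0)[: max_lag + 1]
    counts = (n - np.arange(max_lag + 1)).reshape(-1, *([1] * (x.ndim - 1)))
    return acf / counts


def estimate_vacf(traj, max_lag: int):
    """Normalized velocity autocorrelation chi(tau)/chi(0), FFT-based and
    pooled over the three coordinates.  Returns (lags_ps, vacf)."""
    V = traj.V
    max_lag = int(min(max_lag, V.shape[0] - 1))
    acf = _acorr_fft(V, max_lag).mean(axis=1)
    return traj.dt * np.arange(max_lag + 1), acf / acf[0]


@dataclass
class DiffusionEstimate:
    """Diffusion constant from the MSD slope, with the VACF-integral
    cross-check (the two agree for a stationary velocity process)."""

    D_msd: float
    D_vacf: float

    @property
    def D(self) -> float:
        return self.D_msd


def _msd_fft(X: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-coordinate-averaged mean-squared displacement via FFT."""
    n = X.shape[0]
    sq = (X**2).sum(axis=1)
    s2 = _acorr_fft(X, max_lag).sum(axis=1) if X.ndim > 1 else _acorr_fft(X, max_lag)
    # MSD(l) = <|x_{t+l}|^2 + |x_t|^2> - 2<x_t . x_{t+l}>
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    msd = np.empty(max_lag + 1)
    for l in range(max_lag + 1):
        head = csum[n - l] - csum[0]
        tail = csum[n] - csum[l]
        msd[l] = (head + tail) / (n - l) - 2.0 * s2[l]
    return msd / X.shape[1]  # per coordinate


def estimate_diffusion(traj, fit_window: Optional[tuple] = None) -> DiffusionEstimate:
    """Diffusion constant of a trajectory.

    The primary estimate is the slope of a linear fit MSD(t) = 2 D t over a
    window in the diffusive regime (by default 10-100 velocity correlation
    times, capped at a quarter of the trajectory); the cross-check integrates
    the unnormalized VACF.
    """
    from scipy.ndimage import maximum_filter1d

    n = traj.X.shape[0]
    max_lag = n // 2
    lags, vacf = estimate_vacf(traj, max_lag=min(max_lag, n - 1))
    chi0 = float((traj.V**2).mean())
    # integrate chi only over the correlated window: past it the estimator
    # contributes pure noise.  The window ends where the moving-max envelope
    # of |chi|/chi(0) falls below 2% (robust to oscillatory VACFs).
    unnorm = vacf * chi0
    width = max(5, len(vacf) // 200)
    env = maximum_filter1d(np.abs(vacf), size=width)
    below = np.nonzero(env < 0.02)[0]
    cut = int(below[0]) if below.size else len(vacf) - 1
    cut = max(cut, 2)
    D_vacf = float(np.trapezoid(unnorm[: cut + 1], dx=traj.dt))
    tau_c = max(D_vacf / chi0, traj.dt)
    if fit_window is None:
        t_lo = 10.0 * tau_c
        t_hi = min(100.0 * tau_c, 0.25 * n * traj.dt)
    else:
        t_lo, t_hi = fit_window
    l_lo = max(1, int(t_lo / traj.dt))
    l_hi = max(l_lo + 2, int(t_hi / traj.dt))
    msd = _msd_fft(traj.X, min(l_hi, n - 1))
    ls = np.arange(l_lo, min(l_hi, n - 1) + 1)
    slope = np.polyfit(ls * traj.dt, msd[ls], 1)[0]
    return DiffusionEstimate(D_msd=float(slope / 2.0), D_vacf=D_vacf)
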