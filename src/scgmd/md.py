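"""Lennard-Jones argon NVT molecular dynamics fixture.

A compact all-atom MD engine producing the tagged-particle velocity and
acceleration statistics that the SCG fitting procedures consume: 512 argon
atoms (epsilon/k_B = 120 K, sigma = 0.34 nm, m = 39.948 u) in a cubic
periodic box of side 2.91 nm at T = 94.4 K, integrated with velocity Verlet
and a single Nose-Hoover thermostat.

Units are nm / ps / u / K throughout; with these, 1 u nm^2 ps^-2 = 1 kJ/mol
and k_B = 8.314462618e-3 nm^2 u ps^-2 K^-1.  Accelerations (nm ps^-2) are
forces divided by the atomic mass, so their distribution is the force
distribution up to a constant factor.

Pair interactions use the minimum-image convention with truncated
(unshifted) forces; the reported potential is shifted by its cutoff value
so the conserved quantity stays continuous.  The O(N^2) pair loop is
JIT-compiled, which is entirely adequate at N = 512.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .errors import UnstableStepError, ValidationError
from .stationary import MomentSummary

__all__ = [
    "KB",
    "MDConfig",
    "MDTrajectory",
    "lj_forces",
    "nvt_step",
    "run_md",
    "md_moment_summary",
    "min_pair_distance",
    "write_xyz",
]

KB = 8.314462618e-3  # nm^2 u ps^-2 K^-1


@dataclass(frozen=True)
class MDConfig:
    """Simulation parameters of the liquid-argon fixture.

    Defaults reproduce the reference state point: N = 512 LJ atoms,
    box 2.91 nm (number density 20.8 nm^-3), T = 94.4 K.
    ``thermostat_tau = None`` disables the thermostat (NVE).
    """

    n_atoms: int = 512
    box_side: float = 2.91  # nm
    eps_over_kB: float = 120.0  # K
    sigma_lj: float = 0.34  # nm
    temperature: float = 94.4  # K
    mass: float = 39.948  # u
    dt: float = 0.002  # ps
    cutoff: float = 1.4  # nm
    thermostat_tau: Optional[float] = 0.2  # ps; None -> NVE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff >= self.box_side / 2.0:
            raise ValidationError(
                f"cutoff {self.cutoff} must be below half the box side "
                f"{self.box_side / 2.0} for the minimum-image convention"
            )
        if not (0 < self.dt <= 0.004):
            raise ValidationError("dt must be in (0, 0.004] ps")
        if self.n_atoms < 2:
            raise ValidationError("need at least two atoms")

    @property
    def epsilon(self) -> float:
        """LJ well depth in energy units (nm^2 u ps^-2)."""
        return self.eps_over_kB * KB

    @property
    def dof(self) -> int:
        """Kinetic degrees of freedom (total momentum is conserved at zero)."""
        return 3 * self.n_atoms - 3

    @property
    def potential_shift(self) -> float:
        """Pair-energy offset U(r_c): forces are plain truncated LJ, but the
        tabulated potential is shifted to vanish at the cutoff so the NVE /
        extended-system invariant is continuous when pairs cross r_c."""
        x6 = (self.sigma_lj / self.cutoff) ** 6
        return 4.0 * self.epsilon * (x6 * x6 - x6)

    @property
    def thermostat_mass(self) -> float:
        """Nose-Hoover inertia Q = g kB T tau^2 (infinite when NVE)."""
        if self.thermostat_tau is None:
            return math.inf
        return self.dof * KB * self.temperature * self.thermostat_tau**2


@dataclass
class MDTrajectory:
    """Sampled production trajectory.

    ``acc``/``vel`` have shape (frames, atoms, 3); ``conserved`` is the
    extended-system invariant (NVE energy when the thermostat is off) and
    ``kinetic_temp`` the instantaneous kinetic temperature per frame."""

    config: MDConfig
    dt_sample: float
    times: np.ndarray
    acc: np.ndarray
    vel: np.ndarray
    positions: np.ndarray  # final snapshot (atoms, 3)
    conserved: np.ndarray
    kinetic_temp: np.ndarray
    tagged: int = 0


@njit(cache=True)
def _forces_pbc(pos, L, eps, sig2, rc2, ushift):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    pot = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                inv2 = sig2 / r2
                inv6 = inv2 * inv2 * inv2
                inv12 = inv6 * inv6
                coef = 24.0 * eps * (2.0 * inv12 - inv6) / r2
                f[i, 0] += coef * dx
                f[i, 1] += coef * dy
                f[i, 2] += coef * dz
                f[j, 0] -= coef * dx
                f[j, 1] -= coef * dy
                f[j, 2] -= coef * dz
                pot += 4.0 * eps * (inv12 - inv6) - ushift
    return f, pot


@njit(cache=True)
def _min_pair_distance(pos, L):
    n = pos.shape[0]
    best = 1e30
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < best:
                best = r2
    return math.sqrt(best)


def min_pair_distance(positions: np.ndarray, config: MDConfig) -> float:
    """Smallest minimum-image pair distance (nm)."""
    return float(_min_pair_distance(np.asarray(positions, float), config.box_side))


def lj_forces(positions: np.ndarray, config: MDConfig):
    """Pairwise Lennard-Jones forces and potential energy.

    Minimum-image convention; forces are truncated (unshifted) at the
    cutoff, the potential is tabulated with its cutoff-shift.  Newton's
    third law holds pairwise so the total force is zero to rounding.
    Raises on overlapping atoms (closer than 0.1 sigma).
    """
    pos = np.asarray(positions, dtype=float)
    if min_pair_distance(pos, config) < 0.1 * config.sigma_lj:
        raise ValidationError("overlapping atoms (pair distance < 0.1 sigma)")
    f, pot = _forces_pbc(
        pos, config.box_side, config.epsilon,
        config.sigma_lj**2, config.cutoff**2, config.potential_shift,
    )
    return f, float(pot)


@njit(cache=True)
def _nvt_run(
    pos, vel, L, eps, sig2, rc2, mass, dt, n_steps,
    g_kT, Q, xi0, s0, sample_every, out_acc, out_vel, out_cons, out_temp,
    dof, kB, ushift,
):
    """Operator-split integrator: Nose-Hoover half-step, velocity-Verlet
    core, Nose-Hoover half-step.  Samples every ``sample_every``-th step
    into the out arrays (sized accordingly).
    Returns (xi, s, step_of_blowup_or_minus_one)."""
    n = pos.shape[0]
    xi = xi0
    s = s0
    thermo = Q < 1e290
    f, pot = _forces_pbc(pos, L, eps, sig2, rc2, ushift)
    idx = 0
    for step in range(n_steps):
        if thermo:
            # symmetric Trotter thermostat half-step:
            # quarter xi-kick, velocity scaling over dt/2, quarter xi-kick
            ke = 0.0
            for i in range(n):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            ke *= 0.5 * mass
            xi += 0.25 * dt * (2.0 * ke - g_kT) / Q
            scale = math.exp(-0.5 * dt * xi)
            for i in range(n):
                for k in range(3):
                    vel[i, k] *= scale
            ke *= scale * scale
            s += 0.5 * dt * xi
            xi += 0.25 * dt * (2.0 * ke - g_kT) / Q
        # velocity-Verlet core
        for i in range(n):
            for k in range(3):
                vel[i, k] += 0.5 * dt * f[i, k] / mass
                pos[i, k] += dt * vel[i, k]
                pos[i, k] -= L * math.floor(pos[i, k] / L)
        f, pot = _forces_pbc(pos, L, eps, sig2, rc2, ushift)
        for i in range(n):
            for k in range(3):
                vel[i, k] += 0.5 * dt * f[i, k] / mass
        if thermo:
            ke = 0.0
            for i in range(n):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            ke *= 0.5 * mass
            xi += 0.25 * dt * (2.0 * ke - g_kT) / Q
            scale = math.exp(-0.5 * dt * xi)
            for i in range(n):
                for k in range(3):
                    vel[i, k] *= scale
            ke *= scale * scale
            s += 0.5 * dt * xi
            xi += 0.25 * dt * (2.0 * ke - g_kT) / Q
        if (step + 1) % sample_every == 0 and idx < out_acc.shape[0]:
            ke_new = 0.0
            for i in range(n):
                for k in range(3):
                    out_acc[idx, i, k] = f[i, k] / mass
                    out_vel[idx, i, k] = vel[i, k]
                ke_new += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            ke_new *= 0.5 * mass
            cons = ke_new + pot
            if Q < 1e290:
                cons += 0.5 * Q * xi * xi + g_kT * s
            out_cons[idx] = cons
            out_temp[idx] = 2.0 * ke_new / (dof * kB)
            if not math.isfinite(cons) or ke_new > 1e10:
                return xi, s, step
            idx += 1
    return xi, s, -1


@dataclass
class _MDState:
    """Mutable integration state (positions, velocities, thermostat)."""

    positions: np.ndarray
    velocities: np.ndarray
    xi: float = 0.0
    s: float = 0.0


def initial_state(config: MDConfig) -> _MDState:
    """Simple-cubic lattice filling the box, Maxwell-Boltzmann velocities at
    the target temperature with the centre-of-mass momentum removed."""
    n = config.n_atoms
    m_side = int(math.ceil(n ** (1.0 / 3.0) - 1e-9))
    spacing = config.box_side / m_side
    sites = []
    for a in range(m_side):
        for b in range(m_side):
            for c in range(m_side):
                sites.append((a + 0.5, b + 0.5, c + 0.5))
                if len(sites) == n:
                    break
            if len(sites) == n:
                break
        if len(sites) == n:
            break
    pos = np.array(sites) * spacing
    rng = np.random.default_rng(config.seed)
    vel = rng.standard_normal((n, 3)) * math.sqrt(
        KB * config.temperature / config.mass
    )
    vel -= vel.mean(axis=0)
    # rescale to the exact target kinetic temperature
    ke = 0.5 * config.mass * float((vel**2).sum())
    target = 0.5 * config.dof * KB * config.temperature
    vel *= math.sqrt(target / ke)
    return _MDState(positions=pos, velocities=vel)


def nvt_step(state: _MDState, config: MDConfig, n_steps: int = 1) -> _MDState:
    """Advance the state by ``n_steps`` velocity-Verlet/Nose-Hoover steps
    (in place) and return it."""
    out_acc = np.empty((1, config.n_atoms, 3))
    out_vel = np.empty_like(out_acc)
    out_cons = np.empty(1)
    out_temp = np.empty(1)
    xi, s, bad = _nvt_run(
        state.positions, state.velocities, config.box_side, config.epsilon,
        config.sigma_lj**2, config.cutoff**2, config.mass, config.dt,
        n_steps, config.dof * KB * config.temperature,
        config.thermostat_mass, state.xi, state.s,
        n_steps, out_acc, out_vel, out_cons, out_temp, config.dof, KB,
        config.potential_shift,
    )
    if bad >= 0:
        raise UnstableStepError(f"MD blow-up at step {bad}")
    state.xi, state.s = xi, s
    return state


def run_md(
    config: MDConfig,
    duration: float,
    equilibration: float = 20.0,
    sample_every: int = 10,
) -> MDTrajectory:
    """Equilibrate and run a production NVT (or NVE) trajectory.

    Parameters
    ----------
    duration
        Production length in ps.
    equilibration
        Discarded initial segment in ps (lattice melting + thermalisation).
    sample_every
        Sampling stride in integration steps.

    Accelerations and velocities of all atoms are recorded at the sampling
    stride; identical atoms are statistically exchangeable, so tagged-particle
    statistics may pool them.
    """
    state = initial_state(config)
    n_eq = int(round(equilibration / config.dt))
    n_prod = int(round(duration / config.dt))
    if n_prod < sample_every:
        raise ValidationError("duration shorter than one sampling interval")
    if n_eq > 0:
        nvt_step(state, config, n_eq)
    n_frames = n_prod // sample_every
    out_acc = np.empty((n_frames, config.n_atoms, 3))
    out_vel = np.empty_like(out_acc)
    out_cons = np.empty(n_frames)
    out_temp = np.empty(n_frames)
    xi, s, bad = _nvt_run(
        state.positions, state.velocities, config.box_side, config.epsilon,
        config.sigma_lj**2, config.cutoff**2, config.mass, config.dt,
        n_prod, config.dof * KB * config.temperature,
        config.thermostat_mass, state.xi, state.s,
        sample_every, out_acc, out_vel, out_cons, out_temp, config.dof, KB,
        config.potential_shift,
    )
    if bad >= 0:
        raise UnstableStepError(f"MD blow-up at production step {bad}")
    state.xi, state.s = xi, s
    times = (np.arange(1, n_frames + 1) * sample_every) * config.dt
    return MDTrajectory(
        config=config,
        dt_sample=sample_every * config.dt,
        times=times,
        acc=out_acc,
        vel=out_vel,
        positions=state.positions,
        conserved=out_cons,
        kinetic_temp=out_temp,
    )


def md_moment_summary(
    traj: MDTrajectory, pool_atoms: bool = True, n_blocks: int = 50
) -> MomentSummary:
    """Acceleration and velocity moments with block-bootstrap errors.

    Every acceleration moment is the average of the three per-coordinate
    time averages; with ``pool_atoms`` (default) all atoms enter the average
    as exchangeable copies of the tagged particle, otherwise only the tagged
    atom is used.
    """
    from .sde import _block_se

    if pool_atoms:
        U = traj.acc  # (frames, atoms, 3)
        V = traj.vel
    else:
        U = traj.acc[:, traj.tagged : traj.tagged + 1, :]
        V = traj.vel[:, traj.tagged : traj.tagged + 1, :]
    nf = U.shape[0]
    n_blocks = min(n_blocks, nf)
    if n_blocks < 10:
        raise ValidationError("trajectory shorter than 10 blocks")
    absU = np.abs(U)
    m = MomentSummary(
        absU=float(absU.mean()),
        u2=float((U**2).mean()),
        u4=float((U**4).mean()),
        v2=float((V**2).mean()),
    )
    m.se = {
        "absU": _block_se(absU.reshape(nf, -1).mean(axis=1), n_blocks),
        "u2": _block_se((U**2).reshape(nf, -1).mean(axis=1), n_blocks),
        "u4": _block_se((U**4).reshape(nf, -1).mean(axis=1), n_blocks),
        "v2": _block_se((V**2).reshape(nf, -1).mean(axis=1), n_blocks),
    }
    return m


def write_xyz(path, positions: np.ndarray, config: MDConfig, time: float = 0.0):
    """Write a snapshot in XYZ format; the comment line carries the box side
    (nm) and the time stamp (ps)."""
    pos = np.asarray(positions, float)
    with open(path, "w") as fh:
        fh.write(f"{pos.shape[0]}\n")
        fh.write(f"box_side_nm={config.box_side} time_ps={time}\n")
        for r in pos:
            fh.write(f"Ar {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")
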