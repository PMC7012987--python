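# Methods

This note records the model assumptions, the numerical choices and the
limits of what the test suite demonstrates.

## Model family and assumptions

The coarse-grained particle state is (X, V, U₁..U_N, Z₁..Z_N) per
coordinate; the three coordinates are independent and statistically
exchangeable.  Noise is additive and enters only the auxiliary Z equations
with amplitude η₄.  The map h acting on Z is the identity throughout the
package: every stationary density then factorises with Gaussian V- and
Z-marginals, and all non-Gaussian structure lives in the acceleration U.
A non-identity h would enter the stationary density only through its
antiderivative H(z) replacing z²/2 in the exponent; no such code path is
built, because no concrete h beyond the identity is specified anywhere in
the theory the package implements.

Two nonlinearity families are supported.  The one-parameter power law is
valid as a differentiable, invertible map only for exponents η₅ ≤ 1; the
package follows the stationary theory for all η₅ > 0 but refuses to
*simulate* a one-parameter model with η₅ > 1, where the drift factor
|U|^{1−η₅} diverges at U = 0 (`SingularDriftError` points to the
two-parameter family, which exists precisely to remove that defect).
For η₅ > 1 the two-parameter g is discontinuous at y = 0; the potential
G(g⁻¹(u)) is then defined by the stationarity relation dΨ/du = u/g′(g⁻¹(u))
(equivalently, the published piecewise formula), which differs from the
literal integral of g by an additive constant with no physical content.
The tests check the stationarity relation, which is branch-independent.

## Stationary theory and the F function

All closed-form moments are evaluated through log-gamma differences.  The
two-parameter helper F uses **unnormalized** upper/lower incomplete gamma
functions; standard libraries return regularized versions, so Γ(s, y) is
assembled as `exp(lgamma(s)) * gammaincc(s, y)` — in log space.  For large
arguments, where the regularized routine underflows, log(e^y Γ(s, y)) is
computed by a Lentz continued fraction; F is therefore usable far past the
overflow of F itself (κ₁ of order hundreds), and ratios such as the
kurtosis are formed purely in log space.

Below κ₁ = 10⁻⁸ the two-parameter statistics switch to the analytic
η₆ → 0 limits to avoid cancellation between the two F terms.  One genuine
mathematical caveat: the η₆ → 0 convergence rate of the moment ratios is
O(y^{1−κ₂}) with y = 2κ₁κ₂, so for κ₂ near 1 (small exponents η₅) the
approach to the one-parameter limit is slow — at κ₂ = 0.8 and κ₁ = 10⁻⁶
the kurtosis still deviates by ~6%.  This is a property of the model, not
of the implementation; the tests assert the rate rather than a fixed
tolerance there.

The two-parameter fit solves the 2×2 system {kurtosis, ratio} by a hybrid
Newton method on (log κ₁, logit κ₂) with multistart seeded from the
one-parameter ratio fit.  The solved pair reproduces its inputs to 1e−9.
Note that this stage is sensitive to the third significant digit of its
inputs: inputs rounded to 3 s.f. move κ₁ by a few times 10⁻³.

The 1-D exponent fits invert strictly monotone maps by bracketed Brent
iteration on log η₅ ∈ [log 10⁻³, log 10³]; the attainable statistic range
is computed from the bracket ends at call time and embedded in error
messages.

The general-N moment system (2 equations, N unknowns κⱼ = σⱼ^{2/(1+η_{j,5})})
is solved exactly for N ≤ 2 (elimination + quadratic) and as a
minimum-Euclidean-norm nonnegative solution (SLSQP) for N > 2, where the
system is under-determined by design; additional even-moment constraints
could be appended in the same form.

## SDE integration

Euler–Maruyama, which for this additive-noise system coincides with
Milstein (weak order 1).  Default step: 1% of the fastest linear relaxation
time min(1/η₂, η₃^{−1/2}, η₁^{−1/2}); steps above 20% of it are refused.
Default burn-in: ten times the slowest relaxation time (including the
velocity decorrelation time η₃/(η₁η₂)).  The stationary-moment bias of the
integrator is O(dt·rate) — about 1% of ⟨U²⟩ at the default step for
unit rates — and is validated two ways: against the *exact* stationary
covariance of the Euler chain (discrete Lyapunov equation), which the
simulator must match within Monte-Carlo error at any step, and against the
continuous theory at small steps.  An exact Gaussian (matrix-exponential /
Van Loan) propagator for the linear N = 1 model serves as an independent
oracle, never as the default path.

Initial condition: X, V, Z start at zero; U starts at its typical
stationary magnitude √σⱼ.  The origin is *not* used for U because the
one-parameter drift factor |U|^{1−η₅} vanishes there, making U = 0 an
absorbing point of the discrete map — a trajectory started exactly at zero
never moves.  After the first step the state is almost surely never exactly
zero again, so no regularization is applied in the loop.

Seeding: one `numpy` Generator per run; noise is drawn in fixed-size blocks,
so identical seed and configuration give bit-identical trajectories
regardless of chunking.

## Estimators

Moments are time averages pooled over the three coordinates — the average
of per-coordinate averages, which for equal sample counts equals the pooled
mean.  Standard errors are block bootstrap (50 contiguous blocks, 200
resamples); trajectories shorter than 10 blocks are rejected.  The VACF is
FFT-based with lag-dependent normalization; the diffusion constant comes
from a linear fit to the MSD over a window of 10–100 velocity correlation
times (FFT MSD algorithm), cross-checked by integrating the unnormalized
VACF up to the lag where a moving-max envelope of |χ|/χ(0) falls below 2% —
a plain first-crossing rule truncates oscillatory VACFs at a zero crossing,
the envelope does not.

## Lennard-Jones argon fixture

State point: 512 atoms, cubic box 2.91 nm (number density 20.8 nm⁻³),
ε/k_B = 120 K, σ = 0.34 nm, m = 39.948 u, T = 94.4 K.  Units nm/ps/u/K with
k_B = 8.3145×10⁻³ nm² u ps⁻² K⁻¹ (so 1 u nm² ps⁻² = 1 kJ/mol and
k_BT/m = 0.01965 nm² ps⁻² at the state point).

Details not fixed by the study conditions, decided once: dt = 0.002 ps;
cutoff 1.4 nm (< L/2) with truncated, unshifted *forces* — the tabulated
potential is shifted by U(r_c) so the conserved quantity is continuous when
pairs cross the cutoff (the shift does not affect the dynamics or any
acceleration statistic); simple-cubic 8³ initial lattice with
Maxwell–Boltzmann velocities, zero total momentum and 3N−3 kinetic degrees
of freedom; 20 ps equilibration discarded; single Nosé–Hoover thermostat
with coupling time τ = 0.2 ps (mass Q = (3N−3) k_B T τ²), integrated by
symmetric Trotter half-steps around a velocity-Verlet core.  Measured
invariant drift: ≲ 2×10⁻⁵ relative per 10⁴ steps (NVE and NVT).  The
O(N²) minimum-image pair loop is JIT-compiled; at N = 512 a 0.2 ns
production run takes a few minutes on one core.

The reference tagged-particle statistics come from a 10 ns series of one
atom; this package instead pools all 512 exchangeable atoms over a 0.2 ns
production window (≈ 1.5×10⁷ acceleration samples), keeping the
per-coordinate averaging convention.  Pooling changes the estimator, not
the estimand.  Agreement with the reference values is expected at the
5% level for first/second moments and 10% for fourth moment and kurtosis,
reflecting sensitivity to protocol details (cutoff treatment, thermostat,
equilibration) that the study conditions leave open.

## What the synthetic data does and does not show

The SDE simulators generate data *from the model itself*; passing
recovery tests therefore demonstrates the internal consistency of theory,
integrator and estimators — not that the model describes any particular
fluid.  The argon engine is the genuinely external data source: its force
distribution is produced by Newtonian dynamics, not by the SCG family, and
the fact that the fitted stationary density matches its moments (while the
full distribution shape is only approximated) is exactly the situation the
method is designed for.  Real applications (ions in water, multi-resolution
coupling) involve long-range electrostatics, constraint dynamics and
non-exchangeable species that neither the fixture nor the tests emulate.

## Known limitations

* The one-parameter family cannot be simulated for η₅ > 1 (by design).
* No general-N closed-form VACF; for N > 1 the VACF comes from simulation.
* The general-N fit with N > 2 returns one representative (minimum-norm)
  solution of an under-determined system.
* The MD engine is a fixture, not a production MD code: single thermostat,
  no neighbor lists, no pressure coupling, no long-range corrections.
* Problem sizes in the test suite (10⁶–10⁷ SDE steps, 0.2 ns MD) were
  chosen to give Monte-Carlo error comfortably below the asserted
  tolerances on a single core.
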