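"""SDE simulators and estimators: stationary statistics vs closed theory."""

import math

import numpy as np
import pytest

from scgmd import (
    MomentSummary,
    NonlinearityOneParam,
    NonlinearityTwoParam,
    SingularDriftError,
    ValidationError,
    abs_moment_one,
    complete_fit,
    estimate_diffusion,
    estimate_moments,
    estimate_vacf,
    fit_linear_N1,
    kurtosis_one,
    kurtosis_two,
    KappaPair,
    sigma_constraint,
    simulate,
    simulate_bd,
    simulate_linear_exact,
    vacf_decompose,
    vacf_eval,
    vz_moments,
)

UNIT_MOMENTS = MomentSummary(D=1.0, v2=1.0, u2=1.0, z2=1.0)


def kurtosis_se(m):
    """Conservative delta-method standard error for u4/u2^2 from the
    block-bootstrap errors of the two moments (correlation ignored)."""
    return m.kurtosis * math.sqrt(
        (m.se["u4"] / m.u4) ** 2 + 4.0 * (m.se["u2"] / m.u2) ** 2
    )


@pytest.fixture(scope="module")
def linear_params():
    return fit_linear_N1(UNIT_MOMENTS)


@pytest.fixture(scope="module")
def linear_traj(linear_params):
    # dt well below the relaxation times so the weak-order-1 bias stays
    # inside the Monte-Carlo band
    return simulate(linear_params, n_steps=3_000_000, dt=0.002, seed=11, thin=5)


class TestBrownianDynamics:
    def test_msd_slope_matches_2D(self):
        D, dt, n = 0.7, 0.01, 400_000
        X = simulate_bd(D, dt, n, seed=4)
        disp = X[-1] - X[0]
        # each coordinate: Var = 2 D T
        est = (disp**2).mean()
        T = n * dt
        # 3 coords only -> generous band from chi^2_3
        assert est / (2 * D * T) == pytest.approx(1.0, abs=2.0)
        # tighter: increments over many sub-intervals
        inc = np.diff(X[:: 1000], axis=0)
        est2 = (inc**2).mean() / (2 * D * 1000 * dt)
        se = math.sqrt(2.0 / inc.size)
        assert est2 == pytest.approx(1.0, abs=3 * se)

    def test_zero_diffusion_constant_path(self):
        X = simulate_bd(0.0, 0.01, 100, seed=0)
        assert np.all(X == 0.0)

    def test_increments_gaussian(self):
        from scipy import stats

        X = simulate_bd(1.0, 0.01, 100_000, seed=9)
        inc = np.diff(X, axis=0).ravel()
        z = inc / inc.std()
        # moment-based normality check at n = 3e5
        n = z.size
        skew = float(stats.skew(z))
        kurt = float(stats.kurtosis(z))
        assert abs(skew) < 3 * math.sqrt(6.0 / n)
        assert abs(kurt) < 3 * math.sqrt(24.0 / n)


class TestLinearSimulation:
    def test_stationary_moments_within_3se(self, linear_traj):
        m = estimate_moments(linear_traj)
        assert m.v2 == pytest.approx(1.0, abs=3 * m.se["v2"] + 0.01)
        assert m.u2 == pytest.approx(1.0, abs=3 * m.se["u2"] + 0.01)
        assert m.z2 == pytest.approx(1.0, abs=3 * m.se["z2"] + 0.01)

    def test_vacf_matches_closed_form(self, linear_traj, linear_params):
        e1, e2, e3, _ = linear_params.eta[0]
        dec = vacf_decompose(e1, e2, e3)
        lags, v = estimate_vacf(linear_traj, max_lag=int(5.0 / linear_traj.dt))
        assert v[0] == pytest.approx(1.0)
        assert np.max(np.abs(v - vacf_eval(dec, lags))) < 0.02

    def test_diffusion_constant_recovered(self, linear_traj):
        d = estimate_diffusion(linear_traj)
        assert d.D == pytest.approx(1.0, rel=0.10)
        assert d.D_vacf == pytest.approx(d.D_msd, rel=0.15)

    def test_gaussianity_of_acceleration(self, linear_traj):
        m = estimate_moments(linear_traj)
        assert m.kurtosis == pytest.approx(3.0, abs=3 * kurtosis_se(m))

    def test_exact_propagator_agrees_with_theory(self, linear_params):
        traj = simulate_linear_exact(linear_params, n_steps=400_000, dt=0.05,
                                     seed=21, burn_in=2_000)
        m = estimate_moments(traj)
        D, v2, z2 = vz_moments(linear_params)
        assert m.v2 == pytest.approx(v2, abs=3 * m.se["v2"])
        assert m.z2 == pytest.approx(z2, abs=3 * m.se["z2"])

    def test_euler_and_exact_propagator_consistent(self, linear_params, linear_traj):
        """Weak validation: EM moments sit within a few SE of the exact
        Gaussian propagator's."""
        exact = simulate_linear_exact(linear_params, n_steps=400_000, dt=0.05,
                                      seed=22, burn_in=2_000)
        me = estimate_moments(exact)
        mm = estimate_moments(linear_traj)
        band = 3 * (me.se["u2"] + mm.se["u2"]) + 0.01
        assert mm.u2 == pytest.approx(me.u2, abs=band)


class TestNonlinearSimulation:
    def test_one_param_kurtosis_leptokurtic(self):
        eta5 = 0.550
        spec = NonlinearityOneParam(eta5)
        sigma = sigma_constraint(spec, MomentSummary(u2=1.10))
        params = complete_fit(MomentSummary(D=1, v2=1, z2=1), sigma, spec)
        traj = simulate(params, n_steps=6_000_000, dt=0.002, seed=5, thin=10)
        m = estimate_moments(traj)
        kurt_th = kurtosis_one(eta5)
        se_kurt = kurtosis_se(m)
        assert m.kurtosis == pytest.approx(kurt_th, abs=3 * se_kurt + 0.05)
        assert m.u2 == pytest.approx(abs_moment_one(2, eta5, sigma), abs=3 * m.se["u2"] + 0.02)
        # the core claim: the acceleration distribution is non-Gaussian
        assert m.kurtosis - 3.0 > 10 * se_kurt

    def test_two_param_moments(self):
        spec = NonlinearityTwoParam(0.297, 0.472)
        kp = KappaPair(0.297 * 0.472**1.297 / (2 * 0.3644), 1 / 1.297)
        params = complete_fit(MomentSummary(D=1, v2=1, z2=1), 0.3644, spec)
        traj = simulate(params, n_steps=6_000_000, dt=0.002, seed=6, thin=10)
        m = estimate_moments(traj)
        assert m.kurtosis == pytest.approx(kurtosis_two(kp), rel=0.05)

    def test_singular_one_param_rejected(self):
        params = complete_fit(
            MomentSummary(D=1, v2=1, z2=1), 1.0, NonlinearityOneParam(2.0)
        )
        with pytest.raises(SingularDriftError):
            simulate(params, n_steps=100, seed=0)

    def test_noiseless_dynamics_decay(self, linear_params):
        from scgmd import LinearSCGParams

        eta = linear_params.eta.copy()
        eta[0, 3] = 1e-12  # effectively eta4 = 0
        quiet = LinearSCGParams(eta)
        traj = simulate(quiet, n_steps=50_000, dt=0.002, seed=1, burn_in=0)
        v_amp = np.abs(traj.V)
        assert v_amp[-1000:].max() < 1e-6


class TestEstimators:
    def test_constant_acceleration_moments(self):
        class Shim:
            V = None
            Z = None

            def total_acceleration(self):
                return np.full((1000, 3), -2.0)

        m = estimate_moments(Shim())
        assert m.absU == pytest.approx(2.0)
        assert m.u2 == pytest.approx(4.0)
        assert m.u4 == pytest.approx(16.0)

    def test_iid_gaussian_kurtosis(self):
        rng = np.random.default_rng(3)

        class Shim:
            V = None
            Z = None
            U = rng.standard_normal((200_000, 1, 3))

            def total_acceleration(self):
                return self.U.sum(axis=1)

        m = estimate_moments(Shim())
        n = 600_000
        se = math.sqrt(24.0 / n)
        assert m.kurtosis == pytest.approx(3.0, abs=3 * se)

    def test_short_trajectory_rejected(self):
        class Shim:
            V = None
            Z = None

            def total_acceleration(self):
                return np.zeros((5, 3))

        with pytest.raises(ValidationError):
            estimate_moments(Shim())

    def test_white_noise_vacf_is_delta(self):
        rng = np.random.default_rng(8)

        class Shim:
            V = rng.standard_normal((100_000, 3))
            dt = 1.0

        lags, v = estimate_vacf(Shim(), max_lag=20)
        assert v[0] == pytest.approx(1.0)
        assert np.max(np.abs(v[1:])) < 0.02


class TestTrajectoryMechanics:
    def test_seeded_determinism(self, linear_params):
        a = simulate(linear_params, n_steps=20_000, seed=13)
        b = simulate(linear_params, n_steps=20_000, seed=13)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.X, b.X)
        c = simulate(linear_params, n_steps=20_000, seed=14)
        assert not np.array_equal(a.U, c.U)

    def test_coordinates_exchangeable(self, linear_traj):
        per_coord = (linear_traj.total_acceleration() ** 2).mean(axis=0)
        assert per_coord.std() / per_coord.mean() < 0.05

    def test_step_above_stability_bound_rejected(self, linear_params):
        with pytest.raises(ValidationError):
            simulate(linear_params, n_steps=100, dt=0.5, seed=0)

    def test_weak_convergence_bias_shrinks_with_dt(self, linear_params):
        """Stationary <V^2> bias decreases monotonically as dt is halved.

        Uses the exact one-step Gaussian (discrete Lyapunov) covariance of
        the Euler-Maruyama chain rather than Monte-Carlo, so the trend is
        deterministic."""
        from scipy.linalg import solve_discrete_lyapunov

        e1, e2, e3, e4 = linear_params.eta[0]
        A = np.array([[0, 1, 0], [-e1, 0, 1], [0, -e3, -e2]], float)
        biases = []
        for dt in (0.02, 0.01, 0.005):
            M = np.eye(3) + dt * A
            Q = np.zeros((3, 3))
            Q[2, 2] = e4**2 * dt
            S = solve_discrete_lyapunov(M, Q)
            biases.append(abs(S[0, 0] - 1.0))
        assert biases[0] > biases[1] > biases[2]

    def test_em_matches_discrete_lyapunov_covariance(self, linear_params):
        """The simulated chain reproduces the exact EM stationary covariance
        (a sharper check than comparing against the continuous theory)."""
        from scipy.linalg import solve_discrete_lyapunov

        dt = 0.01
        e1, e2, e3, e4 = linear_params.eta[0]
        A = np.array([[0, 1, 0], [-e1, 0, 1], [0, -e3, -e2]], float)
        M = np.eye(3) + dt * A
        Q = np.zeros((3, 3))
        Q[2, 2] = e4**2 * dt
        S = solve_discrete_lyapunov(M, Q)
        traj = simulate(linear_params, n_steps=2_000_000, dt=dt, seed=17, thin=4)
        m = estimate_moments(traj)
        assert m.v2 == pytest.approx(S[0, 0], abs=3 * m.se["v2"])
        assert m.u2 == pytest.approx(S[1, 1], abs=3 * m.se["u2"])
        assert m.z2 == pytest.approx(S[2, 2], abs=3 * m.se["z2"])
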