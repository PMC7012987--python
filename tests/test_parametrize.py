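"""Fitting procedures: worked-example values, roundtrips, feasibility errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scgmd import (
    InfeasibleError,
    KappaPair,
    LinearSCGParams,
    MomentSummary,
    NonlinearityOneParam,
    NonlinearityTwoParam,
    UnattainableError,
    ValidationError,
    abs_moment_one,
    complete_fit,
    fit_eta5_from_kurtosis,
    fit_eta5_from_ratio,
    fit_generalN_kappas,
    fit_kappa,
    fit_linear_N1,
    fit_scg,
    generalN_moments,
    kappa_to_eta,
    kurtosis_one,
    kurtosis_two,
    mean_abs_over_eta6,
    ratio_one,
    ratio_two,
    sigma_constraint,
    vz_moments,
)


class TestLinearFit:
    def test_unit_moments(self):
        lin = fit_linear_N1(MomentSummary(D=1.0, v2=1.0, u2=1.0, z2=1.0))
        assert lin.eta[0] == pytest.approx([1.0, 1.0, 1.0, math.sqrt(2.0)])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        D=st.floats(0.01, 10), v2=st.floats(0.01, 10),
        u2=st.floats(0.01, 10), z2=st.floats(0.01, 10),
    )
    def test_roundtrip_is_exact(self, D, v2, u2, z2):
        lin = fit_linear_N1(MomentSummary(D=D, v2=v2, u2=u2, z2=z2))
        got = vz_moments(lin)
        assert got == pytest.approx((D, v2, z2), rel=1e-10)
        assert lin.sigma() == pytest.approx(u2, rel=1e-10)

    def test_missing_or_invalid_moment_rejected(self):
        with pytest.raises(ValidationError):
            fit_linear_N1(MomentSummary(D=1.0, v2=1.0, u2=1.0))
        with pytest.raises(ValidationError):
            MomentSummary(D=-1.0)


class TestExponentFits:
    def test_worked_example_values(self):
        assert fit_eta5_from_kurtosis(3.0) == pytest.approx(1.0, rel=1e-9)
        assert fit_eta5_from_kurtosis(5.85) == pytest.approx(0.550, abs=5e-4)
        assert fit_eta5_from_ratio(math.pi / 2) == pytest.approx(1.0, rel=1e-9)
        # at 3 s.f. inputs the ratio inversion lands within one unit in the
        # last printed digit of the reference 0.692
        assert fit_eta5_from_ratio(1.93) == pytest.approx(0.692, abs=0.005)

    @pytest.mark.parametrize("eta5", [0.2, 0.7, 2.5, 8.0])
    def test_roundtrips(self, eta5):
        assert fit_eta5_from_kurtosis(kurtosis_one(eta5)) == pytest.approx(eta5, rel=1e-8)
        assert fit_eta5_from_ratio(ratio_one(eta5)) == pytest.approx(eta5, rel=1e-8)

    def test_out_of_range_kurtosis_names_interval(self):
        with pytest.raises(UnattainableError, match="attainable interval"):
            fit_eta5_from_kurtosis(0.9)  # below the large-exponent limit
        with pytest.raises(UnattainableError):
            fit_eta5_from_ratio(1.0)


class TestKappaFit:
    def test_argon_worked_example(self):
        """(kurtosis, ratio) = (5.85, 1.93) solves to the argon kappa pair
        (within the sensitivity of 3 s.f. rounded inputs)."""
        kp = fit_kappa(5.85, 1.93)
        assert kurtosis_two(kp) == pytest.approx(5.85, abs=1e-10)
        assert ratio_two(kp) == pytest.approx(1.93, abs=1e-10)
        assert kp.kappa1 == pytest.approx(0.149, abs=0.01)
        assert kp.kappa2 == pytest.approx(0.771, abs=0.01)
        # with unrounded inputs the reference pair is recovered to 3 s.f.
        kp2 = fit_kappa(kurtosis_two(KappaPair(0.149, 0.771)),
                        ratio_two(KappaPair(0.149, 0.771)))
        assert kp2.kappa1 == pytest.approx(0.149, abs=5e-4)
        assert kp2.kappa2 == pytest.approx(0.771, abs=5e-4)

    def test_roundtrip(self):
        kp0 = KappaPair(0.3, 0.6)
        kp = fit_kappa(kurtosis_two(kp0), ratio_two(kp0))
        assert kp.kappa1 == pytest.approx(0.3, abs=1e-6)
        assert kp.kappa2 == pytest.approx(0.6, abs=1e-6)

    def test_one_param_limit_consistency(self):
        """Inputs generated by the eta6 = 0 model drive kappa1 to zero and
        kappa2 to 1/(1+eta5)."""
        eta5 = 0.8
        kp = fit_kappa(kurtosis_one(eta5), ratio_one(eta5))
        assert kp.kappa1 < 1e-4
        assert kp.kappa2 == pytest.approx(1.0 / (1.0 + eta5), abs=1e-3)

    def test_infeasible_inputs_raise(self):
        with pytest.raises(UnattainableError):
            fit_kappa(0.5, 1.93)


class TestKappaToEta:
    def test_argon_values(self):
        # the reference pair is itself rounded to 3 s.f., so the recovered
        # values agree to within one unit in the last printed digit
        nl = kappa_to_eta(KappaPair(0.149, 0.771), absU=0.753)
        assert nl.eta5 == pytest.approx(0.297, abs=1e-3)
        assert nl.eta6 == pytest.approx(0.472, abs=1e-3)

    def test_kappa2_half_gives_unit_exponent(self):
        assert kappa_to_eta(KappaPair(0.3, 0.5), 1.0).eta5 == pytest.approx(1.0)

    def test_mean_abs_roundtrip(self):
        kp = KappaPair(0.42, 0.65)
        absU = 1.37
        nl = kappa_to_eta(kp, absU)
        assert mean_abs_over_eta6(kp) * nl.eta6 == pytest.approx(absU, rel=1e-8)


class TestSigmaConstraint:
    def test_gaussian_case_is_u2(self):
        s = sigma_constraint(NonlinearityOneParam(1.0), MomentSummary(u2=1.7))
        assert s.sigma == pytest.approx(1.7, rel=1e-12)

    def test_one_param_self_consistency(self):
        s = sigma_constraint(NonlinearityOneParam(0.550), MomentSummary(u2=1.10))
        assert abs_moment_one(2.0, 0.550, s) == pytest.approx(1.10, rel=1e-10)

    def test_two_param_self_consistency(self):
        kp = fit_kappa(5.85, 1.93)
        nl = kappa_to_eta(kp, 0.753)
        s = sigma_constraint(nl, MomentSummary(absU=0.753), kp)
        k1 = nl.eta5 * nl.eta6 ** (1 + nl.eta5) / (2 * s.sigma)
        got = mean_abs_over_eta6(KappaPair(k1, 1 / (1 + nl.eta5))) * nl.eta6
        assert got == pytest.approx(0.753, rel=1e-10)


class TestCompleteFit:
    def test_unit_exponent_reduces_to_linear(self):
        m = MomentSummary(D=0.8, v2=1.2, u2=0.6, z2=2.0)
        lin = fit_linear_N1(m)
        nl = complete_fit(m, 0.6, NonlinearityOneParam(1.0))
        assert np.allclose(nl.linear.eta, lin.eta)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        D=st.floats(0.05, 5), v2=st.floats(0.05, 5),
        z2=st.floats(0.05, 5), sigma=st.floats(0.05, 5),
    )
    def test_roundtrip_exact(self, D, v2, z2, sigma):
        m = MomentSummary(D=D, v2=v2, z2=z2)
        nl = complete_fit(m, sigma, NonlinearityOneParam(0.55))
        assert vz_moments(nl.linear) == pytest.approx((D, v2, z2), rel=1e-10)
        assert nl.linear.sigma() == pytest.approx(sigma, rel=1e-10)


class TestGeneralNKappas:
    def test_single_component_collapses(self):
        eta5 = 0.55
        sigma = 0.9
        u2 = abs_moment_one(2.0, eta5, sigma)
        u4 = abs_moment_one(4.0, eta5, sigma)
        k = fit_generalN_kappas(u2, u4, [eta5])
        assert k[0] == pytest.approx(sigma ** (2 / (1 + eta5)), rel=1e-10)
        res = generalN_moments([eta5], [k[0] ** ((1 + eta5) / 2)])
        assert res["kurtosis"] == pytest.approx(u4 / u2**2, rel=1e-10)

    def test_two_component_roundtrip(self):
        etas5 = [0.5, 1.0]
        kappas = np.array([0.4, 0.8])
        sigmas = [k ** ((1 + e) / 2) for k, e in zip(kappas, etas5)]
        tot = generalN_moments(etas5, sigmas)
        got = fit_generalN_kappas(tot["u2"], tot["u4"], etas5)
        assert got == pytest.approx(kappas, rel=1e-8)

    def test_gaussian_inputs_zero_out_nongaussian_components(self):
        u2 = 2.0
        got = fit_generalN_kappas(u2, 3.0 * u2**2, [0.5, 1.0])
        assert got[0] == pytest.approx(0.0, abs=1e-10)

    def test_three_component_minimum_norm(self):
        etas5 = [0.4, 0.8, 2.0]
        kstar = np.array([0.2, 0.5, 0.3])
        sigmas = [k ** ((1 + e) / 2) for k, e in zip(kstar, etas5)]
        tot = generalN_moments(etas5, sigmas)
        got = fit_generalN_kappas(tot["u2"], tot["u4"], etas5)
        # constraints reproduced; the returned solution has no larger norm
        res = generalN_moments(etas5, [k ** ((1 + e) / 2) for k, e in zip(got, etas5)])
        assert res["u2"] == pytest.approx(tot["u2"], rel=1e-7)
        assert res["u4"] == pytest.approx(tot["u4"], rel=1e-7)
        assert np.dot(got, got) <= np.dot(kstar, kstar) + 1e-8

    def test_infeasible_mix_raises(self):
        # leptokurtic target with only platykurtic components
        with pytest.raises(InfeasibleError):
            fit_generalN_kappas(1.0, 4.0, [2.0, 3.0])


class TestFitPipelines:
    def test_two_param_pipeline_without_velocity_moments(self):
        m = MomentSummary(absU=0.753, u2=1.93 * 0.753**2)
        m.u4 = 5.85 * m.u2**2
        res = fit_scg(m, "two-param")
        assert isinstance(res.nonlinearity, NonlinearityTwoParam)
        assert res.params is None
        assert res.nonlinearity.eta5 == pytest.approx(0.289, abs=5e-4)

    def test_one_param_pipeline_completes_with_velocity_moments(self):
        m = MomentSummary(D=1.0, v2=1.0, z2=1.0, u2=1.10, u4=5.85 * 1.10**2)
        res = fit_scg(m, "one-param-kurtosis")
        assert res.params is not None
        D, v2, z2 = vz_moments(res.params.linear)
        assert (D, v2, z2) == pytest.approx((1.0, 1.0, 1.0), rel=1e-10)
        assert res.params.linear.sigma() == pytest.approx(res.sigma.sigma, rel=1e-10)

    def test_unknown_procedure_rejected(self):
        with pytest.raises(ValidationError):
            fit_scg(MomentSummary(u2=1.0), "bogus")


def test_linear_params_validation():
    with pytest.raises(ValidationError):
        LinearSCGParams(np.array([[1.0, -1.0, 1.0, 1.0]]))
    with pytest.raises(ValidationError):
        LinearSCGParams(np.ones((1, 3)))
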