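"""Tests for condition-level estimation and thermodynamics."""

import numpy as np
import pytest

from nestedwell import (
    DataError,
    InvalidParameterError,
    NonphysicalSelectivityError,
    IsothermFit,
    RateSet,
    StepSchedule,
    ThermoFit,
    analyze_pair,
    delta_delta_g,
    delta_g,
    extract_k2,
    fit_all_steps,
    fraction_specific,
    generate_k2_temperature_series,
    generate_probe_pair,
    generate_trace,
    kon_from_slopes,
    langmuir_pair_fit,
    nw_joint_fit,
    vant_hoff_fit,
)
from conftest import TRUE, TRUE_KD_EFF


class TestLangmuirPairFit:
    def test_noiseless_recovery(self, noiseless_isotherm):
        iso = noiseless_isotherm
        assert iso.Sigma_inf == pytest.approx(1000.0, rel=1e-3)
        assert iso.Kd_specific == pytest.approx(TRUE_KD_EFF, rel=1e-3)
        assert iso.Kd_nonspecific == pytest.approx(200.0, rel=1e-3)
        assert iso.ordering_expected

    def test_identical_inputs_give_equal_kd(self, noiseless_steps):
        _, steps_ns = noiseless_steps
        iso = langmuir_pair_fit(steps_ns, steps_ns)
        assert iso.Kd_specific == pytest.approx(iso.Kd_nonspecific, rel=1e-6)

    def test_noisy_recovery_within_errors(self):
        sp, ns = generate_probe_pair(noise_sd=10.0, seed=5)  # 1% of saturation
        iso = langmuir_pair_fit(fit_all_steps(sp), fit_all_steps(ns))
        assert abs(iso.Kd_specific - TRUE_KD_EFF) < 3 * iso.se_Kd_specific

    def test_too_few_concentrations(self, noiseless_steps):
        steps_sp, steps_ns = noiseless_steps
        with pytest.raises(DataError):
            langmuir_pair_fit(steps_sp[:2], steps_ns[:2])


class TestKonFromSlopes:
    def test_first_step_from_zero_is_exact(self, single_well_rates):
        """For binding from empty probes, sigma'(c) = Sigma_inf*kon*c exactly."""
        iso = IsothermFit(Sigma_inf=1000.0, Kd_specific=27.6, Kd_nonspecific=200.0)
        steps = []
        for c in (5.0, 10.0):
            sched = StepSchedule(step_times=(0.0,), concentrations=(c,), end_time=3000.0)
            tr = generate_trace(single_well_rates, sched, sigma_inf=1000.0, noise_sd=0.0)
            steps.append(fit_all_steps(tr)[0])
        rate = kon_from_slopes([], steps, iso, regressor="c")
        assert rate.kon == pytest.approx(1.6e-5, rel=1e-6)
        assert rate.koff_nonspecific == pytest.approx(200.0 * rate.kon, rel=1e-12)

    def test_regressor_bias_ordering(self, noiseless_steps, noiseless_isotherm):
        """Later steps bias the plain-c regressor low; delta_c is closer and
        the closed-form corrected regressor is nearly exact."""
        steps_sp, steps_ns = noiseless_steps
        kons = {reg: kon_from_slopes(steps_sp, steps_ns, noiseless_isotherm,
                                     regressor=reg).kon
                for reg in ("c", "delta_c", "corrected")}
        true = TRUE["kon1"]
        assert abs(kons["delta_c"] - true) < abs(kons["c"] - true)
        # both uncorrected regressors underestimate: on a doubling ladder the
        # increment is ~c/2 and saturation shrinks the late-step slopes
        assert 0 < kons["c"] < true
        assert true / 2 < kons["delta_c"] < true
        assert kons["corrected"] == pytest.approx(true, rel=0.03)

    def test_zero_slope_flags_no_signal(self):
        from nestedwell import NoBindingSignalError, StepFitResult

        iso = IsothermFit(Sigma_inf=1000.0, Kd_specific=27.6, Kd_nonspecific=200.0)
        steps = [StepFitResult(c=c, Sigma=0.0, Gamma=1e-3, slope0=0.0, sigma_prev=0.0,
                               residual_rms=0.0) for c in (5.0, 10.0)]
        with pytest.raises(NoBindingSignalError):
            kon_from_slopes([], steps, iso, regressor="c")


class TestExtractK2:
    def test_direct_values(self):
        iso = IsothermFit(Sigma_inf=1.0, Kd_specific=200 * 0.16 / 1.16,
                          Kd_nonspecific=200.0)
        k2, _ = extract_k2(iso)
        assert k2 == pytest.approx(0.16, rel=1e-12)
        iso2 = IsothermFit(Sigma_inf=1.0, Kd_specific=100.0, Kd_nonspecific=200.0)
        assert extract_k2(iso2)[0] == pytest.approx(1.0, rel=1e-12)

    def test_nonphysical_ordering_rejected(self):
        iso = IsothermFit(Sigma_inf=1.0, Kd_specific=250.0, Kd_nonspecific=200.0)
        with pytest.raises(NonphysicalSelectivityError):
            extract_k2(iso)

    def test_end_to_end_noiseless(self, noiseless_isotherm):
        k2, _ = extract_k2(noiseless_isotherm)
        assert k2 == pytest.approx(TRUE["K2"], abs=1e-3)

    def test_bootstrap_se_positive(self):
        sp, ns = generate_probe_pair(noise_sd=10.0, seed=9)
        iso = langmuir_pair_fit(fit_all_steps(sp), fit_all_steps(ns))
        k2, se_b = extract_k2(iso, bootstrap=True, n_boot=60, seed=2)
        _, se_d = extract_k2(iso)
        assert se_b > 0 and np.isfinite(se_b)
        # bootstrap and delta-method should agree in order of magnitude
        assert 0.2 < se_b / se_d < 5.0


class TestNWJointFit:
    def test_noiseless_rate_recovery(self):
        """Moderate inner exchange: all four rates identifiable to < 1%."""
        sp, ns = generate_probe_pair(kon2=1e-3, noise_sd=0.0, seed=2)
        fit = nw_joint_fit(sp, ns)
        r = fit.rates
        assert r.kon1 == pytest.approx(1.6e-5, rel=0.01)
        assert r.koff1 == pytest.approx(3.2e-3, rel=0.01)
        assert r.kon2 == pytest.approx(1e-3, rel=0.01)
        assert r.koff2 == pytest.approx(1.6e-4, rel=0.01)
        assert fit.Sigma_inf == pytest.approx(1000.0, rel=0.01)
        assert not fit.single_well_collapse

    def test_fast_exchange_regime_reported(self):
        sp, ns = generate_probe_pair(kon2=1.0, noise_sd=0.0, seed=3)
        fit = nw_joint_fit(sp, ns)
        assert fit.fast_exchange
        # in this regime only K2 is identifiable, not kon2 itself
        assert fit.K2 == pytest.approx(0.16, rel=0.05)

    def test_single_well_specific_trace_flagged(self):
        """If the 'specific' trace has no inner well, the model collapses."""
        from nestedwell import make_default_schedule

        sched = make_default_schedule()
        rates = RateSet(kon1=1.6e-5, koff1=3.2e-3)
        sp = generate_trace(rates, sched, noise_sd=0.0, probe_class="specific",
                            spot_id="sp")
        ns = generate_trace(rates, sched, noise_sd=0.0, probe_class="nonspecific",
                            spot_id="ns")
        fit = nw_joint_fit(sp, ns)
        assert fit.single_well_collapse or fit.kon2_lower_bound


class TestVantHoff:
    def test_noiseless_exact_inverse(self):
        series = generate_k2_temperature_series(dH=-12.8, dS=-38.7, rel_noise=0.0)
        fit = vant_hoff_fit(series)
        assert fit.dH == pytest.approx(-12.8, rel=1e-9)
        assert fit.dS == pytest.approx(-38.7, rel=1e-9)

    def test_constant_k2_gives_zero_enthalpy(self):
        series = [(T, 0.2) for T in (288.15, 295.0, 303.15, 310.15)]
        fit = vant_hoff_fit(series)
        assert fit.dH == pytest.approx(0.0, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(DataError):
            vant_hoff_fit([(288.15, 0.2), (303.15, 0.3)])
        with pytest.raises(DataError):
            vant_hoff_fit([(288.15, 0.2), (295.0, -0.1), (303.15, 0.3)])

    def test_noisy_recovery_simulation(self):
        """5% lognormal noise, 6 temperatures: mean recovered dH within
        1 kcal/mol of the generating value over 200 seeds."""
        dhs = []
        for seed in range(200):
            series = generate_k2_temperature_series(rel_noise=0.05, seed=seed)
            dhs.append(vant_hoff_fit(series).dH)
        assert abs(np.mean(dhs) - (-12.8)) < 1.0

    def test_dg_identity(self):
        """dG_at(T) = dH - T*dS = R*T*ln K2_model(T) over a temperature grid."""
        fit = ThermoFit(dH=-12.8, dS=-38.7)
        for T in np.linspace(280.0, 320.0, 9):
            assert fit.dG_at(T) == pytest.approx(
                delta_g(float(fit.k2_model(T)), T), abs=1e-12)


class TestScalarThermo:
    def test_delta_g_values(self):
        assert round(delta_g(0.16, 303.15), 1) == -1.1
        assert delta_g(1.0, 310.0) == 0.0
        assert delta_g(0.169, 303.15) == pytest.approx(-1.07, abs=0.005)
        with pytest.raises(InvalidParameterError):
            delta_g(-0.1, 300.0)

    def test_fraction_specific_values(self):
        assert 10 * fraction_specific(0.16) == pytest.approx(8.62, abs=0.005)
        assert fraction_specific(0.0) == 1.0
        assert fraction_specific(1.0) == 0.5
        with pytest.raises(InvalidParameterError):
            fraction_specific(-0.5)

    def test_delta_delta_g_values(self):
        assert delta_delta_g(30.0, 200.0, 303.15) == pytest.approx(1.14, abs=0.005)
        assert delta_delta_g(50.0, 50.0, 303.15) == 0.0
        assert delta_delta_g(25.0, 160.0, 303.15) == pytest.approx(1.12, abs=0.005)


class TestPipelineProperties:
    def test_consistency_langmuir_vs_joint_fit(self, noiseless_pair):
        """K2 from the equilibrium route agrees with the kinetic route."""
        sp, ns = noiseless_pair
        res = analyze_pair(sp, ns)
        joint = nw_joint_fit(sp, ns)
        assert res["K2"] == pytest.approx(joint.K2, rel=0.05)

    def test_recovered_kd_monotone_in_k2(self):
        """Effective Kd recovered by the pipeline grows with the generating K2."""
        kds = []
        for k2 in (0.08, 0.16, 0.32):
            sp, ns = generate_probe_pair(K2=k2, noise_sd=0.0, seed=4)
            kds.append(analyze_pair(sp, ns)["Kd_specific_nM"])
        assert kds[0] < kds[1] < kds[2]

    def test_noiseless_recovery_all_parameters(self, noiseless_pair):
        """Full pipeline on noiseless traces recovers the generating
        (kon, K1, Kd_eff, K2, Sigma_inf) within 5%."""
        sp, ns = noiseless_pair
        res = analyze_pair(sp, ns, regressor="corrected")
        assert res["Sigma_inf"] == pytest.approx(TRUE["sigma_inf"], rel=0.05)
        assert res["Kd_specific_nM"] == pytest.approx(TRUE_KD_EFF, rel=0.05)
        assert res["Kd_nonspecific_nM"] == pytest.approx(TRUE["K1"], rel=0.05)
        assert res["kon_per_s_per_nM"] == pytest.approx(TRUE["kon1"], rel=0.05)
        assert res["K2"] == pytest.approx(TRUE["K2"], rel=0.05)
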