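"""Per-curve chain: calibration, conversion, contact point, fit, QC."""

import dataclasses

import numpy as np
import pytest
from scipy.constants import Boltzmann

from forcemap import contact_mechanics as cm
from forcemap import curve_pipeline as cp
from forcemap import synthetic_data as sd
from forcemap.exceptions import (CalibrationError, ContactPointError,
                                 DomainError, FitError)

from conftest import calib_for, fit_synthetic_curve


def _rigid_curve(sens_nm_v=15.2, noise_sd_v=0.0, seed=0, offset_v=0.3,
                 n=400):
    """Approach over a rigid surface: slope 1 V per `sens` nm past contact."""
    z = np.linspace(2.0, -0.5, n)
    v = np.where(z < 0, -z * 1000.0 / sens_nm_v, 0.0) + offset_v
    if noise_sd_v > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd_v, n)
    return cp.ForceCurve(z, v, "V", np.array(["A"] * n))


class TestSensitivityCalibration:
    def test_exact_slope(self):
        assert cp.calibrate_sensitivity(_rigid_curve()) == pytest.approx(
            15.2, rel=1e-9)

    def test_noisy_slope_within_2pct(self):
        curve = _rigid_curve(noise_sd_v=0.01 * (500 / 15.2), seed=42)
        assert cp.calibrate_sensitivity(curve) == pytest.approx(15.2,
                                                                rel=0.02)

    def test_flat_curve_raises(self):
        z = np.linspace(2.0, -0.5, 400)
        flat = cp.ForceCurve(z, np.full(400, 0.3), "V", np.array(["A"] * 400))
        with pytest.raises(CalibrationError):
            cp.calibrate_sensitivity(flat)


class TestThermalSpringConstant:
    def test_equipartition_round_trip(self):
        k_true, temp = 0.018, 300.0
        sd_nm = np.sqrt(Boltzmann * temp / k_true) * 1e9
        trace = np.random.default_rng(7).normal(0.0, sd_nm, 100_000)
        k = cp.spring_constant_thermal(trace, temp)
        assert k == pytest.approx(k_true, rel=0.05)

    def test_doubling_variance_halves_k(self):
        trace = np.random.default_rng(1).normal(0.0, 0.5, 50_000)
        k1 = cp.spring_constant_thermal(trace, 300.0)
        k2 = cp.spring_constant_thermal(trace * np.sqrt(2), 300.0)
        assert k2 == pytest.approx(k1 / 2, rel=1e-9)

    def test_constant_trace_raises(self):
        with pytest.raises(CalibrationError):
            cp.spring_constant_thermal(np.full(1000, 1.3), 300.0)


class TestForceIndentationConversion:
    def test_rigid_substrate_indentation_near_zero(self, default_calib):
        curve = _rigid_curve(sens_nm_v=default_calib.sensitivity_nm_per_v)
        delta, force = cp.to_force_indentation(curve, default_calib, 0.0)
        # on a rigid surface deflection equals piezo travel: delta ~ 0
        assert np.max(np.abs(delta)) < 1e-6
        assert force.max() > 0

    def test_free_segment_force_near_zero(self, default_calib):
        curve, truth = sd.synthesize_curve(3.0, seed=5)
        calib = calib_for(truth)
        z, _ = curve.approach_arrays()
        j = truth["contact_index"]
        _, f_con = cp.to_force_indentation(curve, calib,
                                           truth["contact_height_um"])
        # baseline-subtracted force starts from ~zero at contact (the first
        # sample past contact sits within one 17 nm z-step of the surface,
        # so its force is a small fraction of the 1 nN set point)
        assert abs(f_con[0]) < 0.05

    def test_generator_round_trip(self, probe):
        e_true = 3.0
        curve, truth = sd.synthesize_curve(e_true, seed=5)
        calib = calib_for(truth)
        delta, force = cp.to_force_indentation(curve, calib,
                                               truth["contact_height_um"])
        keep = delta > 0.02  # skip the near-contact samples (delta ~ 0)
        model = cm.sneddon_force(delta[keep], cm.MaterialParams(e_true),
                                 probe)
        np.testing.assert_allclose(force[keep], model, rtol=5e-3, atol=2e-3)

    def test_missing_unit_tag_rejected(self):
        z = np.linspace(2.0, -0.5, 400)
        with pytest.raises(DomainError):
            cp.ForceCurve(z, np.zeros(400), "volts", np.array(["A"] * 400))


class TestContactPointEstimation:
    def test_noise_free_within_one_sample(self, probe):
        curve, truth = sd.synthesize_curve(2.0, seed=3)
        j, z0 = cp.estimate_contact_point(curve, calib_for(truth), probe)
        assert abs(j - truth["contact_index"]) <= 1

    def test_noisy_median_error_small(self, probe):
        errs = []
        for s in range(40):
            curve, truth = sd.synthesize_curve(2.0, seed=500 + s,
                                               noise_frac_setpoint=0.02)
            j, _ = cp.estimate_contact_point(curve, calib_for(truth), probe)
            errs.append(abs(j - truth["contact_index"]))
        assert np.median(errs) <= 3

    def test_entirely_in_contact_raises(self, default_calib, probe):
        # steep contact from the very first sample: no free baseline
        z = np.linspace(2.0, -0.5, 400)
        v = (2.0 - z) * 1000.0 / 15.2
        curve = cp.ForceCurve(z, v, "V", np.array(["A"] * 400))
        with pytest.raises(ContactPointError):
            cp.estimate_contact_point(curve, default_calib, probe)

    def test_no_contact_raises(self, default_calib, probe):
        z = np.linspace(2.0, -0.5, 400)
        curve = cp.ForceCurve(z, np.full(400, 0.1), "V",
                              np.array(["A"] * 400))
        with pytest.raises(ContactPointError):
            cp.estimate_contact_point(curve, default_calib, probe)


class TestYoungModulusFit:
    @pytest.mark.parametrize("e_true", [1.0, 2.0, 4.0, 8.0])
    def test_noise_free_recovery_within_1pct(self, e_true):
        fit, j, truth = fit_synthetic_curve(e_true, seed=11)
        assert fit.young_modulus_kpa == pytest.approx(e_true, rel=0.01)
        assert abs(j - truth["contact_index"]) <= 1

    def test_robust_and_ls_agree_on_clean_curve(self):
        fr, _, _ = fit_synthetic_curve(4.0, seed=11, robust=True)
        fl, _, _ = fit_synthetic_curve(4.0, seed=11, robust=False)
        assert fr.young_modulus_kpa == pytest.approx(fl.young_modulus_kpa,
                                                     rel=0.01)

    def test_robust_resists_gross_outliers(self, probe):
        r_err, l_err = [], []
        for s in range(30):
            curve, truth = sd.synthesize_curve(
                4.0, seed=300 + s, noise_frac_setpoint=0.02,
                outlier_frac=0.05)
            calib = calib_for(truth)
            j = truth["contact_index"]
            fr = cp.fit_young_modulus(curve, calib, probe, j, robust=True,
                                      set_point_nn=1.0)
            fl = cp.fit_young_modulus(curve, calib, probe, j, robust=False,
                                      set_point_nn=1.0)
            r_err.append(abs(fr.young_modulus_kpa / 4.0 - 1))
            l_err.append(abs(fl.young_modulus_kpa / 4.0 - 1))
        assert np.median(r_err) <= 0.05
        assert np.median(l_err) > np.median(r_err)

    def test_short_contact_region_raises(self, default_calib, probe):
        curve, truth = sd.synthesize_curve(2.0, seed=3)
        calib = calib_for(truth)
        z, _ = curve.approach_arrays()
        with pytest.raises(FitError):
            # contact placed at the very last sample: almost no contact side
            cp.fit_young_modulus(curve, calib, probe, len(z) - 2,
                                 refine_contact=False)

    def test_substrate_curve_exceeds_threshold(self, probe):
        curve, truth = sd.synthesize_curve(2000.0, seed=3,
                                           surface_height_um=0.0)
        fit = cp.process_curve(curve, calib_for(truth), probe,
                               set_point_nn=1.0)
        assert fit.young_modulus_kpa > 10.0
        assert "substrate_stiff" in fit.qc_flags and not fit.accepted


def _clean_fit(**overrides):
    base = dict(young_modulus_kpa=5.0, contact_point_height_um=4.0,
                contact_point_index=100, max_indentation_um=0.5,
                force_at_deepest_fitted_nn=1.0, rms_residual_nn=0.01,
                max_abs_residual_nn=0.02, set_point_nn=1.0,
                n_contact_samples=30, accepted=True)
    base.update(overrides)
    return cp.IndentationFit(**base)


class TestQCFilters:
    def test_substrate_rule(self):
        out = cp.apply_qc_filters(_clean_fit(young_modulus_kpa=12.0))
        assert out.qc_flags == frozenset({"substrate_stiff"})
        assert not out.accepted

    def test_over_indentation_rule(self):
        out = cp.apply_qc_filters(_clean_fit(max_indentation_um=2.5))
        assert out.qc_flags == frozenset({"over_indented"})

    def test_battery_exactly_three_accepted(self):
        # one violation per rule + three clean fits -> exactly 3 accepted
        battery = [
            _clean_fit(young_modulus_kpa=12.0),          # substrate_stiff
            _clean_fit(max_indentation_um=2.5),          # over_indented
            _clean_fit(force_at_deepest_fitted_nn=0.7),  # short_fit
            _clean_fit(rms_residual_nn=0.06),            # poor_rms
            _clean_fit(max_abs_residual_nn=0.08),        # poor_maxdev
            _clean_fit(), _clean_fit(), _clean_fit(),
        ]
        expected = ["substrate_stiff", "over_indented", "short_fit",
                    "poor_rms", "poor_maxdev", None, None, None]
        out = [cp.apply_qc_filters(f) for f in battery]
        assert sum(f.accepted for f in out) == 3
        for fit, want in zip(out, expected):
            assert fit.qc_flags == (frozenset({want}) if want
                                    else frozenset())

    def test_idempotent(self):
        once = cp.apply_qc_filters(_clean_fit(young_modulus_kpa=12.0))
        twice = cp.apply_qc_filters(once)
        assert once.qc_flags == twice.qc_flags
        assert once.accepted == twice.accepted

    def test_rules_individually_toggleable(self):
        fit = _clean_fit(young_modulus_kpa=12.0, max_indentation_um=2.5)
        cfg = cp.FilterConfig(ym_substrate_threshold_kpa=None)
        out = cp.apply_qc_filters(fit, cfg)
        assert out.qc_flags == frozenset({"over_indented"})

    def test_errored_fit_stays_rejected(self):
        fit = cp.IndentationFit(error="no contact")
        out = cp.apply_qc_filters(fit)
        assert not out.accepted and out.qc_flags == frozenset()

    def test_config_validation(self):
        with pytest.raises(DomainError):
            cp.FilterConfig(min_force_fraction=1.5)
        with pytest.raises(DomainError):
            cp.FilterConfig(ym_substrate_threshold_kpa=-2.0)


class TestForceCurveValidation:
    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            cp.ForceCurve(np.zeros(100), np.zeros(99), "V",
                          np.array(["A"] * 100))

    def test_short_segment(self):
        with pytest.raises(DomainError):
            cp.ForceCurve(np.zeros(30), np.zeros(30), "V",
                          np.array(["A"] * 30))
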