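import numpy as np
import pytest

from forcemap import contact_mechanics as cm
from forcemap import curve_pipeline as cp
from forcemap import synthetic_data as sd

PAPER_R_UM = 3.31


@pytest.fixture(scope="session")
def probe():
    return cm.ProbeGeometry(radius_um=PAPER_R_UM)


@pytest.fixture(scope="session")
def default_calib():
    return cp.CalibrationRecord(sensitivity_nm_per_v=15.2,
                                spring_constant_n_m=0.018)


def calib_for(truth) -> cp.CalibrationRecord:
    spec = truth["spec"]
    return cp.CalibrationRecord(spec.sensitivity_nm_v,
                                spec.spring_constant_n_m)


def fit_synthetic_curve(e_kpa, seed, noise=0.0, robust=True, **kwargs):
    """Synthesize one curve and run the full per-curve chain on it."""
    curve, truth = sd.synthesize_curve(e_kpa, seed=seed,
                                       noise_frac_setpoint=noise, **kwargs)
    calib = calib_for(truth)
    probe = cm.ProbeGeometry(truth["spec"].probe_radius_um)
    j, _ = cp.estimate_contact_point(curve, calib, probe)
    fit = cp.fit_young_modulus(curve, calib, probe, j, robust=robust,
                               set_point_nn=truth["spec"].set_point_nn)
    return fit, j, truth
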