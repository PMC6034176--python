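"""Per-curve processing: calibration, force conversion, contact-point
estimation, robust Young's-modulus fitting and the five-rule QC cascade.

The processing chain for one force-distance curve (approach segment only):

1. volts -> force via the deflection sensitivity (nm/V) and cantilever
   spring constant (N/m): F = k * sens * (V - baseline).
2. a straight-line baseline is fitted to the free (non-contact) part of the
   approach and subtracted.
3. the contact point z0 is located by an exhaustive scan over candidate
   samples: each candidate splits the segment into a free side (baseline
   refit) and a contact side (one-parameter Sneddon fit); candidates are
   scored by the median absolute force residual of the contact side and the
   minimizer wins (smallest index on ties).  The winning index is then
   refined continuously within +/- 1 sample, because the z-sampling grid
   (~17 nm at 2 kHz / 33.3 um/s) is coarse relative to the indentation
   depths and pure sample-grid contact points bias E.
4. E is estimated on the contact side by either least squares or a robust
   objective (exact minimizer of the median absolute residual over E; the
   residual is piecewise linear in E so the global minimum sits at one of
   the per-sample ratios F_i / C_i).  The robust path is the default.
5. the QC cascade flags fits that are substrate-stiff (E > 10 kPa), over-
   indented (> 2 um), short (force at the deepest fitted point < 80% of the
   set point), or poorly modelled (RMS residual > 5%, max deviation > 7% of
   the set point); a fit is accepted iff no flag is raised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann
from scipy.optimize import minimize_scalar

from . import contact_mechanics as cm
from .exceptions import (CalibrationError, ContactPointError, DomainError,
                         FitError)

__all__ = [
    "ForceCurve",
    "CalibrationRecord",
    "IndentationFit",
    "FilterConfig",
    "QC_FLAGS",
    "calibrate_sensitivity",
    "spring_constant_thermal",
    "to_force_indentation",
    "estimate_contact_point",
    "fit_young_modulus",
    "apply_qc_filters",
    "process_curve",
    "fit_force_map",
    "fits_to_table",
]

SEG_APPROACH = "A"
SEG_RETRACT = "R"

#: The five QC rules, in the order the cascade reports them.
QC_FLAGS = ("substrate_stiff", "over_indented", "short_fit", "poor_rms",
            "poor_maxdev")

_MIN_SEGMENT_SAMPLES = 50


@dataclass
class ForceCurve:
    """One sampled force-distance record at a grid point.

    ``piezo_height_um`` decreases along the approach (decreasing tip-sample
    distance); ``deflection`` is tagged with its unit ("V" for raw
    photodiode volts, "nm" for pre-converted deflection).
    """

    piezo_height_um: np.ndarray
    deflection: np.ndarray
    deflection_unit: str
    segment: np.ndarray  # per-sample "A" / "R"
    sample_rate_hz: float = 2000.0
    grid_index: tuple = (0, 0)
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.piezo_height_um = np.asarray(self.piezo_height_um, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        self.segment = np.asarray(self.segment)
        if self.deflection_unit not in ("V", "nm"):
            raise DomainError(
                f"deflection unit tag must be 'V' or 'nm', got "
                f"{self.deflection_unit!r}")
        n = len(self.piezo_height_um)
        if len(self.deflection) != n or len(self.segment) != n:
            raise DomainError("curve arrays must have equal length")
        for seg in np.unique(self.segment):
            if np.count_nonzero(self.segment == seg) < _MIN_SEGMENT_SAMPLES:
                raise DomainError(
                    f"segment {seg!r} has fewer than "
                    f"{_MIN_SEGMENT_SAMPLES} samples")

    @property
    def approach(self) -> np.ndarray:
        """Boolean mask of the approach samples."""
        return self.segment == SEG_APPROACH

    def approach_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.approach
        if not m.any():
            raise DomainError("curve has no approach segment")
        return self.piezo_height_um[m], self.deflection[m]


@dataclass(frozen=True)
class CalibrationRecord:
    """Deflection sensitivity (nm/V) and spring constant (N/m)."""

    sensitivity_nm_per_v: float
    spring_constant_n_m: float
    temperature_k: float = 310.15

    def __post_init__(self) -> None:
        if self.sensitivity_nm_per_v <= 0:
            raise DomainError("sensitivity must be positive")
        if self.spring_constant_n_m <= 0:
            raise DomainError("spring constant must be positive")

    @property
    def nn_per_volt(self) -> float:
        """Force per volt of baseline-subtracted deflection: k * sens."""
        # N/m * nm/V = nN/V
        return self.spring_constant_n_m * self.sensitivity_nm_per_v


@dataclass
class IndentationFit:
    """Result of fitting one approach curve with the Sneddon sphere model."""

    young_modulus_kpa: float = np.nan
    contact_point_height_um: float = np.nan
    contact_point_index: int = -1
    max_indentation_um: float = np.nan
    force_at_deepest_fitted_nn: float = np.nan
    rms_residual_nn: float = np.nan
    max_abs_residual_nn: float = np.nan
    set_point_nn: float = np.nan
    n_contact_samples: int = 0
    grid_index: tuple = (0, 0)
    qc_flags: frozenset = frozenset()
    accepted: bool = False
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        """Fit produced a modulus (QC may still reject it)."""
        return self.error is None and np.isfinite(self.young_modulus_kpa)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the QC cascade; ``None`` disables a rule.

    Defaults follow the study's cascade: 10 kPa substrate threshold, 2 um
    maximum indentation, 80% minimum force fraction at the deepest fitted
    point, 5% RMS and 7% maximum deviation relative to the set point.
    """

    ym_substrate_threshold_kpa: Optional[float] = 10.0
    max_indentation_um: Optional[float] = 2.0
    min_force_fraction: Optional[float] = 0.80
    max_rms_fraction: Optional[float] = 0.05
    max_dev_fraction: Optional[float] = 0.07

    def __post_init__(self) -> None:
        for name in ("ym_substrate_threshold_kpa", "max_indentation_um"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive")
        for name in ("min_force_fraction", "max_rms_fraction",
                     "max_dev_fraction"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise DomainError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_sensitivity(hard_surface_curve: ForceCurve) -> float:
    """Deflection sensitivity (nm/V) from a rigid-substrate approach curve.

    On an effectively rigid surface the cantilever deflection equals the
    piezo travel past contact, so the contact part of deflection(V) vs
    piezo height is a straight line of slope -1/sensitivity.  The slope is
    taken by linear regression over the samples in the upper half of the
    deflection excursion (clearly in contact).
    """
    if hard_surface_curve.deflection_unit != "V":
        raise CalibrationError("sensitivity calibration needs raw volts")
    z, v = hard_surface_curve.approach_arrays()
    n = len(v)
    nb = max(20, n // 4)
    coef = np.polyfit(z[:nb], v[:nb], 1)
    resid = v - np.polyval(coef, z)
    sigma = float(np.std(resid[:nb]))
    excursion = float(resid.max())
    if excursion < max(6.0 * sigma, 1e-6):
        raise CalibrationError("no contact region detected on the curve")
    contact = resid > 0.5 * excursion
    if np.count_nonzero(contact) < 5:
        raise CalibrationError("contact region too short for a slope fit")
    slope_v_per_um = np.polyfit(z[contact], v[contact], 1)[0]
    if slope_v_per_um == 0:
        raise CalibrationError("degenerate contact slope")
    return abs(1.0 / slope_v_per_um) * 1000.0  # um/V -> nm/V


def spring_constant_thermal(deflection_trace_nm: np.ndarray,
                            temperature_k: float = 310.15) -> float:
    """Spring constant (N/m) from free thermal fluctuations (equipartition).

    k = k_B T / var(d) with the trace mean-detrended; the simple
    equipartition estimate without mode-shape corrections.
    """
    d = np.asarray(deflection_trace_nm, dtype=float)
    if temperature_k <= 0:
        raise DomainError("temperature must be positive")
    var_m2 = float(np.var(d - d.mean())) * 1e-18
    if var_m2 <= 0:
        raise CalibrationError("deflection trace has zero variance")
    return Boltzmann * temperature_k / var_m2


# ---------------------------------------------------------------------------
# force / indentation conversion
# ---------------------------------------------------------------------------

def _approach_force_raw(curve: ForceCurve, calib: CalibrationRecord):
    """(z_um, force_nN_without_baseline_removal) over the approach."""
    z, d = curve.approach_arrays()
    if curve.deflection_unit == "V":
        f = calib.nn_per_volt * d
    else:  # nm
        f = calib.spring_constant_n_m * d  # N/m * nm = nN
    return z, f


def _baseline(z: np.ndarray, f: np.ndarray, j_split: int,
              guard: int = 3) -> np.ndarray:
    """Linear baseline coefficients fitted to the free side [0, j_split)."""
    j = max(j_split - guard, 10)
    j = min(j, len(z))
    if j < 5:
        raise ContactPointError("free region too short for a baseline fit")
    return np.polyfit(z[:j], f[:j], 1)


def to_force_indentation(curve: ForceCurve, calib: CalibrationRecord,
                         z0: float | int,
                         baseline_coef: Optional[np.ndarray] = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Convert the approach segment to (indentation um, force nN) pairs.

    ``z0`` is the contact point, given either as a sample index into the
    approach segment or directly as a piezo height (um).  Indentation is
    piezo travel past contact minus cantilever bending:
    delta_i = (z0 - z_i) - d_i, with d_i the baseline-subtracted deflection
    expressed as a length, so delta = 0 at the contact point.  Only
    contact-side samples (z_i <= z0) are returned.
    """
    z, f_raw = _approach_force_raw(curve, calib)
    if isinstance(z0, (int, np.integer)):
        if not 0 <= z0 < len(z):
            raise DomainError("contact index outside the approach segment")
        z0_h = float(z[z0])
        j_split = int(z0)
    else:
        z0_h = float(z0)
        j_split = int(np.searchsorted(-z, -z0_h))
    if baseline_coef is None:
        baseline_coef = _baseline(z, f_raw, j_split)
    f = f_raw - np.polyval(baseline_coef, z)
    contact = z <= z0_h
    d_um = f / (calib.spring_constant_n_m * 1000.0)  # nN / (nN/um)
    delta = (z0_h - z[contact]) - d_um[contact]
    return delta, f[contact]


# ---------------------------------------------------------------------------
# contact-point estimation ("exhaustive scan + robust score")
# ---------------------------------------------------------------------------

def _prefix_linfit(z: np.ndarray, f: np.ndarray):
    """Slope/intercept of the LSQ line on every prefix [0..j], vectorized."""
    n = np.arange(1, len(z) + 1, dtype=float)
    sz = np.cumsum(z)
    sf = np.cumsum(f)
    szz = np.cumsum(z * z)
    szf = np.cumsum(z * f)
    denom = n * szz - sz * sz
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n * szf - sz * sf) / denom
        intercept = (sf - slope * sz) / n
    slope[denom <= 0] = 0.0
    intercept[denom <= 0] = f[0]
    return slope, intercept


def estimate_contact_point(curve: ForceCurve, calib: CalibrationRecord,
                           probe: cm.ProbeGeometry, nu: float = 0.5,
                           bracket_frac: float = 0.10,
                           min_contact_samples: int = 4,
                           min_free_samples: int = 20,
                           ) -> tuple[int, float]:
    """Exhaustive contact-point scan over the approach segment.

    Every candidate split index inside a bracket around the first force
    excursion (3x the free-side noise SD, widened by +/- ``bracket_frac``
    of the segment length) is evaluated: the free side gets a linear
    baseline, the contact side a one-parameter Sneddon fit, and the
    candidate with the smallest median absolute contact-side residual wins
    (smallest index on ties).  Deterministic for fixed input.

    Returns (index into the approach segment, piezo height um).
    """
    z, f_raw = _approach_force_raw(curve, calib)
    n = len(z)
    r = probe.radius_um
    k_nn_per_um = calib.spring_constant_n_m * 1000.0
    e_factor = r * r * cm.NN_PER_KPA_UM2 / (1.0 - nu**2)  # C = e_factor * F

    # provisional baseline on the first quarter; noise level from there
    nb = max(min_free_samples, n // 4)
    coef0 = np.polyfit(z[:nb], f_raw[:nb], 1)
    res0 = f_raw - np.polyval(coef0, z)
    sigma = float(np.std(res0[:nb]))
    thr = 3.0 * max(sigma, 1e-9)
    above = res0 > thr
    # sustained excursion: above threshold, and so are >= 3 of the next 4
    # samples (windows are clipped at the end of the segment, so a contact
    # in the last few samples — a stiff dish point — is still found)
    csum = np.concatenate([[0], np.cumsum(above.astype(int))])
    win_stop = np.minimum(np.arange(n) + 5, n)
    win_len = win_stop - np.arange(n)
    n_above = csum[win_stop] - csum[np.arange(n)]
    sustained = np.flatnonzero(above & (n_above >= np.minimum(4, win_len)))
    if sustained.size == 0:
        raise ContactPointError("no contact region found on the approach")
    j_exc = int(sustained[0])
    if j_exc <= min_free_samples:
        raise ContactPointError(
            "approach appears to be entirely in contact (no free baseline)")

    w = max(5, int(round(bracket_frac * n)))
    lo = max(min_free_samples, j_exc - w)
    hi = min(n - min_contact_samples, j_exc + w)
    if hi <= lo:
        raise ContactPointError("contact bracket collapsed")
    cand = np.arange(lo, hi)

    slope, intercept = _prefix_linfit(z, f_raw)
    # residual force matrix per candidate: f_raw - baseline_j(z)
    fres = f_raw[None, :] - (slope[cand, None] * z[None, :]
                             + intercept[cand, None])
    in_contact = np.arange(n)[None, :] > cand[:, None]
    d_um = fres / k_nn_per_um
    delta = (z[cand][:, None] - z[None, :]) - d_um
    delta = np.where(in_contact, delta, 0.0)
    pos = in_contact & (delta > 0)

    force_hat = np.zeros_like(delta)
    if pos.any():
        force_hat[pos] = cm.dimensionless_sneddon_force(delta[pos] / r)
    c = e_factor * force_hat
    c = np.where(in_contact, c, 0.0)
    fres_c = np.where(in_contact, fres, 0.0)
    denom = np.sum(c * c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_ls = np.sum(fres_c * c, axis=1) / denom
    # total L1 misfit of the piecewise model (baseline left of the split,
    # Sneddon right of it) over the same fixed window [lo, n) for every
    # candidate, so scores are directly comparable: a candidate cannot
    # "win" by absorbing well-fit free samples into its contact side.
    window = np.arange(n)[None, :] >= lo
    resid = np.abs(fres - np.where(in_contact, e_ls[:, None] * c, 0.0))
    score = np.where(window, resid, 0.0).sum(axis=1)
    n_pos = pos.sum(axis=1)
    bad = (n_pos < min_contact_samples) | ~np.isfinite(score) | \
        (denom <= 0) | (e_ls <= 0)
    score = np.where(bad, np.inf, score)
    if not np.isfinite(score).any():
        raise ContactPointError(
            "no candidate contact point admitted a valid fit")
    j_best = int(cand[int(np.argmin(score))])
    return j_best, float(z[j_best])


# ---------------------------------------------------------------------------
# Young's-modulus fit
# ---------------------------------------------------------------------------

_HUBER_C = 1.345  # 95% Gaussian efficiency


def _huber_rho(r: np.ndarray, scale: float) -> np.ndarray:
    a = np.abs(r)
    cut = _HUBER_C * scale
    return np.where(a <= cut, 0.5 * r * r, cut * (a - 0.5 * cut))


def _fit_e_at_z0(z: np.ndarray, f: np.ndarray, z0: float, r: float,
                 k_nn_per_um: float, e_factor: float, robust: bool,
                 score_ref_um: Optional[float] = None):
    """E and score for a fixed continuous contact height z0.

    Returns (E_kpa, score, contact_mask, c_values).  The robust path is a
    Huber M-estimate of the slope E of F = E * C: starting from the median
    of the per-sample ratios F_i / C_i, iteratively reweighted least
    squares with the Huber weight at scale 1.4826 * MAD — resistant to
    gross outlier samples yet ~95% efficient under pure Gaussian noise.
    The score is the profile objective minimized during the continuous
    contact-point refinement: total L1 misfit (robust) or SSE (least
    squares) of the piecewise model (zero force above contact, Sneddon
    below) over the fixed window of samples below ``score_ref_um``, so
    scores at different trial z0 are computed on the same sample set.
    """
    contact = z < z0
    d_um = f / k_nn_per_um
    delta = (z0 - z[contact]) - d_um[contact]
    fh = np.zeros_like(delta)
    pos = delta > 0
    if pos.any():
        fh[pos] = cm.dimensionless_sneddon_force(delta[pos] / r)
    c = e_factor * fh
    fc = f[contact]
    ref = z0 if score_ref_um is None else score_ref_um
    f_free = f[(z < ref) & ~contact]  # window samples the model leaves at 0
    denom = float(np.sum(c * c))
    if denom <= 0 or np.count_nonzero(pos) == 0:
        return np.nan, np.inf, contact, c
    if not robust:
        e = float(np.sum(fc * c) / denom)
        score = float(np.sum((fc - e * c) ** 2) + np.sum(f_free**2))
        return e, score, contact, c
    ratios = fc[pos] / c[pos]
    ratios = ratios[ratios > 0]
    if ratios.size == 0:
        return np.nan, np.inf, contact, c
    e = float(np.median(ratios))
    for _ in range(12):
        resid = fc - e * c
        scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        scale = max(scale, 1e-12)
        w = np.minimum(1.0, _HUBER_C * scale / np.maximum(np.abs(resid),
                                                          1e-300))
        wd = float(np.sum(w * c * c))
        if wd <= 0:
            break
        e_new = float(np.sum(w * fc * c) / wd)
        done = abs(e_new - e) <= 1e-10 * max(abs(e), 1e-30)
        e = e_new
        if done:
            break
    if e <= 0:
        return np.nan, np.inf, contact, c
    # winsorized-L1 profile score: residuals are clipped at 5x the robust
    # noise scale so a gross outlier contributes a constant (zero gradient)
    # and cannot steer the contact-point refinement; the clip floor keeps
    # the score sharp on noise-free data.
    resid = np.concatenate([fc - e * c, f_free])
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    clip = max(5.0 * sigma, 1e-6)
    score = float(np.sum(np.minimum(np.abs(resid), clip)))
    return e, score, contact, c


def fit_young_modulus(curve: ForceCurve, calib: CalibrationRecord,
                      probe: cm.ProbeGeometry, z0: tuple[int, float] | int,
                      robust: bool = True, nu: float = 0.5,
                      set_point_nn: Optional[float] = None,
                      min_contact_samples: int = 4,
                      refine_contact: bool = True,
                      refine_window: int = 6) -> IndentationFit:
    """Fit E on the contact side of the approach segment.

    ``z0`` is the discrete contact estimate (index, or (index, height)).
    The contact height is refined continuously within ``refine_window``
    samples of the estimate (bounded scalar minimization of the fit
    objective, making the final fit a joint continuous (z0, E) fit),
    because the piezo sampling grid (~17 nm) is coarse relative to the
    indentation depth and a sample-grid contact point biases E.
    ``robust=True`` (default) minimizes the median absolute residual,
    ``robust=False`` ordinary least squares.
    """
    z, f_raw = _approach_force_raw(curve, calib)
    j = int(z0[0]) if isinstance(z0, tuple) else int(z0)
    if not 0 <= j < len(z):
        raise FitError("contact index outside the approach segment")
    coef = _baseline(z, f_raw, j, guard=refine_window + 2)
    f = f_raw - np.polyval(coef, z)
    r = probe.radius_um
    k_nn_per_um = calib.spring_constant_n_m * 1000.0
    e_factor = r * r * cm.NN_PER_KPA_UM2 / (1.0 - nu**2)

    z0_h = float(z[j])
    if refine_contact:
        w = max(1, int(refine_window))
        z_lo = z[min(j + w, len(z) - 1)]
        z_hi = z[max(j - w, 0)]
        if z_hi > z_lo:
            def _profile(zz: float) -> float:
                s = _fit_e_at_z0(z, f, zz, r, k_nn_per_um, e_factor,
                                 robust, score_ref_um=z_hi)[1]
                return s if np.isfinite(s) else 1e30  # keep Brent finite

            res = minimize_scalar(_profile, bounds=(z_lo, z_hi),
                                  method="bounded", options={"xatol": 1e-7})
            z0_h = float(res.x)

    e, _, contact, c = _fit_e_at_z0(z, f, z0_h, r, k_nn_per_um, e_factor,
                                    robust)
    n_contact = int(np.count_nonzero(contact))
    if n_contact < min_contact_samples:
        raise FitError(
            f"only {n_contact} contact samples "
            f"(minimum {min_contact_samples}); fitted region too short")
    if not np.isfinite(e) or e <= 0:
        raise FitError("non-positive or undefined Young's modulus estimate")

    fc = f[contact]
    model = e * c
    resid = fc - model
    d_um = f / k_nn_per_um
    delta = (z0_h - z[contact]) - d_um[contact]
    i_deep = int(np.argmax(delta))
    sp = float(set_point_nn) if set_point_nn is not None else float(fc.max())
    return IndentationFit(
        young_modulus_kpa=float(e),
        contact_point_height_um=z0_h,
        contact_point_index=j,
        max_indentation_um=float(delta[i_deep]),
        force_at_deepest_fitted_nn=float(fc[i_deep]),
        rms_residual_nn=float(np.sqrt(np.mean(resid**2))),
        max_abs_residual_nn=float(np.max(np.abs(resid))),
        set_point_nn=sp,
        n_contact_samples=n_contact,
        grid_index=tuple(curve.grid_index),
        qc_flags=frozenset(),
        accepted=True,
    )


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def apply_qc_filters(fit: IndentationFit,
                     config: FilterConfig = FilterConfig()) -> IndentationFit:
    """Apply the five-rule cascade; returns a new fit with flags set.

    Pure flagging: flags are recomputed from the fit fields on every call,
    so the operation is idempotent and rule-order independent; a rule whose
    threshold is ``None`` is disabled.
    """
    if not fit.ok:
        return dataclasses.replace(fit, qc_flags=frozenset(), accepted=False)
    flags = set()
    sp = fit.set_point_nn
    if (config.ym_substrate_threshold_kpa is not None
            and fit.young_modulus_kpa > config.ym_substrate_threshold_kpa):
        flags.add("substrate_stiff")
    if (config.max_indentation_um is not None
            and fit.max_indentation_um > config.max_indentation_um):
        flags.add("over_indented")
    if (config.min_force_fraction is not None
            and fit.force_at_deepest_fitted_nn < config.min_force_fraction * sp):
        flags.add("short_fit")
    if (config.max_rms_fraction is not None
            and fit.rms_residual_nn > config.max_rms_fraction * sp):
        flags.add("poor_rms")
    if (config.max_dev_fraction is not None
            and fit.max_abs_residual_nn > config.max_dev_fraction * sp):
        flags.add("poor_maxdev")
    return dataclasses.replace(fit, qc_flags=frozenset(flags),
                               accepted=not flags)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def process_curve(curve: ForceCurve, calib: CalibrationRecord,
                  probe: cm.ProbeGeometry,
                  config: FilterConfig = FilterConfig(),
                  robust: bool = True, nu: float = 0.5,
                  set_point_nn: Optional[float] = None,
                  min_contact_samples: int = 4) -> IndentationFit:
    """Full chain for one curve; failures become an errored (rejected) fit."""
    try:
        j, _ = estimate_contact_point(
            curve, calib, probe, nu=nu,
            min_contact_samples=min_contact_samples)
        fit = fit_young_modulus(
            curve, calib, probe, j, robust=robust, nu=nu,
            set_point_nn=set_point_nn,
            min_contact_samples=min_contact_samples)
    except (ContactPointError, FitError, DomainError) as exc:
        return IndentationFit(grid_index=tuple(curve.grid_index),
                              accepted=False, error=str(exc))
    return apply_qc_filters(fit, config)


def fit_force_map(force_map, config: FilterConfig = FilterConfig(),
                  robust: bool = True, nu: float = 0.5,
                  min_contact_samples: int = 4,
                  progress: bool = False) -> pd.DataFrame:
    """Fit every curve of a ForceMap archive; one table row per grid point.

    Probe, calibration and set point are taken from the archive metadata.
    Column layout matches :func:`fits_to_table`.
    """
    probe = force_map.probe()
    calib = force_map.calibration()
    sp = force_map.set_point_nn
    fits = []
    items = sorted(force_map.curves.items())
    for idx, ((row, col), curve) in enumerate(items):
        fit = process_curve(curve, calib, probe, config=config, robust=robust,
                            nu=nu, set_point_nn=sp,
                            min_contact_samples=min_contact_samples)
        fits.append(fit)
        if progress and idx % 256 == 0:
            print(f"  fitted {idx + 1}/{len(items)} curves", flush=True)
    return fits_to_table(fits)


def fits_to_table(fits: list[IndentationFit]) -> pd.DataFrame:
    """Flat per-curve results table (one row per grid point)."""
    rows = []
    for f in fits:
        rows.append({
            "row": f.grid_index[0],
            "col": f.grid_index[1],
            "E_kPa": f.young_modulus_kpa,
            "z0_um": f.contact_point_height_um,
            "z0_index": f.contact_point_index,
            "max_indentation_um": f.max_indentation_um,
            "force_deepest_nN": f.force_at_deepest_fitted_nn,
            "rms_residual_nN": f.rms_residual_nn,
            "max_abs_residual_nN": f.max_abs_residual_nn,
            "set_point_nN": f.set_point_nn,
            "n_contact": f.n_contact_samples,
            "flags": ";".join(sorted(f.qc_flags)),
            "accepted": bool(f.accepted),
            "error": f.error or "",
        })
    return pd.DataFrame(rows)
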