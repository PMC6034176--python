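"""Synthetic force-map generator with known ground truth.

A phantom cell — a spherical-cap body with an optional taller nucleus dome,
a soft nucleus, a stiffer perinuclear ring and stiff fiber lines over a
rigid dish — is rendered onto a grid, and for every grid point a complete
approach/retract force-distance curve is simulated with the same contact
law the analysis fits (the simulator and the fitter share *only*
:mod:`forcemap.contact_mechanics`; the fitter never sees ground truth).

The forward model per sample: the piezo ramps down at constant speed; past
contact the travel ``s`` splits into indentation ``delta`` and cantilever
bending ``d = P/k`` with ``P`` the Sneddon sphere load at the local true
modulus; the recorded photodiode signal is ``d / sensitivity`` plus a
linear baseline (offset + tilt) and additive Gaussian deflection noise.
The approach stops at the first sample whose measured force reaches the
set point (curves that never reach it are flagged).  The piezo ramp is
allowed to run 1 um below the nominal dish plane so that dish points —
where almost all travel goes into bending — can reach the set point.

Post-thaw softening is modelled as a multiplicative modulus decay
``E(t) = E0 * (f_inf + (1 - f_inf) * exp(-t / tau))`` applied to every
cell compartment (the dish does not decay).

Defaults mirror the study's acquisition: R = 3.31 um colloidal probe, set
point 1 nN, Z-length 15 um, 2 kHz sampling at 33.3 um/s, sensitivity
15.2 nm/V, spring constant 18 mN/m, 64 x 64 grid on 75-100 um.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import contact_mechanics as cm
from .archive import ForceMap, write_archive
from .curve_pipeline import SEG_APPROACH, SEG_RETRACT, ForceCurve
from .exceptions import DomainError

__all__ = ["FiberSpec", "PhantomSpec", "render_phantom", "simulate_force_map",
           "synthesize_curve", "dmso_like", "peg_like"]

_SCHEMA = "phantom-spec/1"


@dataclass(frozen=True)
class FiberSpec:
    """A stiff actin-fiber line: endpoints (um, relative to cell center)."""

    x0_um: float
    y0_um: float
    x1_um: float
    y1_um: float
    width_um: float = 2.0
    e_kpa: float = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth geometry, elasticity, noise and decay of a phantom map."""

    seed: int  # mandatory: every archive is reproducible from it
    grid_shape: tuple = (64, 64)
    extent_um: tuple = (75.0, 75.0)

    # geometry: spherical-cap body + optional nucleus dome, centered
    cell_footprint_radius_um: float = 30.0
    cell_peak_height_um: float = 2.5
    nucleus_radius_um: float = 12.0
    nucleus_bump_height_um: float = 2.5

    # elasticity field (kPa)
    nucleus_e_kpa: float = 0.8
    periphery_e_kpa: float = 1.6
    ring_radius_um: Optional[float] = 14.0
    ring_width_um: float = 4.0
    ring_e_kpa: float = 2.5
    fibers: tuple = ()
    substrate_e_kpa: float = 2000.0

    # noise and artifacts
    noise_frac_setpoint: float = 0.02
    baseline_offset_v: float = 0.01
    baseline_tilt_v_per_um: float = 5e-4
    dish_tilt_deg: float = 0.0

    # post-thaw modulus decay (cell compartments only)
    decay_final_fraction: float = 1.0
    decay_tau_min: float = 30.0

    # acquisition
    set_point_nn: float = 1.0
    z_length_um: float = 15.0
    sample_rate_hz: float = 2000.0
    tip_speed_um_s: float = 33.3
    probe_radius_um: float = cm.PAPER_PROBE_RADIUS_UM
    spring_constant_n_m: float = 0.018
    sensitivity_nm_v: float = 15.2
    poisson_ratio: float = 0.5
    temperature_k: float = 310.15

    def __post_init__(self) -> None:
        for name in ("nucleus_e_kpa", "periphery_e_kpa", "ring_e_kpa",
                     "substrate_e_kpa", "set_point_nn", "z_length_um",
                     "sample_rate_hz", "tip_speed_um_s", "probe_radius_um",
                     "spring_constant_n_m", "sensitivity_nm_v"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        peak = self.cell_peak_height_um + self.nucleus_bump_height_um
        if peak >= self.z_length_um:
            raise DomainError("cell peak height must stay below the Z-length")
        ex, ey = self.extent_um
        if self.cell_footprint_radius_um > 0.5 * min(ex, ey):
            raise DomainError("cell footprint exceeds the scan extent")
        if self.nucleus_radius_um > self.cell_footprint_radius_um:
            raise DomainError("nucleus cannot exceed the cell footprint")
        if not 0.0 < self.decay_final_fraction <= 1.0:
            raise DomainError("decay final fraction must lie in (0, 1]")

    # -- serialization (human-editable JSON, versioned) --------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["fibers"] = [asdict(f) if isinstance(f, FiberSpec) else dict(f)
                       for f in self.fibers]
        d["grid_shape"] = list(self.grid_shape)
        d["extent_um"] = list(self.extent_um)
        return json.dumps({"schema": _SCHEMA, **d}, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        if d.pop("schema", None) != _SCHEMA:
            raise DomainError(f"not a {_SCHEMA} document")
        d["fibers"] = tuple(FiberSpec(**f) for f in d.get("fibers", ()))
        d["grid_shape"] = tuple(d["grid_shape"])
        d["extent_um"] = tuple(d["extent_um"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        return cls.from_json(Path(path).read_text())


def _cap_height(r: np.ndarray, footprint_radius: float,
                peak: float) -> np.ndarray:
    """Spherical-cap height profile h(r); 0 outside the footprint."""
    if peak <= 0:
        return np.zeros_like(r)
    rc = (footprint_radius**2 + peak**2) / (2.0 * peak)  # sphere radius
    h = np.sqrt(np.clip(rc * rc - r * r, 0.0, None)) - (rc - peak)
    return np.where(r < footprint_radius, np.clip(h, 0.0, None), 0.0)


def decay_factor(spec: PhantomSpec, time_min: float) -> float:
    """Multiplicative modulus factor at ``time_min`` after thaw."""
    if time_min < 0:
        raise DomainError("time must be >= 0")
    f = spec.decay_final_fraction
    return f + (1.0 - f) * float(np.exp(-time_min / spec.decay_tau_min))


def _pixel_coords(spec: PhantomSpec):
    nrow, ncol = spec.grid_shape
    ex, ey = spec.extent_um
    x = (np.arange(ncol) + 0.5) * ex / ncol - 0.5 * ex
    y = (np.arange(nrow) + 0.5) * ey / nrow - 0.5 * ey
    return np.meshgrid(x, y)  # (X, Y), each (nrow, ncol)


def render_phantom(spec: PhantomSpec, time_min: float = 0.0):
    """Ground-truth (height_um, e_kpa) fields on the grid, cell centered.

    The modulus field is the substrate value outside the cell footprint and
    the compartment value inside (nucleus over fibers over ring over
    periphery), decayed by the time profile.  Deterministic.
    """
    xx, yy = _pixel_coords(spec)
    r = np.hypot(xx, yy)
    height = _cap_height(r, spec.cell_footprint_radius_um,
                         spec.cell_peak_height_um)
    height += _cap_height(r, spec.nucleus_radius_um,
                          spec.nucleus_bump_height_um)

    inside = r < spec.cell_footprint_radius_um
    e = np.full(spec.grid_shape, spec.substrate_e_kpa, dtype=float)
    e[inside] = spec.periphery_e_kpa
    if spec.ring_radius_um is not None:
        ring = inside & (np.abs(r - spec.ring_radius_um)
                         <= 0.5 * spec.ring_width_um)
        e[ring] = spec.ring_e_kpa
    for f in spec.fibers:
        px, py = np.array([f.x0_um, f.y0_um]), np.array([f.x1_um, f.y1_um])
        seg = py - px
        tt = np.clip(((xx - px[0]) * seg[0] + (yy - px[1]) * seg[1])
                     / max(seg @ seg, 1e-30), 0.0, 1.0)
        dist = np.hypot(xx - (px[0] + tt * seg[0]),
                        yy - (px[1] + tt * seg[1]))
        e[inside & (dist <= 0.5 * f.width_um)] = f.e_kpa
    nucleus = r < spec.nucleus_radius_um
    e[nucleus] = spec.nucleus_e_kpa
    e[inside] *= decay_factor(spec, time_min)
    return height, e


# ---------------------------------------------------------------------------
# curve-level forward model
# ---------------------------------------------------------------------------

def _ramp(spec: PhantomSpec) -> np.ndarray:
    """Approach piezo positions: from Z-length down to 1 um below the dish."""
    dz = spec.tip_speed_um_s / spec.sample_rate_hz
    n = int(np.ceil((spec.z_length_um + 1.0) / dz)) + 1
    return spec.z_length_um - dz * np.arange(n)


def _make_curve(contact_height_um: float, e_kpa: float, spec: PhantomSpec,
                rng: np.random.Generator, grid_index: tuple,
                timestamp_s: float):
    """Simulate one approach/retract curve; returns (curve, reached_setpoint)."""
    z = _ramp(spec)
    e_red = e_kpa / (1.0 - spec.poisson_ratio**2)
    s = np.clip(contact_height_um - z, 0.0, None)
    force = np.zeros_like(z)
    in_c = s > 0
    if in_c.any():
        _, force[in_c] = cm.solve_reduced_indentation(
            s[in_c], e_red, spec.probe_radius_um, spec.spring_constant_n_m)
    d_um = force / (spec.spring_constant_n_m * 1000.0)
    nn_per_v = spec.spring_constant_n_m * spec.sensitivity_nm_v
    sigma_v = spec.noise_frac_setpoint * spec.set_point_nn / nn_per_v
    baseline = spec.baseline_offset_v + spec.baseline_tilt_v_per_um * z

    clean_v = d_um * 1000.0 / spec.sensitivity_nm_v + baseline
    noise = rng.normal(0.0, sigma_v, size=len(z)) if sigma_v > 0 else 0.0
    v = clean_v + noise
    f_meas = (v - baseline) * nn_per_v
    trig = np.flatnonzero(f_meas >= spec.set_point_nn)
    reached = trig.size > 0
    stop = int(trig[0]) + 1 if reached else len(z)
    stop = max(stop, 50)  # segment invariant

    za, va = z[:stop], v[:stop]
    # retract: elastic mirror of the truncated approach, fresh noise
    zr = za[::-1]
    dr = d_um[:stop][::-1]
    br = baseline[:stop][::-1]
    vr = dr * 1000.0 / spec.sensitivity_nm_v + br
    if sigma_v > 0:
        vr = vr + rng.normal(0.0, sigma_v, size=len(zr))
    curve = ForceCurve(
        piezo_height_um=np.concatenate([za, zr]),
        deflection=np.concatenate([va, vr]),
        deflection_unit="V",
        segment=np.array([SEG_APPROACH] * len(za) + [SEG_RETRACT] * len(zr)),
        sample_rate_hz=spec.sample_rate_hz,
        grid_index=grid_index,
        timestamp_s=timestamp_s,
    )
    return curve, reached


def simulate_force_map(spec: PhantomSpec, time_min: float = 0.0,
                       path=None) -> ForceMap:
    """Simulate a complete force-map archive at one post-thaw timepoint.

    Reproducible: the RNG stream is seeded from ``spec.seed`` and the
    timepoint, and pixels are visited in row-major order, so the same spec
    and seed give a byte-identical archive.  If ``path`` is given the
    archive is also written there.
    """
    height, e_field = render_phantom(spec, time_min)
    xx, _ = _pixel_coords(spec)
    dish = np.tan(np.deg2rad(spec.dish_tilt_deg)) * xx
    zc = dish + height

    rng = np.random.default_rng([int(spec.seed), int(round(time_min * 1000))])
    nrow, ncol = spec.grid_shape
    dz = spec.tip_speed_um_s / spec.sample_rate_hz
    time_per_curve = 2.0 * len(_ramp(spec)) / spec.sample_rate_hz
    curves = {}
    unreached = []
    for i in range(nrow):
        for j in range(ncol):
            curve, reached = _make_curve(
                float(zc[i, j]), float(e_field[i, j]), spec, rng, (i, j),
                timestamp_s=time_per_curve * (i * ncol + j))
            curves[(i, j)] = curve
            if not reached:
                unreached.append([i, j])
    meta = {
        "probe_radius_um": spec.probe_radius_um,
        "spring_constant_n_m": spec.spring_constant_n_m,
        "sensitivity_nm_v": spec.sensitivity_nm_v,
        "set_point_nn": spec.set_point_nn,
        "grid_shape": [nrow, ncol],
        "extent_um": list(spec.extent_um),
        "sample_rate_hz": spec.sample_rate_hz,
        "z_length_um": spec.z_length_um,
        "z_step_um": dz,
        "time_per_curve_s": time_per_curve,
        "time_min": time_min,
        "timestamp": f"t+{time_min:g}min",
        "seed": int(spec.seed),
        "temperature_k": spec.temperature_k,
        "setpoint_unreached": unreached,
        "synthetic": True,
    }
    fm = ForceMap(curves=curves, meta=meta)
    if path is not None:
        write_archive(fm, path)
    return fm


def synthesize_curve(e_kpa: float, seed: int,
                     noise_frac_setpoint: float = 0.0,
                     surface_height_um: float = 4.0,
                     outlier_frac: float = 0.0,
                     outlier_nn: float = 0.5,
                     **spec_kwargs):
    """One standalone curve over a uniform surface; returns (curve, truth).

    Convenience wrapper for per-curve tests and benchmarks.  ``truth``
    carries the generating modulus, the exact contact height and the index
    of the last free sample of the approach.  ``outlier_frac`` replaces
    that fraction of the contact-side samples with gross force outliers of
    magnitude ``outlier_nn`` (for robust-fit stress tests).
    """
    spec = PhantomSpec(seed=seed, grid_shape=(1, 1),
                       noise_frac_setpoint=noise_frac_setpoint,
                       **spec_kwargs)
    rng = np.random.default_rng(seed)
    curve, reached = _make_curve(surface_height_um, e_kpa, spec, rng, (0, 0),
                                 0.0)
    za = curve.piezo_height_um[curve.approach]
    contact_index = int(np.searchsorted(-za, -surface_height_um)) - 1
    if outlier_frac > 0:
        nn_per_v = spec.spring_constant_n_m * spec.sensitivity_nm_v
        idx = np.flatnonzero((curve.segment == SEG_APPROACH)
                             & (curve.piezo_height_um < surface_height_um))
        n_out = max(1, int(round(outlier_frac * idx.size)))
        pick = rng.choice(idx, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        curve.deflection[pick] += signs * outlier_nn / nn_per_v
    truth = {"e_kpa": e_kpa, "contact_height_um": surface_height_um,
             "contact_index": contact_index, "reached_setpoint": reached,
             "spec": spec}
    return curve, truth


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

def dmso_like(seed: int, grid_shape=(64, 64), extent_um=(75.0, 75.0),
              **overrides) -> PhantomSpec:
    """Structured phantom: soft nucleus dome, stiff perinuclear ring and
    fiber lines, strong post-thaw softening (to ~40% of the initial median
    over ~2 h).  Mimics a cell frozen with a membrane-permeating
    cryoprotectant."""
    kwargs = dict(
        seed=seed, grid_shape=grid_shape, extent_um=extent_um,
        cell_footprint_radius_um=30.0, cell_peak_height_um=2.5,
        nucleus_radius_um=12.0, nucleus_bump_height_um=2.5,
        nucleus_e_kpa=0.8, periphery_e_kpa=1.6,
        ring_radius_um=14.0, ring_width_um=4.0, ring_e_kpa=2.5,
        fibers=(FiberSpec(-26.0, -18.0, 26.0, -18.0, 2.0, 3.0),
                FiberSpec(-20.0, 22.0, 24.0, 16.0, 2.0, 3.0)),
        decay_final_fraction=0.4, decay_tau_min=20.0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def peg_like(seed: int, grid_shape=(64, 64), extent_um=(75.0, 75.0),
             **overrides) -> PhantomSpec:
    """Homogeneous phantom: taller, rounder cap with uniform soft modulus
    and mild softening (<= 20%).  Mimics a cell frozen with a
    non-penetrating cryoprotectant."""
    kwargs = dict(
        seed=seed, grid_shape=grid_shape, extent_um=extent_um,
        cell_footprint_radius_um=25.0, cell_peak_height_um=6.0,
        nucleus_radius_um=10.0, nucleus_bump_height_um=0.0,
        nucleus_e_kpa=1.0, periphery_e_kpa=1.0,
        ring_radius_um=None, fibers=(),
        decay_final_fraction=0.8, decay_tau_min=30.0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
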