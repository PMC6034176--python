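"""Contact mechanics of a rigid sphere indenting an elastic half-space.

Sneddon's axisymmetric solution for a rigid sphere of radius ``R`` pressed
into a linear-elastic, isotropic half-space relates load ``P``, indentation
depth ``delta`` and contact radius ``a`` (``a < R``) by

    P     = E / (1 - nu^2) * [ (R^2 + a^2)/2 * ln((R+a)/(R-a)) - a*R ]
    delta = a/2 * ln((R+a)/(R-a))

where ``E`` is the Young's modulus and ``nu`` the Poisson ratio (0.5 for an
incompressible material such as a living cell).  The Hertz parabolic
approximation ``P = 4/3 * E/(1-nu^2) * sqrt(R) * delta^(3/2)`` is recovered
in the shallow limit ``delta << R`` and serves as a verification oracle.

Substituting ``a = R * tanh(t)`` (so ``t = atanh(a/R)``) turns the pair into

    delta / R              = t * tanh(t)
    P (1-nu^2) / (E R^2)   = (1 + tanh(t)^2) * t - tanh(t)

which is smooth and singularity-free for all ``t >= 0``; the log divergence
at ``a -> R`` becomes plain linear growth in ``t``.  All inversions below are
performed in ``t``.

Units
-----
The core routines work in SI (m, Pa, N); the public API accepts and returns
the reporting units used throughout the package: lengths in um, moduli in
kPa, forces in nN.  The conversion factor ``NN_PER_KPA_UM2`` (= 1 exactly:
1 kPa * um^2 = 1 nN = 1000 pN) is computed from the base units rather than
hard-coded, and is pinned by a unit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import ConvergenceError, DomainError

__all__ = [
    "ProbeGeometry",
    "MaterialParams",
    "ContactState",
    "indentation_from_contact_radius",
    "contact_radius_from_indentation",
    "sneddon_force",
    "hertz_force",
    "dimensionless_sneddon_force",
    "solve_reduced_indentation",
    "NN_PER_KPA_UM2",
    "PAPER_PROBE_RADIUS_UM",
]

# Base-unit sizes in SI.
_UM = 1e-6  # m
_KPA = 1e3  # Pa
_NN = 1e-9  # N

#: How many nN in 1 kPa * um^2 (exactly 1.0; kept symbolic on purpose).
NN_PER_KPA_UM2 = _KPA * _UM**2 / _NN

#: Colloidal probe radius used throughout the study: half of a 6.62 um sphere.
PAPER_PROBE_RADIUS_UM = 6.62 / 2.0


@dataclass(frozen=True)
class ProbeGeometry:
    """Spherical indenter geometry.

    Parameters
    ----------
    radius_um : float
        Probe radius ``R`` in um.  The package default elsewhere is the
        3.31 um colloidal silica sphere (6.62 um diameter).
    shape : str
        Only ``"spherical"`` is supported.
    """

    radius_um: float = PAPER_PROBE_RADIUS_UM
    shape: str = "spherical"

    def __post_init__(self) -> None:
        if self.shape != "spherical":
            raise DomainError(f"unsupported probe shape {self.shape!r}")
        if not np.isfinite(self.radius_um) or self.radius_um <= 0:
            raise DomainError("probe radius must be positive and finite")


@dataclass(frozen=True)
class MaterialParams:
    """Elastic half-space parameters: Young's modulus (kPa), Poisson ratio."""

    young_modulus_kpa: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.young_modulus_kpa) or self.young_modulus_kpa <= 0:
            raise DomainError("Young's modulus must be positive and finite")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise DomainError("Poisson ratio must lie in [0, 0.5]")

    @property
    def reduced_modulus_kpa(self) -> float:
        """E / (1 - nu^2), the prefactor of the contact laws."""
        return self.young_modulus_kpa / (1.0 - self.poisson_ratio**2)


@dataclass(frozen=True)
class ContactState:
    """A consistent (a, delta, P) triple for one probe/material pairing."""

    contact_radius_um: float
    indentation_um: float
    load_nn: float

    def __post_init__(self) -> None:
        if self.contact_radius_um < 0 or self.indentation_um < 0 or self.load_nn < 0:
            raise DomainError("contact state components must be non-negative")


# ---------------------------------------------------------------------------
# dimensionless kernel, parameterized by t = atanh(a / R)
# ---------------------------------------------------------------------------

def _delta_hat(t: np.ndarray) -> np.ndarray:
    """delta / R as a function of t."""
    return t * np.tanh(t)


def _force_hat(t: np.ndarray) -> np.ndarray:
    """P (1-nu^2) / (E R^2) as a function of t."""
    th = np.tanh(t)
    return (1.0 + th * th) * t - th


def _force_hat_prime(t: np.ndarray) -> np.ndarray:
    th = np.tanh(t)
    sech2 = 1.0 - th * th
    return (1.0 + th * th) + 2.0 * t * th * sech2 - sech2


def _solve_t_from_delta_hat(dhat: np.ndarray, rtol: float = 1e-13,
                            maxiter: int = 80) -> np.ndarray:
    """Vectorized safeguarded Newton for t*tanh(t) = dhat (dhat >= 0).

    Initial guess sqrt(dhat) (small-t limit) or dhat (large-t limit);
    convergence is quadratic and unconditionally safe because the residual
    is smooth, increasing and convex-enough on t > 0.  Verified against the
    scalar bracketed Brent path in the test suite.
    """
    dhat = np.asarray(dhat, dtype=float)
    if np.any(dhat < 0) or not np.all(np.isfinite(dhat)):
        raise DomainError("reduced indentation must be finite and >= 0")
    t = np.where(dhat < 1.0, np.sqrt(dhat), dhat)
    pos = dhat > 0
    for _ in range(maxiter):
        th = np.tanh(t)
        f = t * th - dhat
        fp = th + t * (1.0 - th * th)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(pos, f / np.where(fp > 0, fp, 1.0), 0.0)
        t_new = t - step
        # keep iterates strictly positive where a positive root exists
        t = np.where(pos, np.maximum(t_new, 0.25 * t), 0.0)
        if np.all(np.abs(f) <= rtol * np.maximum(dhat, 1e-300)):
            break
    else:
        worst = float(np.max(np.abs(t * np.tanh(t) - dhat)))
        raise ConvergenceError(
            f"t(delta) Newton did not converge: max residual {worst:.3e}")
    return t


def dimensionless_sneddon_force(delta_over_r: np.ndarray) -> np.ndarray:
    """Reduced load F(delta/R) with P = E/(1-nu^2) * R^2 * F(delta/R).

    Array-friendly fast path used by the fitting pipeline and the simulator.
    """
    t = _solve_t_from_delta_hat(np.asarray(delta_over_r, dtype=float))
    return _force_hat(t)


# ---------------------------------------------------------------------------
# public API (um / kPa / nN at the boundary, SI inside)
# ---------------------------------------------------------------------------

def indentation_from_contact_radius(contact_radius_um, radius_um: float):
    """Indentation delta(a) = a/2 * ln((R+a)/(R-a)), um.

    Strictly increasing in ``a`` and divergent as ``a -> R``; raises
    :class:`DomainError` outside ``0 <= a < R``.
    """
    a = np.asarray(contact_radius_um, dtype=float) * _UM
    r = float(radius_um) * _UM
    if r <= 0:
        raise DomainError("radius must be positive")
    if np.any(a < 0) or np.any(a >= r):
        raise DomainError("contact radius must satisfy 0 <= a < R")
    delta = 0.5 * a * np.log((r + a) / (r - a))
    out = delta / _UM
    return float(out) if np.isscalar(contact_radius_um) else out


def contact_radius_from_indentation(delta_um: float, radius_um: float,
                                    rtol: float = 1e-12) -> float:
    """Unique a in [0, R) with delta(a) = delta, by bracketed Brent in t.

    The root is bracketed in the transformed variable t = atanh(a/R), where
    delta/R = t*tanh(t) is singularity-free; an upper bracket of
    ``max(sqrt(dhat), dhat) + 1`` always encloses the root.
    """
    r = float(radius_um)
    d = float(delta_um)
    if r <= 0:
        raise DomainError("radius must be positive")
    if d < 0 or not np.isfinite(d):
        raise DomainError("indentation must be finite and >= 0")
    if d == 0.0:
        return 0.0
    dhat = d / r
    hi = max(np.sqrt(dhat), dhat) + 1.0
    try:
        t = brentq(lambda tt: tt * np.tanh(tt) - dhat, 0.0, hi,
                   xtol=1e-24, rtol=max(rtol, 4e-16), maxiter=300)
    except RuntimeError as exc:  # pragma: no cover - brentq is bracketed
        raise ConvergenceError(f"a(delta) bracketed solve failed: {exc}") from exc
    return r * float(np.tanh(t))


def sneddon_force(delta_um, material: MaterialParams, probe: ProbeGeometry):
    """Sneddon sphere load P(delta) in nN.

    Exact evaluation: inverts delta -> a (Newton in t, relative tolerance
    1e-13) and evaluates the closed form.  Accepts scalars or arrays.
    Depths beyond 2R are evaluated (the mathematics stays valid for any
    delta since a < R always) but are outside the physical validity of the
    half-space model; downstream QC rejects them.
    """
    delta = np.asarray(delta_um, dtype=float)
    if np.any(delta < 0):
        raise DomainError("indentation must be >= 0")
    r_m = probe.radius_um * _UM
    e_red_pa = material.reduced_modulus_kpa * _KPA
    t = _solve_t_from_delta_hat(delta * _UM / r_m)
    p_n = e_red_pa * r_m**2 * _force_hat(t)
    out = p_n / _NN
    return float(out) if np.isscalar(delta_um) else out


def hertz_force(delta_um, material: MaterialParams, probe: ProbeGeometry):
    """Hertz parabolic-approximation load (4/3) E/(1-nu^2) sqrt(R) delta^1.5, nN."""
    delta = np.asarray(delta_um, dtype=float)
    if np.any(delta < 0):
        raise DomainError("indentation must be >= 0")
    r_m = probe.radius_um * _UM
    e_red_pa = material.reduced_modulus_kpa * _KPA
    p_n = (4.0 / 3.0) * e_red_pa * np.sqrt(r_m) * (delta * _UM) ** 1.5
    out = p_n / _NN
    return float(out) if np.isscalar(delta_um) else out


def contact_state(delta_um: float, material: MaterialParams,
                  probe: ProbeGeometry) -> ContactState:
    """Full (a, delta, P) triple at a given depth."""
    a = contact_radius_from_indentation(delta_um, probe.radius_um)
    p = sneddon_force(delta_um, material, probe)
    return ContactState(contact_radius_um=a, indentation_um=float(delta_um),
                        load_nn=p)


def solve_reduced_indentation(travel_um, e_red_kpa: float, radius_um: float,
                              spring_constant_n_m: float,
                              rtol: float = 1e-12, maxiter: int = 200):
    """Split piezo travel past contact into indentation + cantilever bending.

    Solves, per sample, ``s = delta + P(delta)/k`` for the indentation
    ``delta`` given total travel ``s`` (um), reduced modulus ``E/(1-nu^2)``
    (kPa), probe radius (um) and spring constant (N/m).  Used by the
    forward simulator; vectorized bisection in t (monotone, bracketed, so
    convergence is guaranteed).

    Returns (delta_um, force_nn) arrays.
    """
    s = np.atleast_1d(np.asarray(travel_um, dtype=float))
    if np.any(s < 0):
        raise DomainError("travel must be >= 0")
    r = float(radius_um)
    # k in N/m == nN/nm; travel in um -> bending d_um = P_nN / (1000 k)
    k_nn_per_um = spring_constant_n_m * 1000.0
    coef = e_red_kpa * r * r * NN_PER_KPA_UM2  # P = coef * F(t) in nN

    def total(t):
        return r * _delta_hat(t) + coef * _force_hat(t) / k_nn_per_um

    # delta <= s always, so t(s/r) brackets the root from above.
    hi = _solve_t_from_delta_hat(np.maximum(s, 0.0) / r) + 1e-12
    lo = np.zeros_like(s)
    for _ in range(maxiter):
        mid = 0.5 * (lo + hi)
        too_big = total(mid) > s
        hi = np.where(too_big, mid, hi)
        lo = np.where(too_big, lo, mid)
        if np.all(hi - lo <= rtol * np.maximum(hi, 1e-30)):
            break
    t = 0.5 * (lo + hi)
    delta = r * _delta_hat(t)
    force = coef * _force_hat(t)
    if np.isscalar(travel_um):
        return float(delta[0]), float(force[0])
    return delta, force
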