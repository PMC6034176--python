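# Methods

## Scope and model

`forcemap` analyzes AFM force-mapping data of adherent cells: grids of
force-distance curves (FDCs) recorded with a colloidal (spherical) probe,
from which it reconstructs co-registered Young's-modulus and topography
maps and their evolution over time after thawing of cryopreserved cells.

The mechanical core is Sneddon's solution for a rigid sphere of radius
*R* on an elastic half-space:

    P     = E/(1-ν²) · [ (R²+a²)/2 · ln((R+a)/(R−a)) − aR ]
    δ     = a/2 · ln((R+a)/(R−a))

with load *P*, indentation *δ*, contact radius *a* < *R*, Young's modulus
*E* and Poisson ratio ν (fixed at 0.5, the incompressible limit
appropriate for cells, but overridable). The Hertz parabolic form
(4/3)·E/(1-ν²)·√R·δ^1.5 is used only as a shallow-limit verification
oracle; the two agree within 1% for δ/R ≤ 0.01 and the sphere falls
*below* Hertz at depth (≈3% lower at δ/R = 0.3).

**Numerics.** Substituting a = R·tanh(t) gives δ/R = t·tanh(t) and
P·(1-ν²)/(E·R²) = (1+tanh²t)·t − tanh(t), smooth for all t ≥ 0; the log
singularity at a → R disappears. The scalar inverse uses bracketed Brent
in t (round-trip relative error < 1e-12 over a/R ∈ [1e-4, 0.999]); array
paths use a safeguarded Newton iteration cross-checked against the Brent
route in the tests. Internally the model is evaluated in SI; the public
surface uses μm, kPa and nN (1 kPa·μm² = 1 nN exactly, pinned by a unit
test). Depths beyond 2R are evaluated mathematically (a < R holds for
any δ) but lie outside half-space validity; the QC cascade removes them.

## Per-curve pipeline

1. **Calibration.** Deflection sensitivity (nm/V) is the inverse slope of
   the contact region of a rigid-surface curve (linear regression over
   the upper half of the deflection excursion). The spring constant uses
   the plain equipartition estimate k = k_B·T / var(d) on a free
   deflection trace, without mode-shape corrections.
2. **Conversion.** F = k·sens·(V − baseline); the baseline is a straight
   line fitted to the free part of the approach (the instrument's
   "relative to baseline" set point implies baseline correction; a linear
   rather than constant baseline also absorbs optical interference
   tilt). Indentation subtracts cantilever bending from piezo travel:
   δ_i = (z0 − z_i) − F_i/k.
3. **Contact point.** An exhaustive scan over candidate split indices
   inside a bracket around the first sustained force excursion (3× the
   free-side noise SD, widened by ±10% of the segment length). Each
   candidate gets a linear baseline on its free side (closed-form prefix
   regressions) and a one-parameter Sneddon fit on its contact side.
   Candidates are compared by the total L1 misfit of that piecewise model
   over a fixed sample window, so a candidate cannot lower its score by
   absorbing well-fit free samples into its contact side (a failure mode
   of per-side median or mean scores on stiff-substrate curves, where
   the true contact region is a 4-sample minority). Smallest index wins
   ties; the scan is fully deterministic.
4. **Sub-sample refinement.** The winning index is refined continuously
   within ±6 samples by bounded scalar minimization of the fit objective.
   This matters: the z-sampling grid is ~17 nm (2 kHz at 33.3 μm/s) while
   typical indentations are 0.1–0.5 μm, and a sample-grid contact point
   alone biases E by more than 1%.
5. **Modulus fit.** E is the slope of F = E·C(δ) over the contact side.
   The default robust estimator is a Huber M-estimate (IRLS, tuning
   constant 1.345, scale 1.4826·MAD): ~95% efficient under Gaussian
   noise yet resistant to gross outlier samples; plain least squares is
   available behind the same interface (`robust=False`). The profile
   score used for refinement winsorizes residuals at 5× the robust noise
   scale so a single gross outlier cannot steer the contact point. The
   exact algorithms behind the acquisition software's proprietary robust
   estimators are not published; these are documented stand-ins chosen
   for the same goals (exhaustive search, outlier resistance) and are
   isolated behind the `robust=` switch.
6. **QC cascade** (all thresholds configurable, `None` disables a rule):
   - `substrate_stiff`: E > 10 kPa — curves on the plastic dish or very
     thin cell regions;
   - `over_indented`: max fitted indentation > 2 μm — a symptom of a
     faulty contact-point estimate;
   - `short_fit`: force at the deepest fitted point < 80% of the set
     point — fitted region too small;
   - `poor_rms`: RMS model deviation > 5% of the set point;
   - `poor_maxdev`: maximum model deviation > 7% of the set point.
   A fit is accepted iff no flag is raised; flags are recomputed from the
   fit fields on every call, so the cascade is idempotent and
   order-independent. A minimum of 4 positive-indentation samples is
   required for a fit: at the nominal acquisition (k = 18 mN/m, 1 nN set
   point, ~17 nm steps) a rigid-dish curve reaches the set point within
   ~60 nm of travel, i.e. ~4 samples, and demanding more would turn every
   dish point into a fit error instead of letting the 10 kPa rule reject
   it; 4 points still over-determine the one-parameter fit.

## Map assembly and statistics

Stiffness maps hold accepted moduli only. Heights are contact-point piezo
heights minus a least-squares dish plane: the plane is fitted through
substrate-classified points (`substrate_stiff` flag), points within the
noise floor of it are re-classified as substrate and the plane refitted
once. With fewer than 3 substrate points the global minimum height
becomes the zero level (with a warning). The cell is the set of accepted
points above the substrate noise floor; "full cell height" is the per-map
maximum over the cell mask (maps may contain one or a few cells; no
multi-cell decomposition is attempted). The upper (core/nuclear) region
collects cell points at ≥ 50% of the full height — the boundary point at
exactly 50% belongs to the upper region, a deterministic convention — and
the lower region (cell edges) is the rest.

Per timepoint the package reports median and mean E over the cell and per
region, the SEM, and a Shapiro-Wilk normality p-value (delegated to
scipy). A time series of maps is summarized by medians normalized to the
first timepoint and the maximum relative decrease. The "spatial
deviation" of a region is reported two ways, since either reading is
defensible: the offset of the region median from the whole-map median,
and the region's median absolute deviation from the whole-map median
(MAD/median).

## Synthetic phantom

The generator emulates the study's acquisition so that every stage is
testable without the ~40 GB instrument dataset: a spherical-cap cell
(optionally with a taller nucleus dome) on a rigid dish (2 MPa), with a
soft nucleus, stiffer perinuclear ring and stiff fiber lines; set point
1 nN, Z-length 15 μm, 2 kHz at 33.3 μm/s, probe radius 3.31 μm,
sensitivity 15.2 nm/V, spring constant 18 mN/m, up to 64×64 points on
75–100 μm. Noise is additive Gaussian on the *deflection* signal (where
real instrument noise enters), default SD 2% of the set point, plus a
linear baseline offset/tilt and an optional geometric dish tilt. The
forward model solves s = δ + P(δ)/k per sample (vectorized bisection in
t) and truncates the approach at the first sample whose measured force
reaches the set point; the ramp extends 1 μm below the nominal dish plane
so dish points, where nearly all travel goes into cantilever bending, can
reach the set point. The simulator shares only the contact-mechanics
module with the fitting pipeline, so parameter-recovery tests cannot leak
ground truth by construction.

Compartment moduli default to nucleus 0.8 / periphery 1.6 / ring 2.5 /
fibers 3 kPa. These values make the simulated maximum indentations fall
in ~0.3–1 μm at the 1 nN set point, the depth regime the instrument
actually probes with this probe and cantilever; a much stiffer cell would
indent only ~0.1 μm at the same set point.

Post-thaw softening is multiplicative on all cell compartments:
E(t) = E0·(f∞ + (1−f∞)·e^(−t/τ)). Two presets ship with the package:

- **dmso-like** — structured phantom (soft nucleus dome, stiff ring and
  fibers) with f∞ = 0.4, τ = 20 min: the cell-median modulus decays by
  ~60% over 2 h, and the upper (core) region is softer than the lower.
- **peg-like** — homogeneous, taller and rounder cap (uniform 1 kPa,
  peak 6 μm) with f∞ = 0.8, τ = 30 min: ≤ 20% decay.

Because all cell compartments share the decay factor, the programmed
median decrease equals 1 − factor(t) exactly, giving a closed-form ground
truth for the end-to-end recovery tests.

What the phantom does *not* emulate: viscoelastic approach/retract
hysteresis, adhesion, thermal drift, membrane/glycocalyx layers,
cell-to-cell variability and multi-cell fields. Passing the recovery
suite therefore demonstrates correctness of the inference chain under
the stated noise model, not robustness to every artifact of real data.

## Problem sizes and determinism

Time-series recovery runs (tests and the acceptance script) use 20×20
grids — ~400 curves per map, of which ~190 land on the cell — which is
ample for median statistics while keeping a 9-map series around two
minutes; one full 64×64 map is fitted end-to-end in the acceptance suite
as a scale check. All randomness flows through explicit integer seeds;
identical archive + configuration + seed reproduces fits and statistics
tables byte for byte, and the archive format itself round-trips
bit-exactly (shortest round-trip float repr, `float_precision=
"round_trip"` parsing).

## Known limitations

- Only the spherical indenter is implemented (no pyramidal/conical tips,
  no adhesion models, no bottom-effect correction — the thin-sample
  correction is unnecessary at these depths on cell bodies, and curves
  over thin regions are removed by the cascade anyway).
- The retract segment is stored but not analyzed.
- The equipartition spring-constant estimate ignores mode-shape and
  hydrodynamic corrections (few-percent level).
- Reading proprietary instrument files is out of scope; the plain-text
  exchange archive defined in `forcemap.archive` is the ingestion path,
  and an adapter from vendor formats would be a separate component.
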