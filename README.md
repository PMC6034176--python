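# forcemap

Hertz–Sneddon analysis of AFM force maps of living cells: calibration,
force-curve fitting, quality-control filtering, stiffness/height mapping
and post-thaw time-series statistics — with a synthetic phantom generator
providing exact ground truth for every stage.

## What it is for

Atomic-force-microscopy force mapping records a grid of force–distance
curves (cantilever deflection vs. piezo height) over a cell. Fitting each
approach curve with a contact-mechanics model yields a per-pixel Young's
modulus, and the contact points yield the topography. This package
implements that chain for the common colloidal-probe setup used to watch
cryopreserved fibroblasts recover after thawing: how a cell's surface
stiffness map — soft nucleus, stiffer perinuclear actin ring, stiff
stress fibers — relaxes over the first hours post-thaw, and how that
evolution differs between membrane-penetrating and non-penetrating
cryoprotectants.

Its intended users are biophysicists who have (or simulate) force-volume
data and want a tested, deterministic pipeline: volts → force →
indentation → modulus → QC'd maps → region statistics → time series.

## The model

For a rigid sphere of radius *R* on an elastic half-space (Sneddon),

```
P = E/(1−ν²) · [ (R²+a²)/2 · ln((R+a)/(R−a)) − a·R ]
δ = a/2 · ln((R+a)/(R−a)),            a < R
```

with load *P*, indentation *δ*, contact radius *a*, Young's modulus *E*
and Poisson ratio ν = 0.5 (incompressible). The substitution
a = R·tanh(t) makes both relations singularity-free; inversion is exact
to < 1e−12. Per curve, the contact point is found by an exhaustive
scan with sub-sample refinement and *E* by a robust (Huber) fit of
P(δ) on the approach segment; fits then pass a five-rule QC cascade
(10 kPa substrate threshold, 2 μm indentation cap, 80% set-point
coverage, 5% RMS and 7% maximum model deviation). Accepted pixels form
the stiffness map; contact heights minus a fitted dish plane form the
height map; the cell is split at 50% of its full height into a lower
(edge) and upper (core/nuclear) region; medians, means, SEM and
Shapiro–Wilk normality are reported per timepoint.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```python
from forcemap import synthetic_data as sd, curve_pipeline as cp, map_analysis as ma

spec = sd.dmso_like(seed=42, grid_shape=(16, 16))   # structured phantom cell
stats = []
for t in (0, 60, 120):                              # minutes post-thaw
    fm = sd.simulate_force_map(spec, time_min=t)    # grid of synthetic FDCs
    fits = cp.fit_force_map(fm)                     # contact point + E per curve
    smap, hmap = ma.build_maps(fits, grid_shape=fm.grid_shape)
    part = ma.partition_regions(hmap, smap)
    st = ma.timepoint_statistics(smap, part, time_min=t)
    stats.append(st)
    print(f"t={t:3d} min  n={st.n_points:3d}  median E={st.median_e_kpa:.2f} kPa  "
          f"upper={st.median_e_upper_kpa:.2f}  lower={st.median_e_lower_kpa:.2f}")
ts = ma.time_series(stats)
print(f"max median decrease: {100 * ts.attrs['max_decrease']:.1f}%")
```

prints

```
t=  0 min  n=108  median E=1.60 kPa  upper=0.80  lower=1.61
t= 60 min  n=109  median E=0.69 kPa  upper=0.34  lower=0.69
t=120 min  n=113  median E=0.64 kPa  upper=0.32  lower=0.64
max median decrease: 60.3%
```

Reading: of the 256 grid points, ~108 land on the cell and survive QC
(the rest are dish pixels rejected by the 10 kPa rule, or edge curves
with too little contact). At t = 0 the tall nuclear core (upper region,
0.80 kPa) is half as stiff as the cell edges (1.61 kPa) — the soft-core
signature. The phantom's programmed exponential softening (to 40% of the
initial modulus, τ = 20 min) is recovered by the full pipeline as a
60.3% drop of the median — within measurement noise of the 59.9%
ground-truth value.

The same chain is available from the shell:

```sh
forcemap simulate maps/ --preset dmso-like --seed 42 --grid 16 --times 0,60,120
forcemap run maps/ results/        # fits, maps, statistics.tsv, time_series.tsv
```

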