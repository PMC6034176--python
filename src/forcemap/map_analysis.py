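"""Stiffness/height map assembly, region partition and time statistics.

Per-curve fits are assembled into co-registered 2-D maps: the stiffness
map holds accepted Young's moduli only; the height map is the contact
height with the dish plane removed (least-squares plane through
substrate-classified points, one reclassification pass), so the dish sits
at zero.  The cell is split at 50% of the full cell height into a lower
(edge, 0-50%) and an upper (core/nuclear, 50-100%) region — a point at
exactly 50% belongs to the upper region — and per-timepoint medians,
means, SEM and a Shapiro-Wilk normality p-value are computed per region.
A time series of maps is summarized by medians normalized to the first
timepoint, the maximum relative decrease, and per-region spatial
deviations from the whole-map median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .archive import ForceMap, read_archive, write_archive  # noqa: F401  (re-export)
from .exceptions import MapError, PartitionError, StatsError

__all__ = [
    "StiffnessMap", "HeightMap", "RegionPartition", "TimepointStats",
    "build_maps", "partition_regions", "timepoint_statistics", "time_series",
    "stats_to_table", "ForceMap", "read_archive", "write_archive",
]


@dataclass
class StiffnessMap:
    """Young's moduli (kPa) of accepted fits; mask marks valid entries."""

    values_kpa: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values_kpa.shape != self.mask.shape:
            raise MapError("stiffness values and mask shapes differ")


@dataclass
class HeightMap:
    """Heights (um) above the fitted substrate plane; mask = fitted points."""

    values_um: np.ndarray
    mask: np.ndarray
    substrate_rms_um: float = np.nan

    def __post_init__(self) -> None:
        if self.values_um.shape != self.mask.shape:
            raise MapError("height values and mask shapes differ")


@dataclass
class RegionPartition:
    """Exclusive masks: substrate, lower (0-50%) and upper (50-100%) cell."""

    cell_mask: np.ndarray
    substrate_mask: np.ndarray
    lower_region: np.ndarray
    upper_region: np.ndarray
    full_cell_height_um: float

    def __post_init__(self) -> None:
        if (self.lower_region & self.upper_region).any():
            raise PartitionError("lower and upper regions overlap")
        if ((self.lower_region | self.upper_region) != self.cell_mask).any():
            raise PartitionError("regions do not tile the cell mask")
        if (self.substrate_mask & self.cell_mask).any():
            raise PartitionError("substrate and cell masks overlap")


@dataclass
class TimepointStats:
    """Per-map elasticity statistics at one post-thaw timepoint."""

    time_post_thaw_min: float
    median_e_kpa: float
    mean_e_kpa: float
    median_e_lower_kpa: float
    median_e_upper_kpa: float
    n_points: int
    sem_kpa: float
    shapiro_p: float
    mad_over_median_lower: float = np.nan
    mad_over_median_upper: float = np.nan


def _fits_grid(fits: pd.DataFrame, grid_shape=None):
    """Dense (E, z0, accepted, substrate_flag) grids from the fits table."""
    rows = fits["row"].to_numpy()
    cols = fits["col"].to_numpy()
    if grid_shape is None:
        grid_shape = (int(rows.max()) + 1, int(cols.max()) + 1)
    e = np.full(grid_shape, np.nan)
    z0 = np.full(grid_shape, np.nan)
    accepted = np.zeros(grid_shape, dtype=bool)
    substrate = np.zeros(grid_shape, dtype=bool)
    e[rows, cols] = fits["E_kPa"].to_numpy()
    z0[rows, cols] = fits["z0_um"].to_numpy()
    accepted[rows, cols] = fits["accepted"].to_numpy().astype(bool)
    flags = fits["flags"].fillna("").to_numpy()
    substrate[rows, cols] = np.array(
        ["substrate_stiff" in f for f in flags])
    return e, z0, accepted, substrate, grid_shape


def _fit_plane(z0: np.ndarray, mask: np.ndarray) -> np.ndarray:
    ii, jj = np.nonzero(mask)
    a = np.column_stack([ii, jj, np.ones_like(ii)]).astype(float)
    coef, *_ = np.linalg.lstsq(a, z0[mask], rcond=None)
    gi, gj = np.indices(z0.shape)
    return coef[0] * gi + coef[1] * gj + coef[2]


def build_maps(fits: pd.DataFrame, grid_shape=None,
               substrate_noise_floor_um: float = 0.05,
               ) -> tuple[StiffnessMap, HeightMap]:
    """Assemble co-registered stiffness and height maps from a fits table.

    Substrate classification starts from the ``substrate_stiff`` QC flag; a
    least-squares plane through those contact heights is subtracted, points
    within the noise floor of the plane are re-classified as substrate and
    the plane refitted once.  With fewer than 3 substrate points the global
    minimum height is used as the zero level (with a warning).
    """
    e, z0, accepted, substrate, grid_shape = _fits_grid(fits, grid_shape)
    fitted = np.isfinite(z0)
    sub = substrate & fitted
    if sub.sum() >= 3:
        plane = _fit_plane(z0, sub)
        height = z0 - plane
        floor = max(substrate_noise_floor_um,
                    3.0 * float(np.sqrt(np.mean(height[sub] ** 2))))
        sub2 = fitted & ((np.abs(height) <= floor) | substrate)
        if sub2.sum() >= 3:
            plane = _fit_plane(z0, sub2)
            height = z0 - plane
            sub = sub2
        rms = float(np.sqrt(np.mean(height[sub] ** 2)))
    else:
        warnings.warn("fewer than 3 substrate points; using the global "
                      "minimum height as the zero level", stacklevel=2)
        height = z0 - np.nanmin(z0)
        rms = np.nan
    height = np.where(fitted, height, np.nan)
    smap = StiffnessMap(values_kpa=np.where(accepted, e, np.nan),
                        mask=accepted)
    hmap = HeightMap(values_um=height, mask=fitted, substrate_rms_um=rms)
    return smap, hmap


def partition_regions(height: HeightMap, stiffness: StiffnessMap,
                      substrate_noise_floor_um: float = 0.05,
                      ) -> RegionPartition:
    """Split the map into substrate and lower/upper cell regions.

    Cell = accepted fits above the substrate noise floor; full cell height
    is the per-map maximum over the cell mask, and the upper (core/nuclear)
    region collects cell points at >= 50% of it.
    """
    floor = max(substrate_noise_floor_um,
                3.0 * np.nan_to_num(height.substrate_rms_um))
    h = height.values_um
    cell = stiffness.mask & height.mask & (h > floor)
    if not cell.any():
        raise PartitionError("empty cell mask: no accepted points above "
                             "the substrate")
    substrate = height.mask & ~cell
    full = float(np.nanmax(np.where(cell, h, np.nan)))
    upper = cell & (h >= 0.5 * full)
    lower = cell & ~upper
    return RegionPartition(cell_mask=cell, substrate_mask=substrate,
                           lower_region=lower, upper_region=upper,
                           full_cell_height_um=full)


def _median(x: np.ndarray) -> float:
    return float(np.median(x)) if x.size else np.nan


def timepoint_statistics(stiffness: StiffnessMap,
                         partition: RegionPartition,
                         time_min: float = 0.0) -> TimepointStats:
    """Whole-cell and per-region elasticity statistics for one map."""
    cell_e = stiffness.values_kpa[partition.cell_mask & stiffness.mask]
    cell_e = cell_e[np.isfinite(cell_e)]
    if cell_e.size < 3:
        raise StatsError(f"only {cell_e.size} accepted cell points "
                         "(need >= 3)")
    low_e = stiffness.values_kpa[partition.lower_region & stiffness.mask]
    up_e = stiffness.values_kpa[partition.upper_region & stiffness.mask]
    med = _median(cell_e)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000
        shapiro_p = float(sps.shapiro(cell_e).pvalue)
    return TimepointStats(
        time_post_thaw_min=float(time_min),
        median_e_kpa=med,
        mean_e_kpa=float(np.mean(cell_e)),
        median_e_lower_kpa=_median(low_e),
        median_e_upper_kpa=_median(up_e),
        n_points=int(cell_e.size),
        sem_kpa=float(np.std(cell_e, ddof=1) / np.sqrt(cell_e.size)),
        shapiro_p=shapiro_p,
        mad_over_median_lower=(
            _median(np.abs(low_e - med)) / med if low_e.size else np.nan),
        mad_over_median_upper=(
            _median(np.abs(up_e - med)) / med if up_e.size else np.nan),
    )


def time_series(stats: list[TimepointStats]) -> pd.DataFrame:
    """Relative-change profile across ordered timepoints.

    Medians are normalized to the first timepoint; ``max_decrease`` (the
    largest relative drop of the whole-cell median, in fraction of the
    initial value) is attached as DataFrame attribute ``max_decrease``
    alongside per-region deviations of the region medians from the
    whole-map median.
    """
    if len(stats) < 2:
        raise StatsError("need at least two timepoints for a time series")
    times = [s.time_post_thaw_min for s in stats]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise StatsError("timepoints must be strictly increasing")
    m0 = stats[0].median_e_kpa
    rows = []
    for s in stats:
        rows.append({
            "time_min": s.time_post_thaw_min,
            "median_e_kpa": s.median_e_kpa,
            "median_norm": s.median_e_kpa / m0,
            "mean_e_kpa": s.mean_e_kpa,
            "median_lower_norm": s.median_e_lower_kpa / m0,
            "median_upper_norm": s.median_e_upper_kpa / m0,
            "lower_dev_from_median": abs(s.median_e_lower_kpa
                                         - s.median_e_kpa) / s.median_e_kpa,
            "upper_dev_from_median": abs(s.median_e_upper_kpa
                                         - s.median_e_kpa) / s.median_e_kpa,
            "mad_over_median_lower": s.mad_over_median_lower,
            "mad_over_median_upper": s.mad_over_median_upper,
            "n_points": s.n_points,
            "sem_kpa": s.sem_kpa,
            "shapiro_p": s.shapiro_p,
        })
    df = pd.DataFrame(rows)
    df.attrs["max_decrease"] = float(1.0 - df["median_norm"].min())
    return df


def stats_to_table(stats: list[TimepointStats]) -> pd.DataFrame:
    """Tidy per-timepoint table: one row per map x region."""
    rows = []
    for s in stats:
        for region, med, mad in (
                ("whole", s.median_e_kpa, np.nan),
                ("lower", s.median_e_lower_kpa, s.mad_over_median_lower),
                ("upper", s.median_e_upper_kpa, s.mad_over_median_upper)):
            rows.append({"time_min": s.time_post_thaw_min, "region": region,
                         "median_e_kpa": med, "mean_e_kpa": s.mean_e_kpa,
                         "sem_kpa": s.sem_kpa, "n_points": s.n_points,
                         "shapiro_p": s.shapiro_p,
                         "mad_over_median": mad})
    return pd.DataFrame(rows)
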