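"""Force-map exchange format: a plain-text, versioned, bit-exact archive.

One archive holds one force map: a JSON metadata header (probe radius,
spring constant, sensitivity, set point, grid shape, physical extent,
timestamp, seed if synthetic) followed by one tab-separated block of
samples per grid point, grouped in row-major order with columns

    row  col  sample_index  piezo_height_um  deflection_V  segment

Floats are written with Python's shortest round-trip ``repr``, so
write -> read -> write reproduces the file byte for byte.  Segment labels
are single characters ("A" approach, "R" retract).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contact_mechanics as cm
from .curve_pipeline import CalibrationRecord, ForceCurve
from .exceptions import ArchiveError

__all__ = ["ForceMap", "write_archive", "read_archive", "MAGIC"]

MAGIC = "#FORCEMAP-ARCHIVE v1"
_SCHEMA = "forcemap-archive/1"
_COLUMNS = ["row", "col", "sample_index", "piezo_height_um", "deflection_V",
            "segment"]


@dataclass
class ForceMap:
    """A grid of force-distance curves plus acquisition metadata.

    ``curves`` maps (row, col) -> :class:`ForceCurve`; a missing key is an
    explicitly missing grid point.  ``meta`` carries the acquisition
    metadata; typed accessors build the probe/calibration objects.
    """

    curves: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        for (i, j) in self.curves:
            if not (0 <= i < r and 0 <= j < c):
                raise ArchiveError(f"curve index {(i, j)} outside grid "
                                   f"{self.grid_shape}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.meta["grid_shape"])

    @property
    def extent_um(self) -> tuple[float, float]:
        return tuple(self.meta["extent_um"])

    @property
    def set_point_nn(self) -> float:
        return float(self.meta["set_point_nn"])

    @property
    def time_min(self) -> float:
        return float(self.meta.get("time_min", 0.0))

    def probe(self) -> cm.ProbeGeometry:
        return cm.ProbeGeometry(radius_um=float(self.meta["probe_radius_um"]))

    def calibration(self) -> CalibrationRecord:
        return CalibrationRecord(
            sensitivity_nm_per_v=float(self.meta["sensitivity_nm_v"]),
            spring_constant_n_m=float(self.meta["spring_constant_n_m"]),
            temperature_k=float(self.meta.get("temperature_k", 310.15)),
        )


def _meta_normalized(meta: dict) -> dict:
    out = dict(meta)
    out["schema"] = _SCHEMA
    required = ("probe_radius_um", "spring_constant_n_m", "sensitivity_nm_v",
                "set_point_nn", "grid_shape", "extent_um")
    missing = [k for k in required if k not in out]
    if missing:
        raise ArchiveError(f"archive metadata missing fields: {missing}")
    return out


def write_archive(force_map: ForceMap, path: str | Path) -> None:
    """Serialize a force map to the exchange format (bit-exact round trip)."""
    meta = _meta_normalized(force_map.meta)
    parts = [MAGIC, "#META " + json.dumps(meta, sort_keys=True)]
    frames = []
    for (row, col) in sorted(force_map.curves):
        cv = force_map.curves[(row, col)]
        n = len(cv.piezo_height_um)
        frames.append(pd.DataFrame({
            "row": np.full(n, row, dtype=np.int64),
            "col": np.full(n, col, dtype=np.int64),
            "sample_index": np.arange(n, dtype=np.int64),
            "piezo_height_um": cv.piezo_height_um,
            "deflection_V": cv.deflection,
            "segment": cv.segment,
        }))
    if not frames:
        raise ArchiveError("force map has no curves")
    table = pd.concat(frames, ignore_index=True)
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text("\n".join(parts) + "\n" + buf.getvalue())


def read_archive(path: str | Path) -> ForceMap:
    """Parse an exchange archive back into a :class:`ForceMap`."""
    text = Path(path).read_text()
    lines = text.split("\n", 2)
    if len(lines) < 3 or lines[0] != MAGIC:
        raise ArchiveError(f"{path}: not a {MAGIC} file")
    if not lines[1].startswith("#META "):
        raise ArchiveError(f"{path}: missing #META header")
    meta = json.loads(lines[1][len("#META "):])
    if meta.get("schema") != _SCHEMA:
        raise ArchiveError(f"{path}: unsupported schema {meta.get('schema')!r}")
    table = pd.read_csv(io.StringIO(lines[2]), sep="\t",
                        float_precision="round_trip",
                        dtype={"row": np.int64, "col": np.int64,
                               "sample_index": np.int64,
                               "piezo_height_um": float,
                               "deflection_V": float, "segment": str})
    if list(table.columns) != _COLUMNS:
        raise ArchiveError(f"{path}: unexpected columns {list(table.columns)}")

    sample_rate = float(meta.get("sample_rate_hz", 2000.0))
    time_per_curve = float(meta.get("time_per_curve_s", 0.0))
    curves = {}
    key = table["row"].to_numpy() * (table["col"].max() + 1) \
        + table["col"].to_numpy()
    bounds = np.flatnonzero(np.diff(key)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [len(table)]])
    z = table["piezo_height_um"].to_numpy()
    v = table["deflection_V"].to_numpy()
    seg = table["segment"].to_numpy()
    rows = table["row"].to_numpy()
    cols = table["col"].to_numpy()
    for a, b in zip(starts, stops):
        gi = (int(rows[a]), int(cols[a]))
        curves[gi] = ForceCurve(
            piezo_height_um=z[a:b], deflection=v[a:b], deflection_unit="V",
            segment=seg[a:b], sample_rate_hz=sample_rate, grid_index=gi,
            timestamp_s=time_per_curve * len(curves))
    return ForceMap(curves=curves, meta=meta)
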