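"""Readers, writers and the run-configuration record.

Geographic rasters use the plain-text ESRI ASCII grid format (.asc)
with WGS84 decimal-degree coordinates and cell-center containment
semantics, matching the buffer-extraction contract.  Tabular inputs are
CSV; outputs are written atomically (temp file + rename) together with
the resolved run configuration for provenance.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import tempfile
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Raster",
    "RunConfig",
    "read_spawning_csv",
    "read_raster",
    "write_raster",
    "read_traits",
    "write_outputs",
    "SPAWNING_COLUMNS",
]

#: external spawning-database schema -> internal column names
SPAWNING_COLUMNS = {
    "Site": "site_id",
    "Latitude": "latitude",
    "Longitude": "longitude",
    "Year": "year",
    "Genus": "genus",
    "Species": "species",
    "Depth_m": "depth_m",
    "DoSRtNF": "dosrtnf",
    "Ecoregion": "ecoregion",
    "O_n": "o_n",
}


@dataclass
class Raster:
    """Single-band georeferenced grid, row 0 = northernmost, WGS84 degrees."""
    data: np.ndarray          # (nrows, ncols), np.nan for missing
    x_ll: float               # x of the lower-left corner
    y_ll: float
    cell: float
    nodata: Optional[float] = None

    @property
    def x_min(self): return self.x_ll
    @property
    def y_min(self): return self.y_ll
    @property
    def x_max(self): return self.x_ll + self.cell * self.data.shape[1]
    @property
    def y_max(self): return self.y_ll + self.cell * self.data.shape[0]

    def cell_centers(self):
        """(xs, ys): x centers west->east, y centers matching row order (north->south)."""
        nr, nc = self.data.shape
        xs = self.x_ll + (np.arange(nc) + 0.5) * self.cell
        ys = self.y_ll + (nr - np.arange(nr) - 0.5) * self.cell
        return xs, ys

    def set_circle(self, lat: float, lon: float, radius_deg: float, value: float):
        """Assign `value` to every cell whose center lies within the circle."""
        xs, ys = self.cell_centers()
        mask = (xs[None, :] - lon) ** 2 + (ys[:, None] - lat) ** 2 <= radius_deg ** 2
        self.data[mask] = value


def read_raster(path) -> Raster:
    """Read an ESRI ASCII grid (.asc); nodata cells become NaN."""
    header: Dict[str, float] = {}
    with open(path) as f:
        pos = 0
        for _ in range(6):
            line = f.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[1].replace(".", "").replace("-", "").isdigit():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = f.tell()
        f.seek(pos)
        data = np.loadtxt(f)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"raster header missing {key!r} in {path}")
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"raster data shape {data.shape} does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return Raster(data=data, x_ll=header["xllcorner"], y_ll=header["yllcorner"],
                  cell=header["cellsize"], nodata=None)


def write_raster(raster: Raster, path) -> None:
    nr, nc = raster.data.shape
    nodata = -9999.0
    data = np.where(np.isnan(raster.data), nodata, raster.data)
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as f:
        f.write(f"ncols {nc}\nnrows {nr}\n")
        f.write(f"xllcorner {raster.x_ll}\nyllcorner {raster.y_ll}\n")
        f.write(f"cellsize {raster.cell}\nNODATA_value {nodata}\n")
        np.savetxt(f, data, fmt="%.4g")
    os.replace(tmp, path)


def read_spawning_csv(path) -> pd.DataFrame:
    """Read a spawning-observation table in the external database schema.

    Validates required columns, rejects malformed rows with line-numbered
    messages, and returns the internal canonical columns (plus
    ``in_situ`` derived from the O_n flag).
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty spawning table")
    missing = [c for c in SPAWNING_COLUMNS if c not in df.columns and c != "Site"]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "Site" not in df.columns:
        df["Site"] = (df["Latitude"].round(4).astype(str) + "_"
                      + df["Longitude"].round(4).astype(str))
    out = df.rename(columns=SPAWNING_COLUMNS)[list(SPAWNING_COLUMNS.values())].copy()
    problems = []
    lat = pd.to_numeric(out["latitude"], errors="coerce")
    lon = pd.to_numeric(out["longitude"], errors="coerce")
    dos = pd.to_numeric(out["dosrtnf"], errors="coerce")
    for i in out.index:
        line = i + 2  # header + 1-based
        if not (-90 <= lat[i] <= 90) or not (-180 <= lon[i] <= 180):
            problems.append(f"line {line}: coordinates out of range")
        elif not np.isfinite(dos[i]) or abs(dos[i]) > 15:
            problems.append(f"line {line}: DoSRtNF missing or outside +-15")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems[:20]))
    out["latitude"] = lat
    out["longitude"] = lon
    out["dosrtnf"] = dos.astype(int)
    out["year"] = pd.to_numeric(out["year"], errors="coerce").astype(int)
    out["depth_m"] = pd.to_numeric(out["depth_m"], errors="coerce")
    if (out["depth_m"].dropna() < 0).any():
        raise ValueError(f"{path}: negative depths present")
    out["in_situ"] = out["o_n"].astype(str).str.strip().str.lower().isin(
        ["in situ", "insitu", "in-situ", "i"])
    return out


def read_traits(path) -> Dict[str, float]:
    """Species -> minimum depth (m) from a two-column trait CSV."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    sp = cols.get("species")
    dp = cols.get("lower_depth_m") or cols.get("minimum_depth_m") or cols.get("min_depth_m")
    if sp is None or dp is None:
        raise ValueError(f"{path}: need 'species' and a minimum/lower depth column")
    return dict(zip(df[sp].astype(str), pd.to_numeric(df[dp], errors="coerce")))


@dataclass
class RunConfig:
    """Resolved configuration written alongside every output directory."""
    seed: int = 0
    created_utc: str = field(default_factory=lambda: _dt.datetime.now(
        _dt.timezone.utc).isoformat(timespec="seconds"))
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _atomic_write(text: str, path):
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d)
    with os.fdopen(fd, "w") as f:
        f.write(text)
    os.replace(tmp, path)


def write_outputs(outputs: Mapping[str, object], out_dir, config: Optional[RunConfig] = None):
    """Atomically write result tables/objects plus the resolved config.

    DataFrames go to CSV, dicts to JSON, strings verbatim; the RunConfig
    is always emitted as config.json.
    """
    os.makedirs(out_dir, exist_ok=True)
    for name, obj in outputs.items():
        path = os.path.join(out_dir, name)
        if isinstance(obj, pd.DataFrame):
            _atomic_write(obj.to_csv(index=False), path)
        elif isinstance(obj, (dict, list)):
            _atomic_write(json.dumps(obj, indent=2, default=str), path)
        else:
            _atomic_write(str(obj), path)
    cfg = config or RunConfig()
    _atomic_write(cfg.to_json(), os.path.join(out_dir, "config.json"))
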