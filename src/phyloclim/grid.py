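"""Gridded monthly climate normals.

A :class:`ClimateGrid` holds 12 monthly mean temperatures (deg C) and 12
monthly precipitation totals (mm) on a regular lat/lon lattice.  Cells are
half-open ``[lo, hi)`` boxes; internally row index 0 is the southernmost
row.  Grids round-trip through 24 ESRI ASCII rasters (``T01..T12.asc``,
``P01..P12.asc``), a plain-text format readable by any GIS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class ClimateGrid:
    lat_min: float
    lon_min: float
    cellsize: float  # degrees
    temp: np.ndarray  # (12, nrows, ncols), deg C; row 0 = south
    prec: np.ndarray  # (12, nrows, ncols), mm/month

    def __post_init__(self) -> None:
        self.temp = np.asarray(self.temp, dtype=float)
        self.prec = np.asarray(self.prec, dtype=float)
        if self.temp.shape != self.prec.shape or self.temp.shape[0] != 12:
            raise ValueError("temp and prec must both be (12, nrows, ncols)")
        if np.any(self.prec < 0):
            raise ValueError("negative monthly precipitation")

    @property
    def nrows(self) -> int:
        return self.temp.shape[1]

    @property
    def ncols(self) -> int:
        return self.temp.shape[2]

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.cellsize

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cellsize

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.nrows) + 0.5) * self.cellsize

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.cellsize

    def cell_of(self, lat, lon):
        """Vectorised point->cell lookup.

        Returns integer arrays ``(i, j)`` and a boolean validity mask;
        points outside the grid get ``i = j = -1``.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - self.lat_min) / self.cellsize).astype(np.int64)
        j = np.floor((lon - self.lon_min) / self.cellsize).astype(np.int64)
        ok = (i >= 0) & (i < self.nrows) & (j >= 0) & (j < self.ncols)
        i = np.where(ok, i, -1)
        j = np.where(ok, j, -1)
        return i, j, ok

    def monthly_at_cell(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        return self.temp[:, i, j], self.prec[:, i, j]


def write_asc_dir(grid: ClimateGrid, outdir) -> None:
    """Write the grid as 24 ESRI ASCII rasters T01..T12 / P01..P12."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.lon_min:.8f}\n"
        f"yllcorner {grid.lat_min:.8f}\n"
        f"cellsize {grid.cellsize:.8f}\n"
        f"NODATA_value {NODATA:.1f}\n"
    )
    for prefix, cube in (("T", grid.temp), ("P", grid.prec)):
        for m in range(12):
            path = outdir / f"{prefix}{m + 1:02d}.asc"
            with open(path, "w") as fh:
                fh.write(header)
                # ESRI ASCII rows run north -> south
                np.savetxt(fh, cube[m][::-1], fmt="%.4f")


def read_asc_dir(indir) -> ClimateGrid:
    indir = Path(indir)
    temp, prec = [], []
    meta = None
    for prefix, stack in (("T", temp), ("P", prec)):
        for m in range(12):
            path = indir / f"{prefix}{m + 1:02d}.asc"
            if not path.exists():
                raise FileNotFoundError(f"missing raster {path.name}")
            hdr = {}
            with open(path) as fh:
                for _ in range(6):
                    key, val = fh.readline().split()
                    hdr[key.lower()] = float(val)
                data = np.loadtxt(fh)
            data = np.atleast_2d(data)[::-1]  # back to south-first rows
            this = (hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"])
            if meta is None:
                meta = this
            elif not np.allclose(meta, this):
                raise ValueError("inconsistent raster headers")
            stack.append(data)
    lon_min, lat_min, cs = meta
    return ClimateGrid(lat_min, lon_min, cs, np.stack(temp), np.stack(prec))
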