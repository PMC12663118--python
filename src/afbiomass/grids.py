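"""Georeferenced single-band raster container and plain-text raster I/O.

Every map layer in the pipeline (backscatter, tree cover, canopy height,
biomass density, biome codes) is carried as a :class:`Grid2D`: a north-up,
axis-aligned single-band raster with an explicit no-data mask, square pixels
and an upper-left origin in projected map coordinates (metres).

Rasters are persisted as ESRI ASCII grids (``.asc``), a plain-text format
readable by GDAL, QGIS and R's ``terra``; backscatter conversion helpers
between decibel and linear power live here too because they are format-level
concerns, not science.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Grid2D",
    "GeoreferencingError",
    "read_ascii_grid",
    "write_ascii_grid",
    "db_to_linear",
    "linear_to_db",
    "block_mean",
    "upsample_nearest",
]


class GeoreferencingError(ValueError):
    """Raised when two grids that must share geometry do not."""


@dataclass
class Grid2D:
    """Single-band raster: values + no-data mask + geotransform.

    Attributes
    ----------
    values
        2-D float64 array, row 0 at the northern edge.
    nodata
        Boolean array, ``True`` where the pixel carries no data. ``values``
        under the mask are unspecified (conventionally NaN).
    pixel_size_m
        Square pixel edge length in metres.
    origin
        ``(x, y)`` map coordinates of the *upper-left corner* of pixel (0, 0).
    crs_id
        Free-text identifier of the projected CRS; grids only interoperate
        when it matches.
    """

    values: np.ndarray
    nodata: np.ndarray = None  # type: ignore[assignment]
    pixel_size_m: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metric"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid2D values must be 2-D")
        if self.nodata is None:
            self.nodata = ~np.isfinite(self.values)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.nodata.shape != self.values.shape:
            raise ValueError("nodata mask shape mismatch")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of pixels that carry data."""
        return ~self.nodata

    def same_geometry(self, other: "Grid2D", *, tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.pixel_size_m - other.pixel_size_m) < tol
            and abs(self.origin[0] - other.origin[0]) < tol
            and abs(self.origin[1] - other.origin[1]) < tol
            and self.crs_id == other.crs_id
        )

    def require_same_geometry(self, other: "Grid2D") -> None:
        if not self.same_geometry(other):
            raise GeoreferencingError(
                f"grid geometry mismatch: {self.shape}@{self.pixel_size_m} m "
                f"vs {other.shape}@{other.pixel_size_m} m"
            )

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates -> (row, col) integer indices (floor convention)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size_m).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.pixel_size_m).astype(int)
        return row, col

    def xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre map coordinates of (row, col)."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.pixel_size_m
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.pixel_size_m
        return x, y

    def contains_rowcol(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        r, c = np.asarray(row), np.asarray(col)
        return (r >= 0) & (r < self.shape[0]) & (c >= 0) & (c < self.shape[1])

    # -- construction helpers ---------------------------------------------
    def like(self, values: np.ndarray, nodata: np.ndarray | None = None) -> "Grid2D":
        """New grid sharing this grid's geometry."""
        values = np.asarray(values, dtype=float)
        if nodata is None:
            nodata = ~np.isfinite(values)
        return replace(self, values=values, nodata=np.asarray(nodata, bool), meta={})

    def copy(self) -> "Grid2D":
        return replace(
            self, values=self.values.copy(), nodata=self.nodata.copy(), meta=dict(self.meta)
        )

    def masked_values(self) -> np.ndarray:
        """Values with NaN under the no-data mask."""
        out = self.values.copy()
        out[self.nodata] = np.nan
        return out


# -- I/O -------------------------------------------------------------------

_NODATA_VALUE = -9999.0


def write_ascii_grid(grid: Grid2D, path: str | Path) -> None:
    """Write an ESRI ASCII grid (plain text, ``.asc``)."""
    path = Path(path)
    vals = grid.values.copy()
    vals[grid.nodata] = _NODATA_VALUE
    nrows, ncols = grid.shape
    yll = grid.origin[1] - nrows * grid.pixel_size_m
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {grid.pixel_size_m:.6f}\n"
        f"NODATA_value {_NODATA_VALUE}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path, crs_id: str = "local-metric") -> Grid2D:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    vals = np.loadtxt(lines[n_header:], dtype=float)
    vals = np.atleast_2d(vals)
    nodata = vals == header.get("nodata_value", _NODATA_VALUE)
    vals = vals.astype(float)
    vals[nodata] = np.nan
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + header["nrows"] * cell)
    return Grid2D(vals, nodata, pixel_size_m=cell, origin=origin, crs_id=crs_id)


# -- radiometry unit converters -------------------------------------------

def db_to_linear(db: np.ndarray) -> np.ndarray:
    """Backscatter dB -> linear power (gamma-nought)."""
    return np.power(10.0, np.asarray(db, float) / 10.0)


def linear_to_db(linear: np.ndarray) -> np.ndarray:
    """Backscatter linear power -> dB. Non-positive power maps to NaN."""
    lin = np.asarray(linear, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 10.0 * np.log10(lin)
    out[~(lin > 0)] = np.nan
    return out


# -- resolution changes ----------------------------------------------------

def block_mean(grid: Grid2D, factor: int = 2, *, min_valid: int = 1) -> Grid2D:
    """Aggregate by ``factor`` x ``factor`` block averaging (50 m -> 100 m).

    A coarse pixel is valid when at least ``min_valid`` fine pixels in its
    block are valid; the mean is taken over the valid members only, so the
    spatial mean over a fully valid footprint is conserved exactly.
    """
    nrows, ncols = grid.shape
    if nrows % factor or ncols % factor:
        raise GeoreferencingError("grid shape not divisible by aggregation factor")
    v = grid.masked_values().reshape(nrows // factor, factor, ncols // factor, factor)
    ok = grid.valid.reshape(nrows // factor, factor, ncols // factor, factor)
    count = ok.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(ok, v, 0.0), axis=(1, 3)) / np.maximum(count, 1)
    nodata = count < min_valid
    mean[nodata] = np.nan
    return Grid2D(
        mean,
        nodata,
        pixel_size_m=grid.pixel_size_m * factor,
        origin=grid.origin,
        crs_id=grid.crs_id,
    )


def upsample_nearest(grid: Grid2D, factor: int = 2) -> Grid2D:
    """Subdivide each pixel into ``factor`` x ``factor`` copies (100 m -> 50 m)."""
    v = np.kron(grid.values, np.ones((factor, factor)))
    m = np.kron(grid.nodata, np.ones((factor, factor), dtype=bool))
    return Grid2D(
        v,
        m,
        pixel_size_m=grid.pixel_size_m / factor,
        origin=grid.origin,
        crs_id=grid.crs_id,
    )
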