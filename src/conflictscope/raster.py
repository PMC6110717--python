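"""Planar gridded surfaces (``RasterGrid``) and GeoTIFF round-trips.

Conventions (used consistently by every stage of the pipeline):

* coordinates are planar kilometres with the origin at the grid's
  lower-left corner;
* cells are indexed 0-based, row-major, with row 0 at the *bottom* of the
  grid so that ``values[row, col]`` covers the half-open square
  ``[x0 + col*h, x0 + (col+1)*h) x [y0 + row*h, y0 + (row+1)*h)``;
* a point maps to a cell by floor division of its offset by the cell size;
* nodata cells (marker value, default -9999) are excluded from every
  statistic.

On disk, rasters are single-band float32 GeoTIFFs (written through
``tifffile`` with ModelPixelScale / ModelTiepoint / GDAL_NODATA tags); the
band is stored top-row-first as GeoTIFF requires and flipped on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigurationError, ValidationError

NODATA_DEFAULT = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A rectangular single-band raster on a planar km grid."""

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    nodata: float = NODATA_DEFAULT
    crs: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ConfigurationError("raster values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        nr, nc = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point(s) to (row, col) by floor division; raises if outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValidationError("non-finite coordinates")
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y - y0) / self.cell_size).astype(int)
        nr, nc = self.shape
        # points exactly on the top/right edge belong to the last cell
        col = np.where((x == x0 + nc * self.cell_size), nc - 1, col)
        row = np.where((y == y0 + nr * self.cell_size), nr - 1, row)
        if np.any(col < 0) or np.any(col >= nc) or np.any(row < 0) or np.any(row >= nr):
            raise ValidationError("point(s) outside raster extent")
        return row, col

    def value_at(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return self.values[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, same shape as values."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    # -- statistics over valid cells ---------------------------------------
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """Same geometry, new band."""
        return RasterGrid(values=np.asarray(values, dtype=float),
                          origin=self.origin, cell_size=self.cell_size,
                          nodata=self.nodata, crs=self.crs)

    def buffer_mean(self, x: float, y: float, radius: float) -> float:
        """Mean of valid cells whose centres lie within ``radius`` km of (x, y).

        Returns NaN when the buffer contains no valid cell.
        """
        cx, cy = self.cell_centers()
        inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius ** 2
        sel = inside & self.mask()
        if not np.any(sel):
            return float("nan")
        return float(self.values[sel].mean())


def same_geometry(a: RasterGrid, b: RasterGrid, atol: float = 1e-9) -> bool:
    return (a.shape == b.shape
            and abs(a.cell_size - b.cell_size) <= atol
            and abs(a.origin[0] - b.origin[0]) <= atol
            and abs(a.origin[1] - b.origin[1]) <= atol)


# -- GeoTIFF I/O -------------------------------------------------------------

def write_geotiff(path, grid: RasterGrid) -> None:
    """Write a single-band float32 GeoTIFF with geo tags and nodata."""
    nr, _ = grid.shape
    x0, y0 = grid.origin
    y_top = y0 + nr * grid.cell_size
    band = np.flipud(grid.values).astype(np.float32)  # GeoTIFF rows start at top
    h = float(grid.cell_size)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (h, h, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y_top), 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata), True),
    ]
    tifffile.imwrite(str(path), band, extratags=extratags,
                     description=grid.crs or "")


def read_geotiff(path) -> RasterGrid:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        band = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValidationError(f"{path}: missing geo tags, not a GeoTIFF")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = NODATA_DEFAULT
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs = None
        if 270 in tags and tags[270].value:
            crs = str(tags[270].value)
    if band.ndim != 2:
        raise ValidationError(f"{path}: expected a single band")
    h = float(scale[0])
    nr = band.shape[0]
    x0 = float(tie[3])
    y0 = float(tie[4]) - nr * h
    return RasterGrid(values=np.flipud(band).astype(float),
                      origin=(x0, y0), cell_size=h, nodata=nodata, crs=crs)
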