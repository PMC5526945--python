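"""Regular single-band rasters in local planar metre coordinates.

A :class:`RasterGrid` stores a rectangular 2-D field (elevation, land-surface
temperature, slope, uplift velocity, ...) with square cells, the origin at the
lower-left corner of the grid, and an optional nodata sentinel.  Rows are
stored top-down (row 0 is the northernmost row), the usual raster order.

Supported on-disk formats are the ESRI ASCII grid (``.asc``/``.agr``, plain
text) and single-band TIFF (``.tif``/``.tiff``) with the GeoTIFF pixel-scale,
tie-point and nodata tags.  Coordinates are treated as local planar metres;
no CRS handling or reprojection is performed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["RasterGrid", "read_raster", "write_raster", "ExtentError"]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class ExtentError(ValueError):
    """A queried point lies outside the raster extent."""


@dataclass
class RasterGrid:
    """A rectangular grid of values with square cells.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.  Nodata cells are stored
        as NaN internally regardless of the on-disk sentinel.
    cell_size_m
        Edge length of a (square) cell, metres; must be positive.
    origin_xy
        ``(x, y)`` of the lower-left corner of the grid, metres.
    nodata
        Sentinel written on export; internally nodata is always NaN.
    """

    values: np.ndarray
    cell_size_m: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    nodata: float = field(default=-9999.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be positive")
        # normalise the sentinel to NaN so arithmetic propagates nodata
        if np.isfinite(self.nodata):
            self.values = np.where(self.values == self.nodata, np.nan, self.values)

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin_xy
        return (x0, y0, x0 + ncols * self.cell_size_m, y0 + nrows * self.cell_size_m)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size_m - other.cell_size_m) <= tol
            and abs(self.origin_xy[0] - other.origin_xy[0]) <= tol
            and abs(self.origin_xy[1] - other.origin_xy[1]) <= tol
        )

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """A new grid with the same geometry and different values."""
        return RasterGrid(np.asarray(values, float), self.cell_size_m,
                          self.origin_xy, self.nodata)

    # ------------------------------------------------------------------
    def cell_index(self, x, y):
        """Row/column of the cells containing planar points ``(x, y)``.

        Cells are half-open intervals ``[x0, x0 + cell)`` and
        ``[y0, y0 + cell)``: a point on a shared edge belongs to the cell
        to its east / north.  Points outside the extent raise
        :class:`ExtentError`.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        nrows, ncols = self.values.shape
        col = np.floor((x - self.origin_xy[0]) / self.cell_size_m).astype(int)
        # row measured from the bottom, then flipped to top-down storage
        row_from_bottom = np.floor((y - self.origin_xy[1]) / self.cell_size_m).astype(int)
        bad = (col < 0) | (col >= ncols) | (row_from_bottom < 0) | (row_from_bottom >= nrows)
        if np.any(bad):
            raise ExtentError("point(s) outside raster extent")
        return nrows - 1 - row_from_bottom, col

    def sample(self, points) -> np.ndarray:
        """Nearest-cell values at ``points`` (iterable of ``(x, y)``)."""
        pts = np.atleast_2d(np.asarray(points, float))
        rows, cols = self.cell_index(pts[:, 0], pts[:, 1])
        return self.values[rows, cols]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (x, y) of cell-centre coordinates, top-down rows."""
        nrows, ncols = self.values.shape
        cs = self.cell_size_m
        xs = self.origin_xy[0] + (np.arange(ncols) + 0.5) * cs
        ys = self.origin_xy[1] + (nrows - 1 - np.arange(nrows) + 0.5) * cs
        return np.meshgrid(xs, ys)


def sample_raster(raster: RasterGrid, points) -> np.ndarray:
    """Value of the cell containing each point (nearest-cell rule)."""
    return raster.sample(points)


# ----------------------------------------------------------------------
# ESRI ASCII grid

def _read_ascii(path: str) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header["yllcorner"]
    else:  # centre convention
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2
    nodata = header.get("nodata_value", -9999.0)
    if body.shape != (nrows, ncols):
        raise ValueError(f"grid body {body.shape} does not match header ({nrows}, {ncols})")
    return RasterGrid(body, cell, (x0, y0), nodata)


def _write_ascii(path: str, grid: RasterGrid) -> None:
    nrows, ncols = grid.shape
    out = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_xy[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin_xy[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size_m:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        np.savetxt(fh, out, fmt="%.6f")


# ----------------------------------------------------------------------
# single-band TIFF with GeoTIFF georeferencing tags

def _read_tiff(path: str) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        cell = 1.0
        if _TAG_PIXEL_SCALE in tags:
            cell = float(tags[_TAG_PIXEL_SCALE].value[0])
        x0 = ytop = 0.0
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            x0, ytop = float(tp[3]), float(tp[4])
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    nrows = values.shape[0]
    y0 = ytop - nrows * cell
    return RasterGrid(values, cell, (x0, y0), nodata)


def _write_tiff(path: str, grid: RasterGrid) -> None:
    nrows = grid.shape[0]
    cs = grid.cell_size_m
    ytop = grid.origin_xy[1] + nrows * cs
    out = np.where(np.isnan(grid.values), grid.nodata, grid.values).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_xy[0], ytop, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


# ----------------------------------------------------------------------

def read_raster(path: str) -> RasterGrid:
    """Read a single-band raster (ESRI ASCII grid or TIFF) from disk."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".agr", ".txt"):
        return _read_ascii(path)
    if ext in (".tif", ".tiff"):
        return _read_tiff(path)
    raise ValueError(f"unsupported raster format: {ext!r}")


def write_raster(path: str, grid: RasterGrid) -> None:
    """Write a raster to disk; the format follows the file extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".agr", ".txt"):
        _write_ascii(path, grid)
    elif ext in (".tif", ".tiff"):
        _write_tiff(path, grid)
    else:
        raise ValueError(f"unsupported raster format: {ext!r}")
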