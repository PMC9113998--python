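"""Geo-referenced raster data model and GeoTIFF input/output.

A :class:`GeoGrid` is the universal carrier for every raster in the
pipeline: land cover, elevation, slope, walking speed, crossing cost and
travel time.  Grids live in WGS84 geographic coordinates with square cells
measured in decimal degrees; cell (0, 0) is the upper-left cell and a point
maps to the cell containing it under half-open intervals
``[edge, edge + cell_size)``.

Missing or impassable cells are carried internally as ``NaN`` and encoded
on disk as a declared nodata value, so files interoperate with standard GIS
tools.  Degree/metre conversion uses a single uniform factor of 111120
metres per degree on both axes — an equator-only approximation appropriate
for the equatorial study regions this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "METRES_PER_DEGREE",
    "GeoGrid",
    "BoundingBox",
    "read_geotiff",
    "write_geotiff",
    "resample_bilinear",
    "align_to",
    "degrees_to_metres",
    "metres_to_degrees",
]

#: Uniform conversion factor, metres per degree of latitude or longitude.
#: Valid close to the equator only; applied identically on both axes.
METRES_PER_DEGREE = 111120.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory declaring a geographic WGS84 raster (EPSG:4326),
# pixel-is-area convention.
_WGS84_GEOKEYS = (
    1, 1, 0, 3,
    1024, 0, 1, 2,      # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,      # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,   # GeographicTypeGeoKey = WGS84
)

DEFAULT_NODATA = -9999.0


def degrees_to_metres(delta: float) -> float:
    """Convert a distance in decimal degrees to metres (uniform factor)."""
    return delta * METRES_PER_DEGREE


def metres_to_degrees(metres: float) -> float:
    """Inverse of :func:`degrees_to_metres`."""
    return metres / METRES_PER_DEGREE


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned geographic extent used for clipping and validity checks."""

    min_lon: float
    min_lat: float
    max_lon: float
    max_lat: float

    def __post_init__(self) -> None:
        if not (self.min_lon < self.max_lon and self.min_lat < self.max_lat):
            raise ValueError(
                f"degenerate bounding box: ({self.min_lon}, {self.min_lat}, "
                f"{self.max_lon}, {self.max_lat})"
            )

    def contains(self, lon: float, lat: float) -> bool:
        return (self.min_lon <= lon <= self.max_lon
                and self.min_lat <= lat <= self.max_lat)


@dataclass
class GeoGrid:
    """A single-band geographic raster with square cells.

    Parameters
    ----------
    values:
        2-D float array; ``NaN`` marks nodata.  Non-finite values other
        than ``NaN`` are rejected.
    origin_lon, origin_lat:
        Longitude/latitude of the **upper-left corner** of cell (0, 0),
        in decimal degrees.
    cell_size:
        Cell edge length in decimal degrees (cells are square).
    nodata:
        Sentinel written to disk in place of ``NaN``.
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    nodata: float = field(default=DEFAULT_NODATA)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("empty grid")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if np.isinf(self.values).any():
            raise ValueError("grid values must be finite or NaN (no infinities)")

    # -- geometry -----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> BoundingBox:
        return BoundingBox(
            min_lon=self.origin_lon,
            min_lat=self.origin_lat - self.n_rows * self.cell_size,
            max_lon=self.origin_lon + self.n_cols * self.cell_size,
            max_lat=self.origin_lat,
        )

    def same_geometry(self, other: "GeoGrid", tol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and abs(self.origin_lon - other.origin_lon) < tol
                and abs(self.origin_lat - other.origin_lat) < tol
                and abs(self.cell_size - other.cell_size) < tol)

    def cell_containing(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; may be out of range."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        return row, col

    def in_grid(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_size_m(self) -> float:
        return degrees_to_metres(self.cell_size)

    def copy_with(self, values: np.ndarray) -> "GeoGrid":
        """New grid with the same geometry but different values."""
        return replace(self, values=np.asarray(values, dtype=np.float64))

    # -- equality (value + geometry, NaN-aware) -----------------------------

    def equals(self, other: "GeoGrid", tol: float = 0.0) -> bool:
        if not self.same_geometry(other):
            return False
        a, b = self.values, other.values
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            return False
        fin = ~np.isnan(a)
        if tol == 0.0:
            return bool(np.array_equal(a[fin], b[fin]))
        return bool(np.allclose(a[fin], b[fin], rtol=0, atol=tol))


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_geotiff(grid: GeoGrid, path) -> None:
    """Write a grid as a single-band float64 GeoTIFF.

    NaN cells are encoded as the grid's declared nodata value; the
    geotransform is stored in the standard ModelPixelScale/ModelTiepoint
    tags and the coordinate system declared as geographic WGS84.
    """
    data = grid.values.copy()
    data[np.isnan(data)] = grid.nodata
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_geotiff(path) -> GeoGrid:
    """Read a single-band GeoTIFF written by this package or standard tools.

    Raises
    ------
    ValueError
        For multi-band rasters, non-square cells, or files lacking a
        geotransform (ModelPixelScale + ModelTiepoint tags).
    FileNotFoundError
        If the file does not exist.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(
                f"{path}: expected a single-band raster, got shape {data.shape}"
            )
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing geotransform tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-12 * max(abs(sx), abs(sy)):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) not supported")
        tie = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> model (x, y, z); require (0, 0)
        if tie[0] != 0 or tie[1] != 0:
            raise ValueError(f"{path}: tiepoint not anchored at raster origin")
        origin_lon, origin_lat = tie[3], tie[4]
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    values = np.asarray(data, dtype=np.float64)
    values[values == nodata] = np.nan
    return GeoGrid(values=values, origin_lon=origin_lon, origin_lat=origin_lat,
                   cell_size=float(sx), nodata=nodata)


# ---------------------------------------------------------------------------
# Resampling and alignment
# ---------------------------------------------------------------------------

def _sample(grid: GeoGrid, lons: np.ndarray, lats: np.ndarray,
            mode: str) -> np.ndarray:
    """Sample grid values at geographic points.

    ``mode='bilinear'`` interpolates between cell centres with edge
    replication outside the centre lattice; any interpolation touching a
    NaN source cell yields NaN.  ``mode='nearest'`` takes the containing
    cell's value (suitable for categorical rasters).
    """
    # fractional index of each point in cell-centre coordinates
    fc = (lons - grid.origin_lon) / grid.cell_size - 0.5
    fr = (grid.origin_lat - lats) / grid.cell_size - 0.5
    coords = np.stack([fr.ravel(), fc.ravel()])
    if mode == "nearest":
        out = ndimage.map_coordinates(grid.values, coords, order=0,
                                      mode="nearest")
    elif mode == "bilinear":
        filled = np.nan_to_num(grid.values, nan=0.0)
        out = ndimage.map_coordinates(filled, coords, order=1, mode="nearest")
        na = ndimage.map_coordinates(
            np.isnan(grid.values).astype(np.float64), coords, order=1,
            mode="nearest")
        out[na > 1e-12] = np.nan
    else:  # pragma: no cover - caller bug
        raise ValueError(f"unknown sampling mode {mode!r}")
    return out.reshape(lons.shape)


def resample_bilinear(grid: GeoGrid, target_cell_size: float) -> GeoGrid:
    """Resample a continuous grid to a new resolution over the same extent.

    The output covers exactly the input extent; the number of cells per
    axis is ``round(extent / target_cell_size)``.  Values are bilinear
    interpolations of the input at the new cell centres; NaN propagates
    conservatively (any touched NaN source cell makes the output NaN).
    """
    if not target_cell_size > 0:
        raise ValueError("target_cell_size must be > 0")
    if grid.n_rows < 2 or grid.n_cols < 2:
        raise ValueError("cannot bilinearly resample a grid smaller than 2x2")
    n_rows = int(round(grid.n_rows * grid.cell_size / target_cell_size))
    n_cols = int(round(grid.n_cols * grid.cell_size / target_cell_size))
    if n_rows < 1 or n_cols < 1:
        raise ValueError("target_cell_size larger than grid extent")
    cols = np.arange(n_cols)
    rows = np.arange(n_rows)
    lons = grid.origin_lon + (cols[np.newaxis, :] + 0.5) * target_cell_size
    lats = grid.origin_lat - (rows[:, np.newaxis] + 0.5) * target_cell_size
    lons, lats = np.broadcast_arrays(lons, lats)
    values = _sample(grid, lons, lats, mode="bilinear")
    return GeoGrid(values=values, origin_lon=grid.origin_lon,
                   origin_lat=grid.origin_lat, cell_size=target_cell_size,
                   nodata=grid.nodata)


def align_to(grid: GeoGrid, reference: GeoGrid, mode: str = "bilinear") -> GeoGrid:
    """Re-grid ``grid`` onto ``reference``'s geometry.

    ``mode`` is ``'bilinear'`` for continuous fields (elevation, speed) or
    ``'nearest'`` for categorical ones (land-cover classes).  The grids
    must overlap spatially.
    """
    gb, rb = grid.bounds, reference.bounds
    if (gb.max_lon <= rb.min_lon or rb.max_lon <= gb.min_lon
            or gb.max_lat <= rb.min_lat or rb.max_lat <= gb.min_lat):
        raise ValueError("grids have disjoint extents; cannot align")
    if grid.same_geometry(reference):
        return grid.copy_with(grid.values.copy())
    cols = np.arange(reference.n_cols)
    rows = np.arange(reference.n_rows)
    lons = reference.origin_lon + (cols[np.newaxis, :] + 0.5) * reference.cell_size
    lats = reference.origin_lat - (rows[:, np.newaxis] + 0.5) * reference.cell_size
    lons, lats = np.broadcast_arrays(lons, lats)
    values = _sample(grid, lons, lats, mode=mode)
    return GeoGrid(values=values, origin_lon=reference.origin_lon,
                   origin_lat=reference.origin_lat,
                   cell_size=reference.cell_size, nodata=grid.nodata)
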