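"""Deterministic synthetic scenes for exercising the full pipeline.

A scene bundles the four inputs a real run needs — elevation, land cover,
roads and facilities — on a shared 20 m grid placed just north of the
equator, where the uniform degree-to-metre factor the pipeline uses is
valid.  Generators cover the pipeline's branches: a flat uniform scene
(analytic travel times), an island separated from the mainland by a water
ring (the two-pass water rule), and seeded random scenes with relief,
blocky land cover, an L-shaped two-category road and scattered facilities.

These scenes emulate the *structure* of real inputs (class codes, road
tags, grid geometry), not the statistics of real landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

from .core_grid import GeoGrid, METRES_PER_DEGREE, write_geotiff
from .facilities import Facility
from .roads import RoadLayer

__all__ = ["Scene", "make_uniform_scene", "make_island_scene",
           "make_random_scene", "write_scene"]

CELL_SIZE_DEG = 20.0 / METRES_PER_DEGREE  # a 20 m cell in degrees
ORIGIN_LON = 32.0
ORIGIN_LAT = 0.5                          # near-equatorial placement

#: land-cover codes a random scene draws from (all passable classes)
_LAND_CODES = (1, 2, 3, 4, 6, 7, 8)
WATER_CODE = 10


@dataclass
class Scene:
    dem: GeoGrid
    landcover: GeoGrid
    roads: RoadLayer
    facilities: list[Facility]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.dem.same_geometry(self.landcover):
            raise ValueError("scene grids must share geometry")


def _grid(values: np.ndarray) -> GeoGrid:
    return GeoGrid(values=values, origin_lon=ORIGIN_LON, origin_lat=ORIGIN_LAT,
                   cell_size=CELL_SIZE_DEG)


def _facility_at(grid: GeoGrid, row: int, col: int, fid: str,
                 ftype: str = "clinic") -> Facility:
    lon, lat = grid.cell_center(row, col)
    return Facility(id=fid, lon=lon, lat=lat, facility_type=ftype)


def make_uniform_scene(n: int, speed_class: int = 3) -> Scene:
    """Flat DEM, one land-cover class everywhere, no roads, one central
    facility.  Travel times on this scene have a closed form."""
    if n < 3:
        raise ValueError("uniform scene needs n >= 3")
    dem = _grid(np.full((n, n), 1000.0))
    lc = _grid(np.full((n, n), float(speed_class)))
    fac = _facility_at(dem, n // 2, n // 2, "f1")
    return Scene(dem=dem, landcover=lc, roads=RoadLayer(features=[]),
                 facilities=[fac],
                 description=f"uniform {n}x{n} class-{speed_class} scene")


def make_island_scene(n: int) -> Scene:
    """An island cut off from the mainland by a one-cell water ring.

    The island block occupies rows/cols 1..3 with water (class 10) on the
    surrounding ring (rows/cols 0..4); everything else is grassland
    mainland with a single facility in the lower-right.  Island cells can
    reach the facility only by crossing water.
    """
    if n < 9:
        raise ValueError("island scene needs n >= 9")
    lc = np.full((n, n), 3.0)
    lc[0:5, 0:5] = WATER_CODE          # ring ...
    lc[1:4, 1:4] = 3.0                 # ... around the island block
    dem = _grid(np.full((n, n), 1100.0))
    fac = _facility_at(dem, n - 2, n - 2, "f1")
    return Scene(dem=dem, landcover=_grid(lc), roads=RoadLayer(features=[]),
                 facilities=[fac], description=f"island {n}x{n} scene")


def make_random_scene(n: int, seed: int = 0, relief: float = 10.0,
                      n_facilities: int | None = None) -> Scene:
    """Seeded random scene: smooth DEM, blocky land cover, L-shaped road.

    ``relief`` is the maximum elevation change in metres over one 20 m
    cell as seen by the slope operator: the smoothed random field is
    rescaled so its steepest gradient equals ``relief`` per cell, making
    the scene's maximum percent slope exactly ``100 * relief / 20``.
    A relief of 30 m therefore guarantees at least one impassable
    (>100% slope) cell; a relief of 0 gives a perfectly flat DEM.
    """
    if n < 8:
        raise ValueError("random scene needs n >= 8")
    rng = np.random.default_rng(seed)

    field = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8)
    dy, dx = np.gradient(field, 20.0)
    gmax = float(np.hypot(dx, dy).max())
    if relief > 0 and gmax > 0:
        dem_values = field * (relief / 20.0) / gmax + 1000.0
    else:
        dem_values = np.zeros((n, n)) + 1000.0
    dem = _grid(dem_values)

    # blocky land cover: coarse random classes, nearest-neighbour upsampled
    k = max(2, n // 4)
    coarse = rng.choice(_LAND_CODES, size=(k, k)).astype(float)
    reps = int(np.ceil(n / k))
    lc = _grid(np.kron(coarse, np.ones((reps, reps)))[:n, :n])

    # L-shaped road: a fast primary road across the middle row, a slow
    # track heading south from its midpoint
    mid = n // 2
    west = dem.cell_center(mid, 0)
    east = dem.cell_center(mid, n - 1)
    south = dem.cell_center(n - 1, mid)
    roads = RoadLayer(features=[
        (LineString([west, east]), "primary"),
        (LineString([dem.cell_center(mid, mid), south]), "track"),
    ])

    if n_facilities is None:
        n_facilities = max(1, n // 8)
    cells = rng.choice(n * n, size=n_facilities, replace=False)
    facilities = [
        _facility_at(dem, int(c) // n, int(c) % n, f"f{i + 1}",
                     "clinic" if i % 2 == 0 else "hospital")
        for i, c in enumerate(cells)
    ]
    return Scene(dem=dem, landcover=lc, roads=roads, facilities=facilities,
                 description=f"random {n}x{n} scene (seed {seed}, relief {relief})")


def write_scene(scene: Scene, directory) -> dict[str, Path]:
    """Dump a scene to files (GeoTIFF, GeoJSON, CSV) for file-driven runs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "dem": directory / "dem.tif",
        "landcover": directory / "landcover.tif",
        "roads": directory / "roads.geojson",
        "facilities": directory / "facilities.csv",
    }
    write_geotiff(scene.dem, paths["dem"])
    write_geotiff(scene.landcover, paths["landcover"])
    scene.roads.to_geojson(paths["roads"])
    import pandas as pd

    pd.DataFrame(
        {
            "id": [f.id for f in scene.facilities],
            "longitude": [f.lon for f in scene.facilities],
            "latitude": [f.lat for f in scene.facilities],
            "type": [f.facility_type for f in scene.facilities],
        }
    ).to_csv(paths["facilities"], index=False)
    return paths
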