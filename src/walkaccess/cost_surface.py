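"""Assembly of the cost allocation ("friction") surfaces.

A cost surface holds, for every cell, the time in seconds to walk across
it.  Two twin surfaces are produced per run:

* **water-blocked** — open water is NaN, a hard barrier to travel;
* **water-passable** — open water is crossable at a slow configured speed
  (default 1.0 km/h), used only as a second pass for cells (islands) that
  cannot reach any facility over land.

Assembly order follows the speed pipeline: road speeds first, gaps filled
with land-cover speeds, multiplied by the slope impact ratio, converted
from km/h to m/s, then::

    seconds = cell_size_m / (speed_mps * impact * child_factor)

The child factor scales every speed, water included, so travel times for
adults and for adults with children differ by exactly that factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core_grid import GeoGrid, write_geotiff
from .speed_config import RunConfig, SpeedTable

__all__ = [
    "WATER_CLASS",
    "NODATA_CLASS",
    "CostSurface",
    "speeds_from_landcover",
    "overlay_speeds",
    "assemble",
]

WATER_CLASS = 10     # open-water land-cover code
NODATA_CLASS = 200   # missing-data land-cover code

KMH_TO_MPS = 1000.0 / 3600.0


@dataclass
class CostSurface:
    """Seconds-to-cross-cell grid plus the provenance that produced it."""

    grid: GeoGrid
    water_mode: str          # 'blocked' or 'passable'
    child_factor: float
    water_speed: float
    cell_size_m: float

    def __post_init__(self) -> None:
        if self.water_mode not in ("blocked", "passable"):
            raise ValueError(f"water_mode must be 'blocked' or 'passable', "
                             f"got {self.water_mode!r}")
        finite = self.grid.values[~np.isnan(self.grid.values)]
        if (finite <= 0).any():
            raise ValueError("cost surface contains non-positive crossing times")

    def write(self, path, metadata_path=None) -> None:
        """Write the surface as GeoTIFF plus an optional JSON sidecar."""
        write_geotiff(self.grid, path)
        if metadata_path is not None:
            meta = {
                "water_mode": self.water_mode,
                "child_factor": self.child_factor,
                "water_speed_kmh": self.water_speed,
                "cell_size_m": self.cell_size_m,
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def speeds_from_landcover(
    lc: GeoGrid,
    table: SpeedTable,
    water_mode: str = "blocked",
    water_speed: float = 1.0,
) -> GeoGrid:
    """Map land-cover class codes to walking speeds in km/h.

    Open water (class 10) is NaN in blocked mode and ``water_speed`` in
    passable mode regardless of the table row (the table ships it as NA);
    the missing-data class (200) is always NaN.  Any class code absent
    from the table raises, listing the offenders.
    """
    if water_mode not in ("blocked", "passable"):
        raise ValueError(f"bad water_mode {water_mode!r}")
    values = lc.values
    codes = np.unique(values[~np.isnan(values)]).astype(int)
    unknown = [int(c) for c in codes if str(int(c)) not in table]
    if unknown:
        raise ValueError(f"land-cover codes missing from speed table: {unknown}")
    out = np.full(lc.shape, np.nan)
    for code in codes:
        mask = values == code
        if code == WATER_CLASS:
            out[mask] = np.nan if water_mode == "blocked" else water_speed
        elif code == NODATA_CLASS:
            out[mask] = np.nan
        else:
            out[mask] = table.speed(str(int(code)))
    return lc.copy_with(out)


def overlay_speeds(road_speeds: GeoGrid, landcover_speeds: GeoGrid) -> GeoGrid:
    """Road speed where a road is present, land-cover speed elsewhere.

    Roads win even over water barriers (bridge semantics of the
    road-first rule).
    """
    if not road_speeds.same_geometry(landcover_speeds):
        raise ValueError("road and land-cover speed grids are not aligned")
    road = road_speeds.values
    out = np.where(np.isnan(road), landcover_speeds.values, road)
    return landcover_speeds.copy_with(out)


def assemble(
    speeds: GeoGrid,
    impact: GeoGrid,
    config: RunConfig,
    water_mode: str,
) -> CostSurface:
    """Combine speeds (km/h), slope impact and the child factor into
    seconds-to-cross-cell.

    NaN in either input (barrier land cover or impassable slope) makes the
    cell NaN: an impassable slope dominates even a road.
    """
    if not speeds.same_geometry(impact):
        raise ValueError("speed and impact grids are not aligned")
    s, imp = speeds.values, impact.values
    bad = (~np.isnan(s) & (s <= 0)) | (~np.isnan(imp) & (imp <= 0))
    if bad.any():
        raise ValueError("non-positive speed or impact values in inputs")
    with np.errstate(invalid="ignore"):
        seconds = config.cell_size_m / (
            s * KMH_TO_MPS * imp * config.child_factor
        )
    return CostSurface(
        grid=speeds.copy_with(seconds),
        water_mode=water_mode,
        child_factor=config.child_factor,
        water_speed=config.water_speed,
        cell_size_m=config.cell_size_m,
    )
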