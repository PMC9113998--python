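"""Road vector layer and its conversion to a walking-speed raster.

Roads carry the fastest pedestrian speeds in the cost model (people
preferentially walk along road verges), so the road layer is burned onto
the reference grid before land cover fills the gaps.  Rasterization is
*all-touched*: a cell is marked iff any road segment geometrically
intersects its closed square.  This guarantees that a rasterized polyline
stays 8-connected, preserving network connectivity — a centroid- or
area-threshold rule would break diagonal runs into disconnected cells.

Where roads of different categories share a cell, the fastest speed wins
by default ("speed priority"); priority can be turned off, in which case
later features overwrite earlier ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, box, shape, mapping

from .core_grid import GeoGrid
from .speed_config import (
    SpeedTable,
    UNKNOWN_ROAD_CATEGORY,
    fuzzy_match_categories,
)

__all__ = ["RoadLayer", "rasterize_roads", "resolve_road_speeds"]


@dataclass
class RoadLayer:
    """Categorised road polylines in geographic coordinates.

    Each feature is a ``(geometry, tag)`` pair where ``tag`` holds the
    road category (the OSM-style highway class).
    """

    features: list[tuple[LineString, str]]

    def __post_init__(self) -> None:
        for geom, tag in self.features:
            if not isinstance(tag, str) or not tag.strip():
                raise ValueError("every road feature needs a non-empty tag")
            if len(geom.coords) < 2:
                raise ValueError("road geometries need at least 2 vertices")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def tags(self) -> list[str]:
        return sorted({tag for _, tag in self.features})

    # -- GeoJSON I/O --------------------------------------------------------

    @classmethod
    def from_geojson(cls, path) -> "RoadLayer":
        with open(path) as fh:
            gj = json.load(fh)
        features = []
        for feat in gj.get("features", []):
            geom = shape(feat["geometry"])
            tag = feat.get("properties", {}).get("tag")
            if tag is None:
                raise ValueError(f"{path}: road feature missing 'tag' property")
            if geom.geom_type == "MultiLineString":
                for part in geom.geoms:
                    features.append((part, str(tag)))
            elif geom.geom_type == "LineString":
                features.append((geom, str(tag)))
            else:
                raise ValueError(
                    f"{path}: unsupported geometry type {geom.geom_type}"
                )
        return cls(features=features)

    def to_geojson(self, path) -> None:
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {"tag": tag},
                }
                for geom, tag in self.features
            ],
        }
        with open(path, "w") as fh:
            json.dump(gj, fh)


def resolve_road_speeds(layer_tags: list[str], table: SpeedTable,
                        threshold: float = 80.0) -> dict[str, float]:
    """Assign a speed to every road tag via fuzzy name matching.

    Tags with no table match at the threshold fall back to the 'unknown'
    category's speed and are reported with a warning, so every road always
    receives a speed.
    """
    if not layer_tags:
        return {}
    mapping_, unmatched = fuzzy_match_categories(
        table.categories, layer_tags, threshold=threshold
    )
    speeds = {tag: table.speed(cat) for tag, cat in mapping_.items()}
    if unmatched:
        if UNKNOWN_ROAD_CATEGORY not in table:
            raise ValueError(
                f"unmatched road categories {unmatched} and no "
                f"{UNKNOWN_ROAD_CATEGORY!r} fallback row in the speed table"
            )
        fallback = table.speed(UNKNOWN_ROAD_CATEGORY)
        warnings.warn(
            f"road categories {unmatched} not matched; "
            f"using {UNKNOWN_ROAD_CATEGORY!r} speed {fallback} km/h"
        )
        for tag in unmatched:
            speeds[tag] = fallback
    return speeds


def _touched_cells(geom: LineString, reference: GeoGrid) -> list[tuple[int, int]]:
    """All cells whose closed square intersects the polyline."""
    cs = reference.cell_size
    x0, yN = reference.origin_lon, reference.origin_lat
    cells: set[tuple[int, int]] = set()
    coords = np.asarray(geom.coords)
    for (ax, ay), (bx, by) in zip(coords[:-1], coords[1:]):
        seg = LineString([(ax, ay), (bx, by)])
        c_lo = int(np.floor((min(ax, bx) - x0) / cs))
        c_hi = int(np.floor((max(ax, bx) - x0) / cs))
        r_lo = int(np.floor((yN - max(ay, by)) / cs))
        r_hi = int(np.floor((yN - min(ay, by)) / cs))
        c_lo, c_hi = max(c_lo, 0), min(c_hi, reference.n_cols - 1)
        r_lo, r_hi = max(r_lo, 0), min(r_hi, reference.n_rows - 1)
        if c_lo > c_hi or r_lo > r_hi:
            continue
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi + 1),
                             np.arange(c_lo, c_hi + 1), indexing="ij")
        rr, cc = rr.ravel(), cc.ravel()
        boxes = shapely.box(
            x0 + cc * cs, yN - (rr + 1) * cs,
            x0 + (cc + 1) * cs, yN - rr * cs,
        )
        hit = shapely.intersects(boxes, seg)
        cells.update(zip(rr[hit].tolist(), cc[hit].tolist()))
    return sorted(cells)


def rasterize_roads(
    roads: RoadLayer,
    speeds: dict[str, float],
    reference: GeoGrid,
    priority: bool = True,
) -> GeoGrid:
    """Burn road walking speeds onto the reference grid.

    Features are grouped by speed and each group rasterized separately;
    the groups are then merged taking the maximum value per cell
    (``priority=True``, the default) so that the fastest road wins where
    categories overlap.  With ``priority=False`` later features simply
    overwrite earlier ones.  Cells no road touches are NaN.
    """
    if reference.values.size == 0:  # pragma: no cover - GeoGrid already rejects
        raise ValueError("empty reference grid")
    out = np.full(reference.shape, np.nan)
    for geom, tag in roads.features:
        if tag not in speeds:
            raise ValueError(f"no speed resolved for road tag {tag!r}")
        speed = speeds[tag]
        if np.isnan(speed):
            continue
        for r, c in _touched_cells(geom, reference):
            if priority:
                prev = out[r, c]
                out[r, c] = speed if np.isnan(prev) else max(prev, speed)
            else:
                out[r, c] = speed
    return reference.copy_with(out)
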