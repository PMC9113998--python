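"""In-memory orchestration of the full pipeline.

These functions connect the per-stage modules without touching the file
system, so the same code path serves the command-line tool, the tests and
programmatic use on synthetic scenes.
"""

from __future__ import annotations

from .core_grid import BoundingBox, GeoGrid, align_to
from .cost_surface import CostSurface, assemble, overlay_speeds, speeds_from_landcover
from .facilities import Facility, FacilityReport, filter_by_type, validate_and_snap
from .roads import RoadLayer, rasterize_roads, resolve_road_speeds
from .speed_config import RunConfig, SpeedTable, default_speed_table
from .synthetic import Scene
from .terrain import impact_grid, slope_percent
from .travel_time import to_minutes, two_pass_travel_time

__all__ = ["build_cost_surfaces", "solve_travel_time", "run_scene"]


def build_cost_surfaces(
    landcover: GeoGrid,
    dem: GeoGrid,
    roads: RoadLayer,
    config: RunConfig,
    lc_table: SpeedTable | None = None,
    road_table: SpeedTable | None = None,
) -> dict[str, CostSurface]:
    """Water-blocked and water-passable cost surfaces for one scene."""
    if lc_table is None:
        lc_table = default_speed_table("landcover")
    if road_table is None:
        road_table = default_speed_table("road")
    if not dem.same_geometry(landcover):
        dem = align_to(dem, landcover, mode="bilinear")
    road_speed_map = resolve_road_speeds(roads.tags, road_table,
                                         threshold=config.fuzzy_threshold)
    road_speeds = rasterize_roads(roads, road_speed_map, landcover,
                                  priority=config.road_priority)
    impact = impact_grid(slope_percent(dem))
    surfaces: dict[str, CostSurface] = {}
    for mode in ("blocked", "passable"):
        lc_speeds = speeds_from_landcover(landcover, lc_table, water_mode=mode,
                                          water_speed=config.water_speed)
        speeds = overlay_speeds(road_speeds, lc_speeds)
        surfaces[mode] = assemble(speeds, impact, config, water_mode=mode)
    return surfaces


def solve_travel_time(
    surfaces: dict[str, CostSurface],
    facilities: list[Facility],
    config: RunConfig,
    boundary: BoundingBox | None = None,
) -> tuple[GeoGrid, FacilityReport]:
    """Audit facilities and solve the two-pass travel time, in minutes."""
    wanted = set(config.facility_types) or None
    facilities = filter_by_type(facilities, wanted)
    sources, report = validate_and_snap(facilities, surfaces["blocked"],
                                        boundary=boundary,
                                        rng_seed=config.rng_seed)
    seconds = two_pass_travel_time(surfaces["blocked"], surfaces["passable"],
                                   sources)
    return to_minutes(seconds, like=surfaces["blocked"].grid), report


def run_scene(scene: Scene, config: RunConfig | None = None):
    """Full pipeline on a synthetic scene.

    Returns ``(minutes_grid, surfaces, report)``.
    """
    if config is None:
        config = RunConfig()
    surfaces = build_cost_surfaces(scene.landcover, scene.dem, scene.roads,
                                   config)
    minutes, report = solve_travel_time(surfaces, scene.facilities, config)
    return minutes, surfaces, report
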