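"""Health-facility points: loading, type filtering, validation and snapping.

Facility coordinates come from registries whose positional quality is
mixed: points fall outside the study boundary, on open water, or on cells
the slope gate has removed.  Before the travel-time solve each facility is
audited against the water-blocked cost surface:

* outside the boundary or the grid  -> removed;
* on a passable cell                -> kept;
* on an impassable (NaN) cell with at least one passable 8-neighbour
  -> moved to one such neighbour chosen uniformly at random (seeded);
* on an impassable cell with no passable neighbour -> removed.

Every decision is logged in a :class:`FacilityReport` that partitions the
input facilities exactly into kept / moved / removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_grid import BoundingBox
from .cost_surface import CostSurface

__all__ = [
    "Facility",
    "FacilityRecord",
    "FacilityReport",
    "load_facilities",
    "filter_by_type",
    "validate_and_snap",
]

_NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1),
                 (0, -1),           (0, 1),
                 (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class Facility:
    id: str
    lon: float
    lat: float
    facility_type: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.lon) or not np.isfinite(self.lat):
            raise ValueError(f"facility {self.id!r}: non-finite coordinates")


@dataclass(frozen=True)
class FacilityRecord:
    """One audit row: what happened to one input facility and why."""

    id: str
    action: str                       # 'kept' | 'moved' | 'removed'
    reason: str
    original_cell: tuple[int, int] | None
    final_cell: tuple[int, int] | None


@dataclass
class FacilityReport:
    rows: list[FacilityRecord]

    def count(self, action: str) -> int:
        return sum(1 for r in self.rows if r.action == action)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.rows],
                "action": [r.action for r in self.rows],
                "reason": [r.reason for r in self.rows],
                "original_row": [None if r.original_cell is None
                                 else r.original_cell[0] for r in self.rows],
                "original_col": [None if r.original_cell is None
                                 else r.original_cell[1] for r in self.rows],
                "final_row": [None if r.final_cell is None
                              else r.final_cell[0] for r in self.rows],
                "final_col": [None if r.final_cell is None
                              else r.final_cell[1] for r in self.rows],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


_COLUMN_ALIASES = {
    "id": ("id", "facility_id"),
    "lon": ("lon", "longitude", "long", "x"),
    "lat": ("lat", "latitude", "y"),
    "type": ("type", "facility_type", "amenity"),
}


def _find_column(df: pd.DataFrame, key: str, required: bool = True) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for alias in _COLUMN_ALIASES[key]:
        if alias in lower:
            return lower[alias]
    if required:
        raise ValueError(f"facility table missing a column for {key!r} "
                         f"(accepted names: {_COLUMN_ALIASES[key]})")
    return None


def load_facilities(path) -> list[Facility]:
    """Read facilities from a CSV with id, longitude, latitude, type columns.

    Rows with unparseable coordinates are skipped with a row-level warning;
    duplicate ids are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    id_col = _find_column(df, "id")
    lon_col = _find_column(df, "lon")
    lat_col = _find_column(df, "lat")
    type_col = _find_column(df, "type", required=False)
    facilities: list[Facility] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        fid = str(row[id_col]).strip()
        if fid in seen:
            raise ValueError(f"{path}: duplicate facility id {fid!r}")
        seen.add(fid)
        try:
            lon, lat = float(row[lon_col]), float(row[lat_col])
            if not (np.isfinite(lon) and np.isfinite(lat)):
                raise ValueError
        except (TypeError, ValueError):
            warnings.warn(
                f"{path}: row {i} (id {fid!r}) has non-numeric coordinates; skipped"
            )
            continue
        ftype = str(row[type_col]).strip() if type_col else ""
        facilities.append(Facility(id=fid, lon=lon, lat=lat, facility_type=ftype))
    return facilities


def filter_by_type(facilities: list[Facility],
                   wanted_types: set[str] | None) -> list[Facility]:
    """Keep facilities of the wanted types; empty/None set means any type."""
    if not wanted_types:
        return list(facilities)
    wanted = {t.strip().lower() for t in wanted_types}
    kept = [f for f in facilities if f.facility_type.strip().lower() in wanted]
    if not kept:
        warnings.warn(f"no facilities of types {sorted(wanted)} in the data")
    return kept


def validate_and_snap(
    facilities: list[Facility],
    surface: CostSurface,
    boundary: BoundingBox | None = None,
    rng_seed: int = 0,
) -> tuple[list[tuple[int, int]], FacilityReport]:
    """Audit facilities against the water-blocked surface.

    Returns the deduplicated list of passable source cells (input order
    preserved) and the per-facility report.  Raises if no facility
    survives — the solver would have no destinations.
    """
    grid = surface.grid
    passable = ~np.isnan(grid.values)
    rng = np.random.default_rng(rng_seed)
    rows: list[FacilityRecord] = []
    sources: list[tuple[int, int]] = []
    seen_cells: set[tuple[int, int]] = set()

    for fac in facilities:
        if boundary is not None and not boundary.contains(fac.lon, fac.lat):
            rows.append(FacilityRecord(fac.id, "removed", "outside boundary",
                                       None, None))
            continue
        cell = grid.cell_containing(fac.lon, fac.lat)
        if not grid.in_grid(*cell):
            rows.append(FacilityRecord(fac.id, "removed", "outside grid extent",
                                       None, None))
            continue
        if passable[cell]:
            rows.append(FacilityRecord(fac.id, "kept", "on passable cell",
                                       cell, cell))
            final = cell
        else:
            candidates = [
                (cell[0] + dr, cell[1] + dc)
                for dr, dc in _NEIGHBOURS_8
                if grid.in_grid(cell[0] + dr, cell[1] + dc)
                and passable[cell[0] + dr, cell[1] + dc]
            ]
            if not candidates:
                rows.append(FacilityRecord(
                    fac.id, "removed",
                    "impassable cell with no passable neighbour", cell, None))
                continue
            final = candidates[int(rng.integers(len(candidates)))]
            rows.append(FacilityRecord(
                fac.id, "moved", "impassable cell; snapped to passable neighbour",
                cell, final))
        if final not in seen_cells:
            seen_cells.add(final)
            sources.append(final)

    if not sources:
        raise ValueError("no valid facility locations survive validation; "
                         "travel time has no destinations")
    return sources, FacilityReport(rows=rows)
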