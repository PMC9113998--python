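"""Walking-speed tables, run configuration and the child speed reduction.

Two CSV tables drive the cost model: land-cover class speeds (keyed by the
integer class code of the land-cover product) and road-category speeds
(keyed by the highway tag of the road layer).  Speeds are stored in km/h as
printed in the source tables; ``NA`` marks categories that act as barriers
(open water, flooded ground, missing data).

The child reduction models an adult walking accompanied by, or carrying, a
young child: observed speeds drop by roughly 22%, which the pipeline
applies as a single multiplicative factor (default 0.78) to every walking
speed.  Setting the factor to 1.0 produces adult surfaces.
"""

from __future__ import annotations

import configparser
import importlib.resources
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpeedTable",
    "RunConfig",
    "load_speed_table",
    "default_speed_table",
    "load_run_config",
    "fuzzy_match_categories",
    "child_weight",
    "DEFAULT_CHILD_FACTOR",
    "DEFAULT_WATER_SPEED",
    "DEFAULT_CELL_SIZE_M",
    "DEFAULT_MAX_SPEED",
    "UNKNOWN_ROAD_CATEGORY",
]

DEFAULT_CHILD_FACTOR = 0.78   # 22% reduction for travel with children
DEFAULT_WATER_SPEED = 1.0     # km/h, water-passable surface only
DEFAULT_CELL_SIZE_M = 20.0    # metres
DEFAULT_MAX_SPEED = 5.0       # km/h, fastest pedestrian speed (main roads)
UNKNOWN_ROAD_CATEGORY = "unknown"

_NA_STRINGS = {"na", "n/a", "nan", ""}


@dataclass(frozen=True)
class SpeedTable:
    """Mapping from category (road tag or land-cover code) to km/h speed.

    ``NaN`` speeds are legal and mean "barrier" — the category is
    impassable (its semantics are decided by the cost-surface assembly).
    """

    kind: str                       # 'road' or 'landcover'
    entries: dict[str, float]       # category -> speed (km/h) or NaN

    def __post_init__(self) -> None:
        if self.kind not in ("road", "landcover"):
            raise ValueError(f"kind must be 'road' or 'landcover', got {self.kind!r}")

    def speed(self, category: str) -> float:
        return self.entries[_norm(str(category))]

    def __contains__(self, category: str) -> bool:
        return _norm(str(category)) in self.entries

    @property
    def categories(self) -> list[str]:
        return list(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(self.entries), "speed": list(self.entries.values())}
        )


def _norm(category: str) -> str:
    return category.strip().lower()


def _parse_speed(raw) -> float:
    if isinstance(raw, str) and raw.strip().lower() in _NA_STRINGS:
        return np.nan
    value = float(raw)
    return value


def load_speed_table(path, kind: str,
                     max_speed: float = DEFAULT_MAX_SPEED) -> SpeedTable:
    """Load and validate a ``category,speed`` CSV.

    Raises on duplicate categories, non-positive speeds, speeds above the
    configured pedestrian maximum, and unparseable rows.  ``NA`` speeds are
    preserved as NaN.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    if "category" not in cols or "speed" not in cols:
        raise ValueError(f"{path}: expected columns 'category' and 'speed'")
    df.columns = cols
    entries: dict[str, float] = {}
    for i, row in df.iterrows():
        cat = _norm(str(row["category"]))
        if not cat:
            raise ValueError(f"{path}: empty category on row {i}")
        try:
            speed = _parse_speed(row["speed"])
        except ValueError as exc:
            raise ValueError(f"{path}: bad speed {row['speed']!r} on row {i}") from exc
        if cat in entries:
            raise ValueError(f"{path}: duplicate category {cat!r}")
        if not np.isnan(speed):
            if speed <= 0:
                raise ValueError(f"{path}: non-positive speed {speed} for {cat!r}")
            if speed > max_speed:
                raise ValueError(
                    f"{path}: speed {speed} for {cat!r} exceeds maximum {max_speed}"
                )
        entries[cat] = speed
    if not entries:
        raise ValueError(f"{path}: empty speed table")
    return SpeedTable(kind=kind, entries=entries)


def default_speed_table(kind: str) -> SpeedTable:
    """The packaged default table: land-cover class speeds or road speeds."""
    name = {"landcover": "landcovercosts.csv", "road": "roadcosts.csv"}[kind]
    ref = importlib.resources.files("walkaccess.data") / name
    with importlib.resources.as_file(ref) as p:
        return load_speed_table(p, kind)


@dataclass
class RunConfig:
    """Everything a pipeline run needs: paths, parameters and the seed."""

    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    child_factor: float = DEFAULT_CHILD_FACTOR
    water_speed: float = DEFAULT_WATER_SPEED
    cell_size_m: float = DEFAULT_CELL_SIZE_M
    max_speed: float = DEFAULT_MAX_SPEED
    fuzzy_threshold: float = 80.0
    road_priority: bool = True
    facility_types: tuple[str, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.child_factor <= 1:
            raise ValueError(f"child_factor must be in (0, 1], got {self.child_factor}")
        if not self.water_speed > 0:
            raise ValueError(f"water_speed must be > 0, got {self.water_speed}")
        if not self.cell_size_m > 0:
            raise ValueError(f"cell_size_m must be > 0, got {self.cell_size_m}")

    def input_path(self, key: str, required: bool = True) -> Path | None:
        if key not in self.inputs:
            if required:
                raise ValueError(f"configuration missing required input {key!r}")
            return None
        return Path(self.inputs[key])


def load_run_config(path) -> RunConfig:
    """Parse an INI-style run configuration.

    Sections ``[inputs]`` and ``[outputs]`` hold file paths;
    ``[parameters]`` holds the numeric settings, all optional with the
    documented defaults (child_factor 0.78, water_speed 1.0 km/h,
    cell_size_m 20).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cp = configparser.ConfigParser()
    cp.read(path)
    params = cp["parameters"] if cp.has_section("parameters") else {}
    types = params.get("facility_types", "") if params else ""
    facility_types = tuple(t.strip() for t in types.split(",") if t.strip())

    def _get(key, default, cast):
        return cast(params.get(key, default)) if params else default

    return RunConfig(
        inputs=dict(cp["inputs"]) if cp.has_section("inputs") else {},
        outputs=dict(cp["outputs"]) if cp.has_section("outputs") else {},
        child_factor=_get("child_factor", DEFAULT_CHILD_FACTOR, float),
        water_speed=_get("water_speed", DEFAULT_WATER_SPEED, float),
        cell_size_m=_get("cell_size_m", DEFAULT_CELL_SIZE_M, float),
        max_speed=_get("max_speed", DEFAULT_MAX_SPEED, float),
        fuzzy_threshold=_get("fuzzy_threshold", 80.0, float),
        road_priority=_get("road_priority", True,
                           lambda v: str(v).strip().lower() not in ("false", "0", "no")),
        facility_types=facility_types,
        rng_seed=_get("seed", 0, int),
    )


def fuzzy_match_categories(
    table_categories: list[str],
    layer_categories: list[str],
    threshold: float = 80.0,
) -> tuple[dict[str, str], list[str]]:
    """Match road-layer category names to speed-table categories.

    Names are normalised (lowercase, trimmed) first; each layer category
    maps to the table category with the highest similarity (0-100 scale)
    at or above ``threshold``.  Categories with no sufficiently similar
    table entry come back in ``unmatched`` — downstream they receive the
    'unknown' road speed rather than failing the run.
    """
    if not table_categories or not layer_categories:
        raise ValueError("both category lists must be non-empty")
    norm_table = {_norm(t): t for t in table_categories}
    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for layer_cat in layer_categories:
        key = _norm(layer_cat)
        if key in norm_table:
            mapping[layer_cat] = norm_table[key]
            continue
        best_cat, best_score = None, -1.0
        for tkey, tcat in norm_table.items():
            score = 100.0 * SequenceMatcher(None, key, tkey).ratio()
            if score > best_score:
                best_cat, best_score = tcat, score
        if best_score >= threshold:
            mapping[layer_cat] = best_cat
        else:
            unmatched.append(layer_cat)
    return mapping, unmatched


def child_weight(speed, child_factor: float = DEFAULT_CHILD_FACTOR):
    """Apply the child walking-speed reduction; NaN (barrier) stays NaN.

    Works on scalars and arrays alike.
    """
    if not 0 < child_factor <= 1:
        raise ValueError(f"child_factor must be in (0, 1], got {child_factor}")
    return speed * child_factor
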