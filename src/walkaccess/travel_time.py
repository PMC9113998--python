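"""Multi-source least-cost travel time and validation utilities.

The travel-time map answers, for every cell, "how many minutes does the
nearest health facility take to reach on foot?".  It is a multi-source
shortest-path problem on the 8-connected grid graph whose edge cost
between adjacent cells i and j is::

    0.5 * (c_i + c_j) * d

with ``c`` the cells' seconds-to-cross values and ``d`` the step length in
cell units (1 orthogonal, sqrt(2) diagonal) — so a straight orthogonal
traverse of k uniform cells costs exactly k*c.  The solve uses the
geometric minimum-cost-path routine of scikit-image, initialised from all
facility cells at once; NaN cells are impassable and unreachable cells
come back as +inf.

The two-pass water rule handles islands: travel time is first computed on
the water-blocked surface; only cells that are unreachable there (they
must cross water) take their value from a second solve on the
water-passable surface.  Cells unreachable in both passes are NA.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from skimage.graph import MCP_Geometric

from .core_grid import GeoGrid
from .cost_surface import CostSurface

__all__ = [
    "cost_distance",
    "two_pass_travel_time",
    "to_minutes",
    "extract_at_points",
    "summary_stats",
    "threshold_counts",
    "rank_correlation",
]


def cost_distance(surface: CostSurface,
                  sources: list[tuple[int, int]]) -> np.ndarray:
    """Seconds from every cell to its nearest source over the cost surface.

    Returns a float array of the grid's shape: 0 at sources, +inf where no
    path exists (including NaN/impassable cells themselves).
    """
    if not sources:
        raise ValueError("at least one source cell is required")
    costs = surface.grid.values.copy()
    costs[np.isnan(costs)] = np.inf
    for cell in sources:
        if not surface.grid.in_grid(*cell):
            raise ValueError(f"source cell {cell} outside the grid")
        if np.isinf(costs[cell]):
            raise ValueError(f"source cell {cell} is impassable")
    mcp = MCP_Geometric(costs, fully_connected=True)
    cumulative, _ = mcp.find_costs(starts=list(sources))
    return np.asarray(cumulative, dtype=np.float64)


def two_pass_travel_time(
    blocked: CostSurface,
    passable: CostSurface,
    sources: list[tuple[int, int]],
) -> np.ndarray:
    """Travel time in seconds under the two-pass water-barrier rule.

    Pass 1 runs on the water-blocked surface; cells finite there keep
    their value.  Cells infinite in pass 1 — those that must traverse
    water — take their value from a pass-2 solve on the water-passable
    surface.  Cells infinite in both passes stay +inf.
    """
    if not blocked.grid.same_geometry(passable.grid):
        raise ValueError("blocked and passable surfaces have different geometry")
    t1 = cost_distance(blocked, sources)
    needs_water = np.isinf(t1)
    if not needs_water.any():
        return t1
    t2 = cost_distance(passable, sources)
    return np.where(needs_water, t2, t1)


def to_minutes(seconds: np.ndarray, like: GeoGrid) -> GeoGrid:
    """Convert a seconds array to a minutes grid; +inf becomes NA."""
    minutes = np.asarray(seconds, dtype=np.float64) / 60.0
    minutes[np.isinf(minutes)] = np.nan
    return like.copy_with(minutes)


def extract_at_points(grid: GeoGrid,
                      points: list[tuple[float, float]]) -> np.ndarray:
    """Value of the containing cell for each (lon, lat) point.

    Points outside the grid extent yield NaN with a warning.
    """
    out = np.empty(len(points))
    n_outside = 0
    for i, (lon, lat) in enumerate(points):
        cell = grid.cell_containing(lon, lat)
        if grid.in_grid(*cell):
            out[i] = grid.values[cell]
        else:
            out[i] = np.nan
            n_outside += 1
    if n_outside:
        warnings.warn(f"{n_outside} point(s) outside the grid extent; NA returned")
    return out


def summary_stats(values) -> dict[str, float]:
    """Min, quartiles, mean and max over the non-NA values."""
    arr = np.asarray(values, dtype=np.float64).ravel()
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("summary_stats requires at least one non-NA value")
    return {
        "min": float(arr.min()),
        "q1": float(np.percentile(arr, 25)),
        "median": float(np.percentile(arr, 50)),
        "mean": float(arr.mean()),
        "q3": float(np.percentile(arr, 75)),
        "max": float(arr.max()),
    }


def threshold_counts(values, bounds: list[float]) -> list[int]:
    """Counts of values at 0, in (0, b1], (b1, b2], ... and above the last bound.

    Returns ``len(bounds) + 2`` counts; NA values are ignored.
    """
    bounds = list(bounds)
    if any(b2 <= b1 for b1, b2 in zip(bounds[:-1], bounds[1:])):
        raise ValueError("bounds must be strictly increasing")
    arr = np.asarray(values, dtype=np.float64).ravel()
    arr = arr[~np.isnan(arr)]
    counts = [int((arr == 0).sum())]
    lo = 0.0
    for b in bounds:
        counts.append(int(((arr > lo) & (arr <= b)).sum()))
        lo = b
    counts.append(int((arr > lo).sum()))
    return counts


def rank_correlation(a, b) -> float:
    """Spearman's rank correlation (midrank ties) between two samples."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    if a.size < 3:
        raise ValueError("rank correlation needs at least 3 pairs")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
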