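"""Slope from the DEM and its impact on walking speed.

Percent slope is computed from the elevation grid as
``S = 100 * |grad H|`` with both axes converted from degrees to metres via
the uniform equatorial factor before differencing (central differences in
the interior, one-sided at the borders).  Slopes above 100% (a 45°
gradient) are treated as impassable and stored as NaN.

Walking speed on a signed slope follows an empirical Gaussian-shaped
hiking function::

    speed(S) = 0.11 + exp(-(S + 5)^2 / (2 * 30^2))   [m/s]

which peaks at a slight downhill (S = -5%).  Because trips to a facility
are round trips, the slope effect is the mean of the uphill and downhill
speeds for the same gradient, expressed as a dimensionless ratio to the
flat-ground speed::

    impact(S) = 0.5 * (speed(+S) + speed(-S)) / speed(0)

so ``impact(0) == 1`` and impact decreases monotonically with gradient.
"""

from __future__ import annotations

import numpy as np

from .core_grid import GeoGrid, METRES_PER_DEGREE

__all__ = ["slope_percent", "speed_on_slope", "slope_impact", "impact_grid",
           "MAX_PASSABLE_SLOPE"]

#: Percent slope above which a cell is impassable (45 degrees).
MAX_PASSABLE_SLOPE = 100.0


def slope_percent(dem: GeoGrid) -> GeoGrid:
    """Percent slope of an elevation grid (metres) on geographic cells.

    NaN elevations poison their difference neighbourhood; slopes above
    :data:`MAX_PASSABLE_SLOPE` become NaN (impassable).
    """
    if dem.n_rows < 2 or dem.n_cols < 2:
        raise ValueError("DEM must be at least 2x2 to compute slope")
    spacing_m = dem.cell_size * METRES_PER_DEGREE
    dy, dx = np.gradient(dem.values, spacing_m)
    with np.errstate(invalid="ignore"):
        s = 100.0 * np.hypot(dx, dy)
        s[s > MAX_PASSABLE_SLOPE] = np.nan
    return dem.copy_with(s)


def speed_on_slope(S):
    """Walking speed in m/s on a signed percent slope (scalar or array)."""
    S = np.asarray(S, dtype=np.float64)
    out = 0.11 + np.exp(-((S + 5.0) ** 2) / (2.0 * 30.0**2))
    return out if out.ndim else float(out)


def slope_impact(S):
    """Round-trip slope impact ratio in (0, 1] for slope magnitude S.

    Scalar or array; the caller must already have masked slopes above
    100% — values outside [0, 100] raise.
    """
    arr = np.asarray(S, dtype=np.float64)
    finite = arr[~np.isnan(arr)]
    if ((finite < 0) | (finite > MAX_PASSABLE_SLOPE)).any():
        raise ValueError("slope magnitude must lie in [0, 100]")
    out = 0.5 * (speed_on_slope(arr) + speed_on_slope(-arr)) / speed_on_slope(0.0)
    return out if arr.ndim else float(out)


def impact_grid(slope: GeoGrid) -> GeoGrid:
    """Elementwise slope impact of a percent-slope grid; NaN propagates."""
    return slope.copy_with(slope_impact(slope.values))
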