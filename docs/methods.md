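# Methods

## Model overview

`walkaccess` estimates pedestrian travel time to the nearest destination
on a fine (default 20 m) geographic grid in four stages.

**1. Walking-speed surface.** Each cell receives a speed in km/h. Roads
are rasterized *all-touched* (a cell is a road cell iff any segment
intersects its closed square — this keeps rasterized polylines
8-connected, which is essential for the network to remain traversable),
grouped by speed with the fastest category winning shared cells. Cells
without roads take the walking speed of their land-cover class. The
default tables assign 5.0 km/h to major roads (motorway/trunk/primary),
4.5 to secondary/tertiary, 4.0 to residential streets, 3.5 to paths,
tracks and unknown categories; and for land cover 3.0 km/h to grassland,
cropland and sparse vegetation, 1.5 to trees, shrubs and built-up areas,
1.15 to bare areas (mostly dry riverbeds), with open water, regularly
flooded ground and missing data as barriers (NA). Road-layer category
names are matched to the table by normalised fuzzy string similarity
(0–100 scale, default threshold 80); unmatched categories fall back to
the "unknown" row (3.5 km/h) with a warning, so every road always gets a
speed.

**2. Terrain weighting.** Percent slope is S = 100·|∇H| from the DEM,
with degree spacing converted to metres by the uniform equatorial factor
111 120 m/° on both axes, central differences in the interior and
one-sided differences at the borders. Walking speed on a signed slope is
the Gaussian-shaped empirical hiking function
`0.11 + exp(−(S+5)²/(2·30²))` m/s, maximal at a gentle 5 % downhill.
Trips to a facility are modelled as return trips, so the dimensionless
slope impact is the mean of uphill and downhill speeds over the flat
speed; it is 1 at S = 0 and decreases monotonically. Slopes above 100 %
(45°) are impassable (NA), even where a road crosses them.

**3. Cost assembly.** Seconds to cross a cell:
`t = cell_size_m / (speed·(1000/3600)·impact·child_factor)`. The child
factor (default 0.78, i.e. a 22 % speed reduction, from observations of
adults walking with or carrying young children) multiplies *every* speed,
water included; 1.0 gives adult surfaces. Because it is a single scalar
on speeds, the resulting travel-time map scales exactly by its inverse —
a property the tests exercise end to end. Two twin surfaces are built:
water-**blocked** (open water NA) and water-**passable** (open water at
the configured water speed, default 1.0 km/h). A road crossing water
keeps its road speed in both (bridge semantics of the road-first
overlay).

**4. Travel time.** Facilities are audited against the blocked surface:
points outside the boundary/grid are removed; points on impassable cells
move to a uniformly random passable 8-neighbour (seeded) or are removed
if none exists; every decision is reported. The solve is multi-source
Dijkstra on the 8-connected grid, edge cost ½(cᵢ+cⱼ)·d with d ∈ {1, √2}
cell units, so k uniform orthogonal steps cost exactly k·c. It uses the
geometric minimum-cost-path routine of scikit-image; an independent
explicit-graph heapq Dijkstra serves as the oracle in the test suite.
Cells unreachable on the blocked surface (islands) take their value from
a second solve on the passable surface; cells unreachable in both are NA.
Output is minutes.

## Parameters

| parameter | unit | default | meaning |
|---|---|---|---|
| `child_factor` | – | 0.78 | multiplicative speed reduction for travel with children; 1.0 = adult |
| `water_speed` | km/h | 1.0 | crossing speed on the water-passable surface |
| `cell_size_m` | m | 20 | cell size used in the crossing-time formula |
| `max_speed` | km/h | 5.0 | validation ceiling for table speeds (fastest pedestrian speed) |
| `fuzzy_threshold` | 0–100 | 80 | minimum similarity for road-name matching |
| `road_priority` | – | on | fastest-speed merge of overlapping roads (off = last written wins) |
| `seed` | – | 0 | drives facility snapping |

## Numerical choices

- Degree↔metre conversion uses the single factor 111 120 on both axes; an
  equator-only approximation, recorded as such. Grids must have square
  cells in degrees; non-square inputs are rejected.
- Bilinear resampling (used to bring a coarser DEM onto the reference
  grid) is conservative with missing data: any interpolation touching an
  NA source cell yields NA, so no elevation is fabricated.
- Unreachable cells are carried internally as +inf and rendered as the
  declared nodata value in outputs; the raster container itself admits
  only finite values or NA.
- Dijkstra ties need no tie-break: only the scalar travel-time field is
  published.
- Facility snapping draws from the passable 8-neighbourhood with
  `numpy.random.default_rng(seed)`, so runs are bit-reproducible.
- The child-weighted speed column is kept at full precision rather than
  display-rounded (e.g. bare areas 1.15 × 0.78 = 0.897, not 0.89).

## Synthetic scenes

The generators produce the structural features the pipeline branches on,
deterministically under a seed: a flat uniform scene (closed-form travel
times), an island cut off by a one-cell water ring (exercises the
two-pass rule), and random scenes with a smoothed random DEM, blocky
land cover, an L-shaped two-category road and scattered facilities. The
`relief` parameter of random scenes is defined as the maximum single-cell
rise in metres as measured by the slope operator — the field is rescaled
so the steepest gradient equals `relief` per cell — which makes the
scene's maximum percent slope exactly `100·relief/20` and lets tests
assert the slope gate analytically (relief 30 m ⇒ 150 % ⇒ impassable
cells present). Scenes emulate input *structure* (class codes, road tags,
grid geometry near the equator), not the statistics of real landscapes:
passing tests demonstrate correctness of the mechanics, not calibration
against real travel-time observations.

Test problem sizes (grids up to ~25×25, 200 random solver comparisons)
were chosen so the full suite and the acceptance script each run in a few
seconds while still covering every branch; the solver's complexity is
O(N log N) in cells, and country-scale rasters differ only in size.

## Known limitations

- Geographic coordinates only; projected grids would need the conversion
  factor generalised (the uniform factor is biased away from the equator).
- Isotropic costs: direction of travel does not change the cost of a
  step beyond the up/down averaging already in the slope impact. At 20 m
  resolution the averaging is an adequate model of return trips.
- Walking only; no motorised modes, no catchment assignment, no
  population weighting.
- Vector roads are read from GeoJSON; facility tables from CSV.
- The boundary check is a bounding box, not an administrative polygon;
  polygon masks can be applied upstream.
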