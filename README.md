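# walkaccess

Fine-resolution pedestrian travel-time maps to health facilities.

Physical access to healthcare in much of sub-Saharan Africa is on foot, and
coarse (1 km) accessibility surfaces smooth away the features that actually
govern walking routes: rivers and lakes, steep slopes, and the road and
path network people follow. `walkaccess` builds **walking-speed cost
allocation ("friction") surfaces** on a 20 m geographic grid from a
categorical land-cover raster, a road polyline layer and a DEM, then solves
a **multi-source least-cost-path problem** giving each cell its travel time
in minutes to the nearest health facility. It is aimed at spatial
epidemiologists and health-access analysts.

## The model

Every cell gets a walking speed: road cells take the fastest touching road
category's speed (5.0 km/h on major roads down to 3.5 km/h on paths),
other cells take their land-cover class speed (1.0–3.0 km/h); open water is
a barrier. Speed is weighted by terrain: with percent slope
*S* = 100·|∇H|, walking speed follows the Gaussian-shaped hiking function

    speed(S) = 0.11 + exp(−(S + 5)² / (2·30²))   [m/s]

and, because trips are return trips, the slope effect is the mean of the
uphill and downhill speeds relative to flat ground,

    impact(S) = ½·(speed(+S) + speed(−S)) / speed(0),

with slopes above 100 % (45°) impassable. The time to cross a cell is

    t = cell_size / (speed · impact · child_factor)   [seconds]

where `child_factor` (default 0.78, a 22 % reduction) models an adult
travelling with a young child; set it to 1.0 for adult maps. Travel time is
the multi-source Dijkstra solution on the 8-connected grid with edge cost
½(cᵢ + cⱼ)·d (d = 1 or √2 cell units). Two twin surfaces handle islands:
water is first a hard barrier; only cells unreachable over land are
re-solved on a surface where water is crossable at 1.0 km/h.

## Worked example

```sh
walkaccess make-fixture --kind island --n 12 --out fx
walkaccess run-all fx/creation.cfg
```

```python
>>> import numpy as np, walkaccess as wa
>>> scene = wa.make_island_scene(12)          # water ring cuts off an island
>>> minutes, surfaces, report = wa.run_scene(scene)
>>> report.count("kept")
1
>>> round(float(np.nanmax(minutes.values)), 2)
9.43
>>> round(float(minutes.values[2, 2]), 2)     # island cell, reached via water
7.25
```

The single mainland facility is kept by the audit; the farthest cell is
9.43 minutes away for a child-weighted walker. Island cells (e.g. 7.25
min) are finite only because the second pass lets the route cross water at
the slow water speed — on the water-blocked surface they are unreachable.
On a uniform grassland scene the numbers have closed forms: a neighbouring
cell costs 20 m ÷ (3 km/h · 0.78) = 30.77 s ≈ 0.51 min.

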