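"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the libraries the implementation uses for the
same step (scikit-image's minimum-cost-path routine, shapely's geometric
predicates) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import heapq
import math
from fractions import Fraction

import numpy as np


def dijkstra_oracle(costs: np.ndarray,
                    sources: list[tuple[int, int]]) -> np.ndarray:
    """Explicit-graph Dijkstra on the 8-connected grid.

    ``costs`` holds seconds-to-cross-cell with NaN impassable; the edge
    cost between adjacent cells is the mean of their crossing times times
    the Euclidean step length in cell units.
    """
    n, m = costs.shape
    dist = np.full((n, m), np.inf)
    heap: list[tuple[float, tuple[int, int]]] = []
    for s in sources:
        dist[s] = 0.0
        heapq.heappush(heap, (0.0, s))
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n and 0 <= cc < m):
                    continue
                if math.isnan(costs[r, c]) or math.isnan(costs[rr, cc]):
                    continue
                nd = d + 0.5 * (costs[r, c] + costs[rr, cc]) * math.hypot(dr, dc)
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, (rr, cc)))
    return dist


def _segment_hits_box(ax, ay, bx, by, xmin, ymin, xmax, ymax) -> bool:
    """Liang-Barsky clipping in exact rational arithmetic: does segment AB
    intersect the closed box?  Exactness matters because lines through cell
    corners are knife-edge cases where float rounding flips the answer."""
    ax, ay, bx, by = map(Fraction, (ax, ay, bx, by))
    xmin, ymin, xmax, ymax = map(Fraction, (xmin, ymin, xmax, ymax))
    dx, dy = bx - ax, by - ay
    t0, t1 = Fraction(0), Fraction(1)
    for p, q in ((-dx, ax - xmin), (dx, xmax - ax),
                 (-dy, ay - ymin), (dy, ymax - ay)):
        if p == 0:
            if q < 0:
                return False
        else:
            t = q / p
            if p < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
            if t0 > t1:
                return False
    return True


def supercover_cells(coords, origin_lon, origin_lat, cell_size,
                     n_rows, n_cols) -> set[tuple[int, int]]:
    """All cells whose closed square a polyline touches (brute force).

    Tests every cell of the grid against every segment with Liang-Barsky
    clipping — O(cells x segments), fine at fixture scale.
    """
    cells: set[tuple[int, int]] = set()
    coords = list(coords)
    for (ax, ay), (bx, by) in zip(coords[:-1], coords[1:]):
        for r in range(n_rows):
            ymax = origin_lat - r * cell_size
            ymin = ymax - cell_size
            for c in range(n_cols):
                xmin = origin_lon + c * cell_size
                xmax = xmin + cell_size
                if _segment_hits_box(ax, ay, bx, by, xmin, ymin, xmax, ymax):
                    cells.add((r, c))
    return cells


def is_8_connected(cells: set[tuple[int, int]]) -> bool:
    """True iff the cell set forms one 8-connected component."""
    if not cells:
        return True
    seen = set()
    stack = [next(iter(cells))]
    while stack:
        r, c = stack.pop()
        if (r, c) in seen:
            continue
        seen.add((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (r + dr, c + dc) in cells and (r + dr, c + dc) not in seen:
                    stack.append((r + dr, c + dc))
    return seen == cells
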