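import numpy as np
import pytest

from walkaccess.cost_surface import CostSurface
from walkaccess.speed_config import RunConfig
from walkaccess.synthetic import make_island_scene
from walkaccess.travel_time import (
    cost_distance,
    extract_at_points,
    rank_correlation,
    summary_stats,
    threshold_counts,
    to_minutes,
    two_pass_travel_time,
)

from conftest import make_grid, random_cost_array
from _oracles import dijkstra_oracle


def surface_from(costs, mode="blocked"):
    return CostSurface(grid=make_grid(costs), water_mode=mode,
                       child_factor=0.78, water_speed=1.0, cell_size_m=20.0)


class TestCostDistance:
    def test_uniform_3x3_closed_form(self):
        surf = surface_from(np.full((3, 3), 14.4))
        t = cost_distance(surf, [(1, 1)])
        assert t[1, 1] == 0.0
        for cell in [(0, 1), (1, 0), (1, 2), (2, 1)]:
            assert t[cell] == pytest.approx(14.4, abs=1e-9)
        for cell in [(0, 0), (0, 2), (2, 0), (2, 2)]:
            assert t[cell] == pytest.approx(14.4 * np.sqrt(2), abs=1e-9)

    def test_straight_run_costs_k_times_c(self):
        surf = surface_from(np.full((1, 6), 30.0))
        t = cost_distance(surf, [(0, 0)])
        assert np.allclose(t[0], 30.0 * np.arange(6))

    def test_sources_are_zero(self):
        surf = surface_from(np.full((4, 4), 20.0))
        srcs = [(0, 0), (3, 3), (1, 2)]
        t = cost_distance(surf, srcs)
        for s in srcs:
            assert t[s] == 0.0
        assert np.all(t[t > 0] > 0)

    def test_na_ring_isolates_region(self):
        costs = np.full((7, 7), 10.0)
        costs[1, 1:6] = np.nan
        costs[5, 1:6] = np.nan
        costs[1:6, 1] = np.nan
        costs[1:6, 5] = np.nan
        surf = surface_from(costs)
        t = cost_distance(surf, [(0, 0)])
        assert np.isinf(t[3, 3])
        assert np.isfinite(t[6, 6])

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            cost_distance(surface_from(np.ones((3, 3))), [])

    def test_impassable_source_rejected(self):
        costs = np.ones((3, 3))
        costs[1, 1] = np.nan
        with pytest.raises(ValueError, match="impassable"):
            cost_distance(surface_from(costs), [(1, 1)])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_explicit_graph_dijkstra(self, seed):
        """Solver equals an independent explicit-graph Dijkstra on random
        surfaces with NA patches."""
        rng = np.random.default_rng(seed)
        shape = rng.integers(5, 26, size=2)
        costs = random_cost_array(rng, *shape)
        passable = np.argwhere(~np.isnan(costs))
        k = int(rng.integers(1, 4))
        sources = [tuple(passable[i]) for i in
                   rng.choice(len(passable), size=k, replace=False)]
        t = cost_distance(surface_from(costs), sources)
        expected = dijkstra_oracle(costs, sources)
        finite = np.isfinite(expected)
        assert np.array_equal(np.isfinite(t), finite)
        assert np.max(np.abs(t[finite] - expected[finite])) < 1e-9

    def test_adding_a_source_never_increases_times(self):
        rng = np.random.default_rng(0)
        costs = random_cost_array(rng, 15, 15, na_fraction=0.1)
        passable = [tuple(c) for c in np.argwhere(~np.isnan(costs))]
        surf = surface_from(costs)
        t1 = cost_distance(surf, passable[:1])
        t2 = cost_distance(surf, passable[:1] + [passable[50]])
        assert np.all(t2 <= t1 + 1e-12)

    def test_triangle_consistency(self):
        rng = np.random.default_rng(1)
        costs = random_cost_array(rng, 10, 10, na_fraction=0.15)
        passable = [tuple(c) for c in np.argwhere(~np.isnan(costs))]
        t = cost_distance(surface_from(costs), passable[:2])
        n, m = costs.shape
        for r in range(n):
            for c in range(m):
                if not np.isfinite(t[r, c]):
                    continue
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (dr, dc) == (0, 0) or not (0 <= rr < n and 0 <= cc < m):
                            continue
                        if not np.isfinite(t[rr, cc]):
                            continue
                        step = 0.5 * (costs[r, c] + costs[rr, cc]) * np.hypot(dr, dc)
                        assert t[r, c] <= t[rr, cc] + step + 1e-9


class TestTwoPass:
    def island_surfaces(self, n=12):
        scene = make_island_scene(n)
        from walkaccess.pipeline import build_cost_surfaces
        cfg = RunConfig()
        return build_cost_surfaces(scene.landcover, scene.dem, scene.roads,
                                   cfg), scene

    def test_no_water_identical_to_pass_one(self):
        costs = np.full((5, 5), 25.0)
        surf = surface_from(costs)
        surf_p = surface_from(costs, "passable")
        t = two_pass_travel_time(surf, surf_p, [(2, 2)])
        assert np.array_equal(t, cost_distance(surf, [(2, 2)]))

    def test_island_finite_only_via_water(self):
        surfaces, scene = self.island_surfaces()
        n = scene.landcover.n_rows
        sources = [(n - 2, n - 2)]
        t1 = cost_distance(surfaces["blocked"], sources)
        merged = two_pass_travel_time(surfaces["blocked"],
                                      surfaces["passable"], sources)
        island = np.s_[1:4, 1:4]
        assert np.isinf(t1[island]).all()
        assert np.isfinite(merged[island]).all()
        # mainland values bit-identical between pass 1 and merged
        mainland = np.isfinite(t1)
        assert np.array_equal(merged[mainland], t1[mainland])

    def test_pass1_dominates_pass2(self):
        surfaces, scene = self.island_surfaces()
        n = scene.landcover.n_rows
        sources = [(n - 2, n - 2)]
        t1 = cost_distance(surfaces["blocked"], sources)
        t2 = cost_distance(surfaces["passable"], sources)
        fin = np.isfinite(t1)
        assert np.all(t1[fin] >= t2[fin] - 1e-9)

    def test_geometry_mismatch_rejected(self):
        a = surface_from(np.ones((3, 3)))
        b = surface_from(np.ones((4, 4)), "passable")
        with pytest.raises(ValueError, match="geometry"):
            two_pass_travel_time(a, b, [(0, 0)])


class TestUnitsAndExtraction:
    def test_to_minutes(self):
        like = make_grid(np.zeros((1, 3)))
        out = to_minutes(np.array([[14.4, 0.0, np.inf]]), like)
        assert out.values[0, 0] == pytest.approx(0.24)
        assert out.values[0, 1] == 0.0
        assert np.isnan(out.values[0, 2])

    def test_extract_at_points(self):
        g = make_grid(np.arange(9, dtype=float).reshape(3, 3))
        pts = [g.cell_center(0, 0), g.cell_center(2, 1), (99.0, 99.0)]
        with pytest.warns(UserWarning, match="outside"):
            vals = extract_at_points(g, pts)
        assert vals[0] == 0.0
        assert vals[1] == 7.0
        assert np.isnan(vals[2])


class TestValidationStats:
    def test_summary_stats_basics(self):
        s = summary_stats([1, 2, 3, 4])
        assert s["min"] == 1 and s["max"] == 4 and s["mean"] == 2.5

    def test_single_value_and_constant(self):
        s = summary_stats([7.0])
        assert all(v == 7.0 for v in s.values())
        c = summary_stats([3.0, 3.0, 3.0])
        assert c["q3"] - c["q1"] == 0.0

    def test_all_na_rejected(self):
        with pytest.raises(ValueError):
            summary_stats([np.nan, np.nan])

    def test_threshold_counts(self):
        counts = threshold_counts([0, 10, 20, 40], [15, 30])
        assert counts == [1, 1, 1, 1]   # zero, (0,15], (15,30], >30

    def test_threshold_counts_edge_cases(self):
        assert threshold_counts([], [15, 30]) == [0, 0, 0, 0]
        assert threshold_counts([100, 200], [15, 30]) == [0, 0, 0, 2]
        with pytest.raises(ValueError):
            threshold_counts([1], [30, 15])

    def test_rank_correlation(self):
        a = [1.0, 2.5, 3.0, 4.1, 5.0]
        assert rank_correlation(a, [2 * x for x in a]) == pytest.approx(1.0)
        assert rank_correlation(a, [-x for x in a]) == pytest.approx(-1.0)
        # hand-computed: d = (1,1,1,1,0) squared sums to 4 -> 1 - 24/120
        assert rank_correlation([1, 2, 3, 4, 5],
                                [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_rank_correlation_input_validation(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            rank_correlation([1, 2], [2, 1])
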