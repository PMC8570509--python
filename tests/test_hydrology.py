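import numpy as np
import pytest
from shapely.geometry import Point

from geohab.hydrology import (
    D8_OFFSETS, OUTLET, d8_flow_direction, delineate_watersheds,
    downstream_index, extract_streams, fill_sinks, first_order_divides,
    flow_accumulation,
)
from geohab.raster_io import Grid, VectorLayer
from geohab.synthetic_landscape import Feature, LandscapeSpec, make_dem

from conftest import random_grid


def brute_accumulation(fdir: Grid) -> np.ndarray:
    """Path-tracing oracle: for every cell walk its full flow path and
    increment every downstream cell. Independent of topological sorting."""
    down = downstream_index(fdir)
    nrows, ncols = fdir.shape
    acc = np.zeros((nrows, ncols))
    for r in range(nrows):
        for c in range(ncols):
            if not fdir.mask()[r, c]:
                continue
            j = down[r, c]
            steps = 0
            while j >= 0:
                acc[j // ncols, j % ncols] += 1
                j = down[j // ncols, j % ncols]
                steps += 1
                assert steps <= nrows * ncols, "cycle"
    return acc


def filled_random_dem(rng, n=15):
    g = random_grid(rng, n, n)
    return fill_sinks(g)


class TestFillSinks:
    def test_pit_raised_to_rim_spill_level(self):
        # hand-trace on 5x5: low outer apron at 5, rim ring at 10, pit at 8;
        # water escaping the pit must cross the rim, so the spill level is 10
        vals = np.full((5, 5), 5.0)
        vals[1:4, 1:4] = 10.0   # bowl rim
        vals[2, 2] = 8.0        # pit 2 below the rim
        out = fill_sinks(Grid(vals))
        assert out.values[2, 2] == pytest.approx(10.0)
        # nothing else moves
        changed = out.values != vals
        assert changed.sum() == 1

    def test_monotone_ramp_unchanged(self, south_ramp):
        out = fill_sinks(south_ramp)
        np.testing.assert_array_equal(out.values, south_ramp.values)

    def test_idempotent_and_monotone(self, rng):
        g = random_grid(rng, 15, 15)
        once = fill_sinks(g)
        twice = fill_sinks(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert (once.values >= g.values - 1e-12).all()

    def test_minimality_fills_only_depressions(self):
        spec = LandscapeSpec(nrows=15, ncols=15, base_slope=0.3,
                             features=[Feature("basin", (7, 7), 20.0, 90.0)])
        dem = make_dem(spec)
        out = fill_sinks(dem)
        raised = out.values > dem.values + 1e-12
        assert raised.any()
        # raised cells are confined to the basin's neighborhood
        rr, cc = np.nonzero(raised)
        assert ((np.abs(rr - 7) <= 6) & (np.abs(cc - 7) <= 6)).all()


class TestFlowDirection:
    def test_south_plane_points_south(self, south_ramp):
        fdir = d8_flow_direction(south_ramp)
        south = D8_OFFSETS.index((1, 0))
        inner = fdir.values[1:-1, 1:-1]
        assert (inner == south).all()
        assert (fdir.values[-1] == OUTLET).all()

    def test_cone_directions_radiate_outward(self):
        n = 11
        r, c = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        cone = Grid(100.0 - np.hypot(r - 5, c - 5))
        fdir = d8_flow_direction(cone)
        # along each axis/diagonal from the apex, flow follows that ray
        assert fdir.values[5, 7] == D8_OFFSETS.index((0, 1))    # E of apex
        assert fdir.values[5, 3] == D8_OFFSETS.index((0, -1))   # W
        assert fdir.values[7, 5] == D8_OFFSETS.index((1, 0))    # S
        assert fdir.values[3, 3] == D8_OFFSETS.index((-1, -1))  # NW

    def test_tie_break_uses_fixed_scan_order(self):
        # center with equal drop/distance slope to E and S: E wins (first
        # in the E,SE,S,SW,W,NW,N,NE scan)
        vals = np.array([[9.0, 9.0, 9.0],
                         [9.0, 5.0, 4.0],
                         [9.0, 4.0, 9.0]])
        fdir = d8_flow_direction(Grid(vals))
        assert fdir.values[1, 1] == D8_OFFSETS.index((0, 1))

    def test_unfilled_sink_raises(self):
        vals = np.full((5, 5), 10.0)
        vals[2, 2] = 1.0
        with pytest.raises(ValueError, match="sink at cell"):
            d8_flow_direction(Grid(vals))

    def test_flats_drain_to_spill(self):
        # interior flat walled in on all sides, one gap in the wall: the
        # whole flat must route through the gap cell
        vals = np.full((7, 7), 20.0)
        vals[1:6, 1:6] = 10.0   # flat interior
        vals[0, 3] = 5.0        # gap (spill) in the north wall
        fdir = d8_flow_direction(Grid(vals))
        acc = flow_accumulation(fdir)
        assert acc.values[0, 3] >= 25.0  # all 25 flat cells pass the gap


class TestFlowAccumulation:
    def test_south_plane_column_chains(self):
        rows = np.arange(4)[:, None] * np.ones((1, 4))
        fdir = d8_flow_direction(Grid(10.0 - rows))
        acc = flow_accumulation(fdir)
        for r in range(4):
            np.testing.assert_array_equal(acc.values[r], r)

    def test_inward_bowl_center_collects_eight(self):
        # direction field constructed by hand: all 8 ring cells point at
        # the center, which is the outlet — enumerating 8 contributors
        from geohab.hydrology import D8_OFFSETS, OUTLET

        codes = np.empty((3, 3))
        for r in range(3):
            for c in range(3):
                if (r, c) == (1, 1):
                    codes[r, c] = OUTLET
                else:
                    codes[r, c] = D8_OFFSETS.index((1 - r, 1 - c))
        acc = flow_accumulation(Grid(codes))
        assert acc.values[1, 1] == 8.0

    def test_outlet_conservation(self, rng):
        filled = filled_random_dem(rng)
        fdir = d8_flow_direction(filled)
        acc = flow_accumulation(fdir)
        outlets = fdir.values == OUTLET
        assert (acc.values[outlets] + 1).sum() == filled.values.size

    def test_per_cell_conservation(self, rng):
        filled = filled_random_dem(rng)
        fdir = d8_flow_direction(filled)
        acc = flow_accumulation(fdir).values
        down = downstream_index(fdir)
        nrows, ncols = fdir.shape
        upstream_sum = np.zeros_like(acc)
        for r in range(nrows):
            for c in range(ncols):
                j = down[r, c]
                if j >= 0:
                    upstream_sum[j // ncols, j % ncols] += acc[r, c] + 1
        np.testing.assert_array_equal(acc, upstream_sum)

    def test_matches_path_tracing_oracle(self, rng):
        for _ in range(10):
            fdir = d8_flow_direction(filled_random_dem(rng))
            acc = flow_accumulation(fdir)
            np.testing.assert_array_equal(acc.values,
                                          brute_accumulation(fdir))


class TestStreams:
    def test_threshold_above_max_gives_empty_network(self, rng):
        fdir = d8_flow_direction(filled_random_dem(rng, 10))
        facc = flow_accumulation(fdir)
        net = extract_streams(facc, fdir, threshold=1e9)
        assert net.is_empty()
        assert net.links == []

    def test_strahler_merge_increments_order(self):
        # two parallel valleys joining at the south edge
        vals = np.array([
            [9.0, 1.0, 9.0, 1.2, 9.0],
            [9.0, 0.8, 9.0, 1.0, 9.0],
            [9.0, 0.6, 9.0, 0.8, 9.0],
            [9.0, 0.4, 0.45, 0.5, 9.0],
            [9.0, 0.2, 9.0, 9.0, 9.0],
        ])
        fdir = d8_flow_direction(fill_sinks(Grid(vals)))
        facc = flow_accumulation(fdir)
        net = extract_streams(facc, fdir, threshold=2)
        orders = net.order
        assert max(orders.values()) == 2
        outlet_cell = 4 * 5 + 1
        assert orders[outlet_cell] == 2

    def test_stream_cells_are_high_accumulation(self, rng):
        fdir = d8_flow_direction(filled_random_dem(rng))
        facc = flow_accumulation(fdir)
        net = extract_streams(facc, fdir, threshold=5)
        assert (facc.values[net.stream_mask] >= 5).all()
        assert (facc.values[~net.stream_mask & facc.mask()] < 5).all()


class TestWatersheds:
    def test_funnel_drains_to_single_outlet(self):
        # cone whose apex sits on the south edge: every flow path converges
        # there, so a single pour point captures the whole grid
        r, c = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        funnel = Grid(np.hypot(r - 8.0, c - 4.0) + 1.0)
        fdir = d8_flow_direction(funnel)
        pp = VectorLayer([Point(0, 0)], [{"row": 8, "col": 4}])
        basins = delineate_watersheds(fdir, pp)
        assert (basins.values == 1).all()

    def test_twin_valleys_partition_on_ridge(self):
        cols = np.arange(11)
        # ridge along column 5; valleys at columns 0 and 10
        vals = np.abs(cols - 5)[None, :] * 2.0 + \
            np.arange(11)[:, None] * 0.1
        fdir = d8_flow_direction(Grid(vals))
        pp = VectorLayer([Point(0, 0), Point(0, 0)],
                         [{"row": 10, "col": 0}, {"row": 10, "col": 10}])
        basins = delineate_watersheds(fdir, pp)
        assert (basins.values[:, :5][basins.mask()[:, :5]] == 1).all()
        assert (basins.values[:, 6:][basins.mask()[:, 6:]] == 2).all()

    def test_basins_partition_drained_cells(self, rng):
        filled = filled_random_dem(rng)
        fdir = d8_flow_direction(filled)
        acc = flow_accumulation(fdir)
        top = np.unravel_index(np.argmax(acc.values), acc.shape)
        pp = VectorLayer([Point(0, 0)],
                         [{"row": int(top[0]), "col": int(top[1])}])
        basins = delineate_watersheds(fdir, pp)
        labeled = basins.mask().sum()
        assert labeled == acc.values[top] + 1

    def test_off_grid_pour_point_rejected(self, south_ramp):
        fdir = d8_flow_direction(south_ramp)
        pp = VectorLayer([Point(0, 0)], [{"row": 99, "col": 0}])
        with pytest.raises(ValueError, match="off-grid"):
            delineate_watersheds(fdir, pp)


class TestFirstOrderDivides:
    def test_single_straight_stream_has_no_divide(self):
        # one valley, one channel, one basin: nothing borders anything
        r, c = np.meshgrid(np.arange(7), np.arange(5), indexing="ij")
        vals = 2.0 * np.abs(c - 2) + (6.0 - r)
        fdir = d8_flow_direction(fill_sinks(Grid(vals)))
        facc = flow_accumulation(fdir)
        net = extract_streams(facc, fdir, threshold=10)
        assert not net.is_empty()
        assert max(net.order.values()) == 1
        divides = first_order_divides(net, fdir)
        assert len(divides) == 0

    def test_twin_valleys_divide_on_ridge_crest(self):
        spec = LandscapeSpec(
            nrows=20, ncols=21, cellsize=30.0, base_slope=0.5,
            features=[Feature("valley", (0, 4), 30.0, 90.0, end=(19, 4)),
                      Feature("valley", (0, 16), 30.0, 90.0, end=(19, 16))])
        dem = make_dem(spec)
        fdir = d8_flow_direction(fill_sinks(dem))
        facc = flow_accumulation(fdir)
        net = extract_streams(facc, fdir, threshold=8)
        divides = first_order_divides(net, fdir)
        assert len(divides) > 0
        cols = [a["col"] for _, a in divides]
        # divide cells concentrate near the separating crest (column 10)
        assert np.median(cols) == pytest.approx(10, abs=2)

    def test_empty_network_gives_empty_layer(self, rng):
        fdir = d8_flow_direction(filled_random_dem(rng, 8))
        facc = flow_accumulation(fdir)
        net = extract_streams(facc, fdir, threshold=1e9)
        assert len(first_order_divides(net, fdir)) == 0
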