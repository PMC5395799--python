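"""Friction surfaces, both accumulation engines, and zone classification."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import accesskit as ak
from accesskit.raster import RasterGrid
from accesskit.schema import IMPASSABLE_SECONDS
from accesskit.travelcost import MOVES, DestinationSet, ScenarioSpec


def uniform_cost(n=21, seconds=90.0, cell_size=50.0):
    return RasterGrid(np.full((n, n), seconds), cell_size=cell_size)


def smooth_cost(seed, n=100, lo=60.0, hi=260.0):
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal((n, n)), sigma=8, mode="nearest")
    f = (f - f.min()) / max(np.ptp(f), 1e-12)
    return RasterGrid(lo + (hi - lo) * f, cell_size=50.0)


def center_dest(grid):
    r = grid.n_rows // 2
    c = grid.n_cols // 2
    return DestinationSet(points=[grid.cell_center(r, c)], cells=[(r, c)])


class TestCostGrid:
    # per-cell seconds at 50 m for the reference speed table
    @pytest.mark.parametrize(
        "class_id, expected",
        [
            (1, 180.0),    # Forest, 1 km/h
            (2, 90.0),     # Grass, 2 km/h
            (3, 60.0),     # Bare, 3 km/h
            (4, 240.0),    # Scrub, 0.75 km/h
            (101, 90.0),   # fordable streams walk like grass
            (104, 90.0),
            (105, IMPASSABLE_SECONDS),  # top stream class never passable
            (201, 3.6),    # national road, 50 km/h
            (202, 7.2),    # provincial road, 25 km/h
            (203, 18.0),   # local road, 10 km/h
        ],
    )
    def test_reference_seconds_per_cell(self, class_id, expected, speed_table):
        lc = RasterGrid(np.full((2, 2), float(class_id)), cell_size=50)
        cost = ak.build_cost_grid(lc, speed_table)
        assert cost.values[0, 0] == pytest.approx(expected)

    def test_stretcher_mode_divides_walking_speed_by_five(self, speed_table):
        lc = RasterGrid(np.full((2, 2), 1.0), cell_size=50)
        cost = ak.build_cost_grid(lc, speed_table, ScenarioSpec(walking_mode="stretcher"))
        assert cost.values[0, 0] == pytest.approx(900.0)

    def test_assisted_mode_halves_walking_speed(self, speed_table):
        lc = RasterGrid(np.full((2, 2), 2.0), cell_size=50)
        cost = ak.build_cost_grid(lc, speed_table, ScenarioSpec(walking_mode="assisted"))
        assert cost.values[0, 0] == pytest.approx(180.0)

    def test_walking_modes_leave_roads_vehicular(self, speed_table):
        lc = RasterGrid(np.full((2, 2), 203.0), cell_size=50)
        cost = ak.build_cost_grid(lc, speed_table, ScenarioSpec(walking_mode="stretcher"))
        assert cost.values[0, 0] == pytest.approx(18.0)

    def test_night_slows_every_passable_cell_by_a_quarter(self, landcover_grid, speed_table):
        day = ak.build_cost_grid(landcover_grid, speed_table)
        night = ak.build_cost_grid(landcover_grid, speed_table, ScenarioSpec(time_of_day="night"))
        passable = day.values < IMPASSABLE_SECONDS
        assert np.allclose(night.values[passable], 1.25 * day.values[passable])
        assert np.all(night.values[~passable] == IMPASSABLE_SECONDS)

    @pytest.mark.parametrize(
        "weather, closed, open_",
        [("rainy", [103, 104, 105], [101, 102]), ("flooding", [101, 102, 103, 104, 105], [])],
    )
    def test_weather_closes_watercourses(self, weather, closed, open_, speed_table):
        for cid in closed:
            lc = RasterGrid(np.full((2, 2), float(cid)), cell_size=50)
            cost = ak.build_cost_grid(lc, speed_table, ScenarioSpec(weather=weather))
            assert cost.values[0, 0] == IMPASSABLE_SECONDS
        for cid in open_:
            lc = RasterGrid(np.full((2, 2), float(cid)), cell_size=50)
            cost = ak.build_cost_grid(lc, speed_table, ScenarioSpec(weather=weather))
            assert cost.values[0, 0] < IMPASSABLE_SECONDS

    def test_road_speed_override(self, speed_table):
        lc = RasterGrid(np.full((2, 2), 201.0), cell_size=50)
        cost = ak.build_cost_grid(
            lc, speed_table, ScenarioSpec(road_speed_overrides={201: 25.0})
        )
        assert cost.values[0, 0] == pytest.approx(7.2)

    def test_barriers_win_over_everything(self, speed_table):
        lc = RasterGrid(np.full((2, 2), 201.0), cell_size=50)
        spec = ScenarioSpec(time_of_day="night", barriers=[([(0, 0)], 30)])
        cost = ak.build_cost_grid(lc, speed_table, spec)
        assert cost.values[0, 0] == 30 * 60.0

    def test_drawn_road_changes_class_before_lookup(self, speed_table):
        lc = RasterGrid(np.full((3, 3), 1.0), cell_size=50)
        spec = ScenarioSpec(drawn_roads=[([(1, 1)], 203)])
        cost = ak.build_cost_grid(lc, speed_table, spec)
        assert cost.values[1, 1] == pytest.approx(18.0)
        assert cost.values[0, 0] == pytest.approx(180.0)

    def test_barrier_minutes_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(barriers=[([(0, 0)], 700)])

    @pytest.mark.parametrize("field, value", [
        ("walking_mode", "crawling"), ("time_of_day", "dusk"), ("weather", "snow"),
    ])
    def test_enumerated_fields_validated(self, field, value):
        with pytest.raises(ValueError):
            ScenarioSpec(**{field: value})


class TestChamfer:
    def test_destination_is_zero_and_axial_neighbour_one_cell(self):
        cost = uniform_cost()
        tt = ak.chamfer_travel_time(cost, center_dest(cost))
        r = c = 10
        assert tt.values[r, c] == 0.0
        assert tt.values[r, c + 1] == pytest.approx(90.0)
        assert tt.values[r + 1, c + 1] == pytest.approx(90.0 * math.sqrt(2))

    def test_matches_dijkstra_within_five_percent_on_random_fields(self):
        # rough, uncorrelated cost fields need the convergence option (the
        # four-scan default is tuned to spatially smooth surfaces)
        rng = np.random.default_rng(0)
        for _ in range(5):
            cost = RasterGrid(rng.uniform(30, 300, size=(20, 20)), cell_size=50)
            dest = center_dest(cost)
            cham = ak.chamfer_travel_time(cost, dest, converge=True).values
            dij = ak.dijkstra_travel_time(cost, dest).values
            m = dij > 0
            assert np.max(np.abs(cham[m] - dij[m]) / dij[m]) <= 0.05

    def test_impassable_ring_leaves_interior_unreachable(self):
        cost = uniform_cost(15)
        # two-cell-thick ring so knight moves cannot hop it
        vals = cost.values.copy()
        for ring in (3, 4):
            vals[ring, ring:-ring] = IMPASSABLE_SECONDS
            vals[-ring - 1, ring:-ring] = IMPASSABLE_SECONDS
            vals[ring:-ring, ring] = IMPASSABLE_SECONDS
            vals[ring:-ring, -ring - 1] = IMPASSABLE_SECONDS
        ringed = cost.copy_with(vals)
        # destination outside the ring, probe inside
        dest = DestinationSet(points=[(25.0, 725.0)], cells=[(0, 0)])
        for engine in (ak.chamfer_travel_time, ak.dijkstra_travel_time):
            tt = engine(ringed, dest)
            assert tt.values[7, 7] == IMPASSABLE_SECONDS

    def test_uniform_grid_error_within_the_mask_metric_bound(self):
        # the exact 5x5 mask weights (1, sqrt2, sqrt5) have worst-case
        # overestimate sqrt(1+(sqrt5-2)^2)-1 = 2.748% vs Euclidean
        cost = uniform_cost(41)
        tt = ak.chamfer_travel_time(cost, center_dest(cost)).values
        rr, cc = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
        euclid = np.hypot(rr - 20, cc - 20) * 90.0
        m = euclid > 0
        rel = (tt[m] - euclid[m]) / euclid[m]
        assert rel.max() <= math.sqrt(1 + (math.sqrt(5) - 2) ** 2) - 1 + 1e-9
        assert rel.min() >= -1e-9  # a graph distance never undercuts Euclidean

    def test_convergence_option_stops_when_stable(self):
        cost = smooth_cost(3, n=40)
        dest = center_dest(cost)
        four = ak.chamfer_travel_time(cost, dest)
        conv = ak.chamfer_travel_time(cost, dest, converge=True)
        assert np.all(conv.values <= four.values + 1e-9)

    def test_empty_or_blocked_destinations_rejected(self):
        cost = uniform_cost(5)
        with pytest.raises(ValueError):
            ak.chamfer_travel_time(cost, DestinationSet(points=[], cells=[]))
        blocked = cost.copy_with(np.full((5, 5), IMPASSABLE_SECONDS))
        with pytest.raises(ValueError, match="impassable"):
            ak.chamfer_travel_time(blocked, center_dest(cost))


class TestDijkstra:
    def test_uniform_axial_closed_form(self):
        cost = uniform_cost()
        tt = ak.dijkstra_travel_time(cost, center_dest(cost))
        for k in range(1, 10):
            assert tt.values[10, 10 + k] == pytest.approx(k * 90.0)

    def test_adding_a_destination_never_increases_any_value(self):
        cost = smooth_cost(1, n=30)
        one = ak.dijkstra_travel_time(
            cost, DestinationSet(points=[(0, 0)], cells=[(5, 5)])
        )
        two = ak.dijkstra_travel_time(
            cost, DestinationSet(points=[(0, 0), (1, 1)], cells=[(5, 5), (25, 20)])
        )
        assert np.all(two.values <= one.values + 1e-9)

    def test_matches_bellman_ford_on_small_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            cost = RasterGrid(rng.uniform(10, 200, size=(8, 8)), cell_size=50)
            dest = DestinationSet(points=[(0, 0)], cells=[(3, 4)])
            dij = ak.dijkstra_travel_time(cost, dest).values
            # naive repeated-relaxation oracle over the same move graph
            dist = np.full((8, 8), np.inf)
            dist[3, 4] = 0.0
            for _ in range(64):
                for r in range(8):
                    for c in range(8):
                        for dr, dc, d in MOVES:
                            nr, nc = r + dr, c + dc
                            if 0 <= nr < 8 and 0 <= nc < 8:
                                w = d * 0.5 * (cost.values[r, c] + cost.values[nr, nc])
                                if dist[nr, nc] + w < dist[r, c]:
                                    dist[r, c] = dist[nr, nc] + w
            assert np.allclose(dij, dist)


class TestEngineProperties:
    def test_raising_a_cost_never_decreases_travel_time(self):
        cost = smooth_cost(5, n=30)
        dest = center_dest(cost)
        raised_vals = cost.values.copy()
        raised_vals[10:14, 10:14] *= 3.0
        raised = cost.copy_with(raised_vals)
        for engine in (ak.chamfer_travel_time, ak.dijkstra_travel_time):
            base = engine(cost, dest).values
            high = engine(raised, dest).values
            assert np.all(high >= base - 1e-9)

    def test_scaling_costs_scales_times_exactly(self):
        cost = smooth_cost(9, n=30)
        dest = center_dest(cost)
        f = 1.25
        scaled = cost.copy_with(cost.values * f)
        dij = ak.dijkstra_travel_time(cost, dest).values
        dij_s = ak.dijkstra_travel_time(scaled, dest).values
        assert np.allclose(dij_s, f * dij)
        cham = ak.chamfer_travel_time(cost, dest).values
        cham_s = ak.chamfer_travel_time(scaled, dest).values
        assert np.allclose(cham_s, f * cham, rtol=1e-9)

    def test_every_finite_cell_has_a_strictly_smaller_neighbour(self, travel_time):
        t = travel_time.values
        finite = (t > 0) & (t < IMPASSABLE_SECONDS)
        rows, cols = np.nonzero(finite)
        for r, c in zip(rows, cols):
            best = min(
                t[r + dr, c + dc]
                for dr, dc, _ in MOVES
                if 0 <= r + dr < t.shape[0] and 0 <= c + dc < t.shape[1]
            )
            assert best < t[r, c]


class TestZones:
    @pytest.mark.parametrize(
        "minutes, zone", [(0, 1), (14.9, 1), (15.0, 2), (100, 5), (121, 6), (5000, 6)]
    )
    def test_probe_minutes(self, minutes, zone, zone_table):
        tt = RasterGrid(np.array([[minutes * 60.0]]), cell_size=50)
        assert ak.classify_zones(tt, zone_table).values[0, 0] == zone

    def test_unreachable_cells_take_the_top_class(self, zone_table):
        tt = RasterGrid(np.array([[IMPASSABLE_SECONDS]]), cell_size=50)
        assert ak.classify_zones(tt, zone_table).values[0, 0] == 6

    def test_top_class_bound(self, zone_table):
        assert zone_table.maxima[-1] == 999_999


class TestDestinations:
    def test_snapping_to_cell_centres(self):
        grid = RasterGrid(np.zeros((4, 4)), cell_size=50)
        d = DestinationSet.from_points([(60, 60)], grid)
        assert d.cells == [(2, 1)]

    def test_coincident_points_collapse(self):
        grid = RasterGrid(np.zeros((4, 4)), cell_size=50)
        d = DestinationSet.from_points([(60, 60), (70, 70)], grid)
        assert d.cells == [(2, 1)]

    def test_point_outside_extent_rejected(self):
        grid = RasterGrid(np.zeros((4, 4)), cell_size=50)
        with pytest.raises(ValueError):
            DestinationSet.from_points([(999, 0)], grid)
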