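"""Shared fixtures: one small synthetic study area run through the full
land-cover chain, reused across modules (session scope keeps the suite fast)."""

from __future__ import annotations

import numpy as np
import pytest

import accesskit as ak
from accesskit.landcover import compose_landcover, rasterize_roads

FIXTURE_SEED = 1
FIXTURE_SIZE = 80


@pytest.fixture(scope="session")
def landscape():
    return ak.generate_landscape(FIXTURE_SEED, FIXTURE_SIZE, FIXTURE_SIZE)


@pytest.fixture(scope="session")
def stream_classes(landscape):
    filled = ak.fill_sinks(landscape.dem)
    flow = ak.d8_flow(filled)
    acc = ak.flow_accumulation(flow)
    streams = ak.strahler(flow, acc, max(1, int(0.005 * landscape.dem.values.size)))
    return ak.streams_to_classes(streams)


@pytest.fixture(scope="session")
def landcover_grid(landscape, stream_classes):
    roads = rasterize_roads(landscape.roads, landscape.dem)
    return compose_landcover(landscape.vegetation, stream_classes, roads)


@pytest.fixture(scope="session")
def speed_table():
    return ak.default_speed_table()


@pytest.fixture(scope="session")
def zone_table():
    return ak.default_zone_table()


@pytest.fixture(scope="session")
def cost_grid(landcover_grid, speed_table):
    return ak.build_cost_grid(landcover_grid, speed_table)


@pytest.fixture(scope="session")
def destinations(landscape, landcover_grid):
    return ak.DestinationSet.from_vector(landscape.destinations, landcover_grid)


@pytest.fixture(scope="session")
def travel_time(cost_grid, destinations):
    return ak.dijkstra_travel_time(cost_grid, destinations)


def random_grid(rng: np.random.Generator, n_rows=5, n_cols=7) -> ak.RasterGrid:
    """A random raster with occasional nodata, for round-trip checks."""
    vals = np.round(rng.uniform(-100, 100, size=(n_rows, n_cols)), 3)
    vals[rng.random(vals.shape) < 0.1] = -9999
    return ak.RasterGrid(
        vals,
        cell_size=float(rng.choice([25, 50, 100])),
        origin_x=float(rng.integers(-1000, 1000)),
        origin_y=float(rng.integers(-1000, 1000)),
    )
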