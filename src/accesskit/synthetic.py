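"""Seeded synthetic landscapes for self-contained runs and tests.

Real deployments of the toolkit start from an elevation model, a classified
vegetation raster and road vectors. This module fabricates structurally
equivalent inputs — a smooth, mostly edge-draining DEM, patchy four-class
vegetation, a three-tier road network and facility points — so that the full
pipeline runs with no download and is exactly reproducible per seed.

The default extent is 600 x 600 cells at 50 m (a 30 x 30 km window, the
demonstration scale the toolkit targets); tests use far smaller grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .io_formats import Feature, VectorLayer
from .raster import RasterGrid

__all__ = [
    "LandscapeFixture",
    "generate_dem",
    "generate_vegetation",
    "generate_roads",
    "generate_destinations",
    "generate_landscape",
]

DEFAULT_ROWS = 600
DEFAULT_COLS = 600
DEFAULT_CELL_SIZE = 50.0


@dataclass
class LandscapeFixture:
    """A complete co-registered input set for one synthetic study area."""

    dem: RasterGrid
    vegetation: RasterGrid
    roads: VectorLayer
    destinations: VectorLayer
    seed: int


def _grid_like(values: np.ndarray, cell_size: float) -> RasterGrid:
    return RasterGrid(values=values, cell_size=cell_size, origin_x=0.0, origin_y=0.0)


def generate_dem(
    seed: int,
    n_rows: int = DEFAULT_ROWS,
    n_cols: int = DEFAULT_COLS,
    relief_m: float = 150.0,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> RasterGrid:
    """Smooth correlated elevation with a gentle dome so drainage reaches
    the grid edge.

    The field is low-pass-filtered Gaussian noise (correlation length about
    a twelfth of the grid) blended with a radial dome of the same relief;
    the dome guarantees the regional gradient points outward, so depression
    filling touches only a small fraction of cells.
    """
    if n_rows < 16 or n_cols < 16:
        raise ValueError("DEM dimensions must be at least 16 x 16")
    if relief_m <= 0:
        raise ValueError(f"relief_m must be > 0, got {relief_m}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rows, n_cols))
    sigma = max(n_rows, n_cols) / 12.0
    smooth = gaussian_filter(noise, sigma=sigma, mode="nearest")
    smooth = (smooth - smooth.min()) / max(np.ptp(smooth), 1e-12)

    rr = (np.arange(n_rows) - (n_rows - 1) / 2.0) / (n_rows / 2.0)
    cc = (np.arange(n_cols) - (n_cols - 1) / 2.0) / (n_cols / 2.0)
    radius = np.sqrt(rr[:, None] ** 2 + cc[None, :] ** 2)
    dome = 1.0 - radius / max(radius.max(), 1e-12)

    dem = relief_m * (0.45 * smooth + 0.55 * dome)
    return _grid_like(dem, cell_size)


def generate_vegetation(seed: int, dem: RasterGrid) -> RasterGrid:
    """Patchy categorical cover over {1 Forest, 2 Grass, 3 Bare, 4 Scrub}.

    A smoothed noise field blended with relative elevation is cut at fixed
    quantiles, which yields spatially contiguous patches and guarantees all
    four classes are present: grass in the lowlands, forest at mid-slope,
    scrub above, bare rock on the highest, driest fraction.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(dem.shape)
    sigma = max(dem.shape) / 25.0
    patch = gaussian_filter(noise, sigma=sigma, mode="nearest")
    patch = (patch - patch.min()) / max(np.ptp(patch), 1e-12)
    z = dem.values
    z_norm = (z - z.min()) / max(np.ptp(z), 1e-12)
    score = 0.65 * patch + 0.35 * z_norm
    q1, q2, q3 = np.quantile(score, [0.35, 0.65, 0.88])
    veg = np.full(dem.shape, 2, dtype=np.int64)  # Grass lowlands
    veg[score >= q1] = 1  # Forest mid-slope
    veg[score >= q2] = 4  # Scrub
    veg[score >= q3] = 3  # Bare, rocky tops
    return dem.copy_with(veg.astype(float))


def generate_roads(seed: int, grid: RasterGrid) -> VectorLayer:
    """A three-tier road network: one national trunk crossing the extent
    west to east, provincial branches to the north and south edges, and
    short local spurs off the branches."""
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    width = xmax - xmin
    height = ymax - ymin
    margin = grid.cell_size

    def clamp(x: float, y: float) -> tuple[float, float]:
        return (
            float(np.clip(x, xmin + margin, xmax - margin)),
            float(np.clip(y, ymin + margin, ymax - margin)),
        )

    feats: list[Feature] = []

    # national trunk: west edge to east edge with gentle meanders
    n_knots = 8
    xs = np.linspace(xmin + margin, xmax - margin, n_knots)
    base_y = ymin + height * rng.uniform(0.4, 0.6)
    ys = base_y + rng.normal(0.0, height * 0.05, size=n_knots)
    trunk = [clamp(x, y) for x, y in zip(xs, ys)]
    feats.append(Feature(LineString(trunk), {"class": "national"}))

    # provincial branches: from trunk knots toward the north and south edges
    branch_starts = [trunk[2], trunk[5]]
    branch_dirs = [1.0, -1.0]  # north, then south
    branches: list[list[tuple[float, float]]] = []
    for start, direction in zip(branch_starts, branch_dirs):
        end_y = ymax - margin if direction > 0 else ymin + margin
        n_b = 5
        bys = np.linspace(start[1], end_y, n_b)
        bxs = start[0] + np.concatenate(
            ([0.0], np.cumsum(rng.normal(0.0, width * 0.03, size=n_b - 1)))
        )
        branch = [clamp(x, y) for x, y in zip(bxs, bys)]
        branches.append(branch)
        feats.append(Feature(LineString(branch), {"class": "provincial"}))

    # local spurs: short tracks off the middle of each branch
    for branch in branches:
        mid = branch[len(branch) // 2]
        ang = rng.uniform(0.0, 2.0 * np.pi)
        length = width * rng.uniform(0.08, 0.15)
        end = clamp(mid[0] + length * np.cos(ang), mid[1] + length * np.sin(ang))
        feats.append(Feature(LineString([mid, end]), {"class": "local"}))

    return VectorLayer(features=feats)


def generate_destinations(
    seed: int, k: int, grid: RasterGrid, roads: VectorLayer | None = None
) -> VectorLayer:
    """k facility points inside the extent, placed on the road network when
    one is supplied (health services sit on roads), jittered otherwise."""
    if k < 1:
        raise ValueError(f"need at least one destination, got k={k}")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    margin = 2 * grid.cell_size
    feats: list[Feature] = []
    if roads is not None and len(roads) > 0:
        lines = [f.geometry for f in roads.features if isinstance(f.geometry, LineString)]
        trunk = max(lines, key=lambda g: g.length)
        for i in range(k):
            frac = (i + 1) / (k + 1) + rng.uniform(-0.05, 0.05)
            p = trunk.interpolate(float(np.clip(frac, 0.02, 0.98)), normalized=True)
            feats.append(Feature(Point(p.x, p.y), {"name": f"facility-{i + 1}"}))
    else:
        for i in range(k):
            x = rng.uniform(xmin + margin, xmax - margin)
            y = rng.uniform(ymin + margin, ymax - margin)
            feats.append(Feature(Point(x, y), {"name": f"facility-{i + 1}"}))
    return VectorLayer(features=feats)


def generate_landscape(
    seed: int,
    n_rows: int = DEFAULT_ROWS,
    n_cols: int = DEFAULT_COLS,
    cell_size: float = DEFAULT_CELL_SIZE,
    relief_m: float = 150.0,
    k_destinations: int = 2,
) -> LandscapeFixture:
    """One fully co-registered landscape; sub-seeds are derived from *seed*
    so every layer (and the whole fixture) is deterministic."""
    ss = np.random.SeedSequence(seed)
    s_dem, s_veg, s_road, s_dest = (int(s) % (2**31) for s in ss.generate_state(4))
    dem = generate_dem(s_dem, n_rows, n_cols, relief_m=relief_m, cell_size=cell_size)
    vegetation = generate_vegetation(s_veg, dem)
    roads = generate_roads(s_road, dem)
    destinations = generate_destinations(s_dest, k_destinations, dem, roads=roads)
    return LandscapeFixture(
        dem=dem, vegetation=vegetation, roads=roads, destinations=destinations, seed=seed
    )
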