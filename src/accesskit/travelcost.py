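"""Friction surfaces and accumulated travel time to health-service points.

The chain is: a 12-class land-cover grid plus a travel-speed lookup table
and a scenario (walking mode, time of day, weather, overrides, barriers)
gives a per-cell traversal-time surface in seconds (:func:`build_cost_grid`);
travel time to the nearest destination is then accumulated over a
16-neighbour move graph either by a sequential chamfer distance transform
with a 5x5 mask (:func:`chamfer_travel_time`, the fast interactive engine)
or exactly by multi-source Dijkstra (:func:`dijkstra_travel_time`, the
oracle); finally the accumulated minutes are banded into remoteness zones
(:func:`classify_zones`).

Moves and their costs
---------------------
The move graph connects each cell to its 8 ring neighbours and the 8 knight
neighbours of the 5x5 mask. A move of fractional distance d (in cell units,
d in {1, sqrt 2, sqrt 5}) between cells with traversal times t1, t2 seconds
costs ``d * (t1 + t2) / 2`` — the standard symmetric accumulated-cost
convention, which makes travel time on a uniform surface exact along grid
axes. Cells at or above the 99,999 s sentinel are removed from the graph
entirely (hard barriers), so cost can never leak through an impassable ring.
Note the knight moves connect cells two rows/columns apart without checking
the cells jumped over; a drawn barrier must therefore be at least two cells
thick to be truly impassable, which the barrier-drawing helpers ensure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .io_formats import VectorLayer
from .raster import RasterGrid
from .schema import IMPASSABLE_SECONDS, ALL_CLASSES, ROAD_CLASSES, STREAM_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedLookup",
    "ScenarioSpec",
    "ZoneTable",
    "DestinationSet",
    "MOVES",
    "build_cost_grid",
    "chamfer_travel_time",
    "dijkstra_travel_time",
    "classify_zones",
]

#: The 16 moves of the 5x5 mask: (drow, dcol, distance in cell units).
#: 8-connected ring (1, sqrt 2) plus knight moves (sqrt 5).
MOVES: tuple[tuple[int, int, float], ...] = tuple(
    (dr, dc, math.hypot(dr, dc))
    for dr in (-2, -1, 0, 1, 2)
    for dc in (-2, -1, 0, 1, 2)
    if (dr, dc) != (0, 0) and max(abs(dr), abs(dc)) <= 2 and (abs(dr) != 2 or abs(dc) != 0)
    and (abs(dc) != 2 or abs(dr) != 0) and not (abs(dr) == 2 and abs(dc) == 2)
)
assert len(MOVES) == 16

_MOVE_DR = np.array([m[0] for m in MOVES], dtype=np.int64)
_MOVE_DC = np.array([m[1] for m in MOVES], dtype=np.int64)
_MOVE_D = np.array([m[2] for m in MOVES], dtype=np.float64)


# ---------------------------------------------------------------------------
# Speed lookup (Table-1 style)
# ---------------------------------------------------------------------------


@dataclass
class SpeedLookup:
    """Travel speed (km/h) per land-cover class id.

    Per-cell traversal seconds are derived as
    ``cell_size_m / (kmh * 1000 / 3600)``; speed 0 maps to the 99,999 s
    impassable sentinel.
    """

    kmh: dict[int, float]
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = sorted(set(ALL_CLASSES) - set(self.kmh))
        if missing:
            raise ValueError(f"speed lookup missing class ids {missing}")
        for cid, v in self.kmh.items():
            if v < 0:
                raise ValueError(f"negative speed for class {cid}")

    def seconds_per_cell(self, class_id: int, cell_size_m: float) -> float:
        if class_id not in self.kmh:
            raise KeyError(f"no speed entry for land-cover class {class_id}")
        v = self.kmh[class_id]
        if v <= 0:
            return IMPASSABLE_SECONDS
        return cell_size_m / (v * 1000.0 / 3600.0)

    def with_overrides(self, overrides: dict[int, float]) -> "SpeedLookup":
        unknown = sorted(set(overrides) - set(self.kmh))
        if unknown:
            raise KeyError(f"speed override for unknown class ids {unknown}")
        return SpeedLookup(kmh={**self.kmh, **overrides}, names=dict(self.names))


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

WALKING_MODES = ("walking", "assisted", "stretcher")
TIMES_OF_DAY = ("day", "night")
WEATHERS = ("dry", "rainy", "flooding")

#: Walking-speed multiplier per mode; assisted halves the speed, a stretcher
#: case moves at a fifth of it.
WALKING_FACTOR = {"walking": 1.0, "assisted": 0.5, "stretcher": 0.2}

#: Night slows all travel speeds by 20% (seconds x 1.25).
NIGHT_SPEED_FACTOR = 0.8

#: Stream classes made impassable per weather: rain closes the three highest
#: order watercourses; flooding closes them all.
WEATHER_CLOSED = {
    "dry": frozenset(),
    "rainy": frozenset({103, 104, 105}),
    "flooding": frozenset(STREAM_CLASSES),
}


@dataclass
class ScenarioSpec:
    """One travel scenario: who travels, when, in what weather, over which
    edited landscape, to which destinations.

    barriers are (cells, minutes) pairs: the listed cells take
    ``minutes * 60`` seconds each to cross, minutes in [1, 600];
    drawn_roads are (cells, class_id) land-cover edits applied before the
    lookup. service selects which destinations are open (see
    :mod:`accesskit.scenarios`); destinations optionally carries the
    scenario's own destination points as (x, y) map coordinates.
    """

    walking_mode: str = "walking"
    time_of_day: str = "day"
    weather: str = "dry"
    road_speed_overrides: dict[int, float] = field(default_factory=dict)
    barriers: list[tuple[list[tuple[int, int]], float]] = field(default_factory=list)
    drawn_roads: list[tuple[list[tuple[int, int]], int]] = field(default_factory=list)
    service: str = "any"
    walking_factor_on_roads: bool = False
    destinations: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.walking_mode not in WALKING_MODES:
            raise ValueError(
                f"walking_mode must be one of {WALKING_MODES}, got {self.walking_mode!r}"
            )
        if self.time_of_day not in TIMES_OF_DAY:
            raise ValueError(
                f"time_of_day must be one of {TIMES_OF_DAY}, got {self.time_of_day!r}"
            )
        if self.weather not in WEATHERS:
            raise ValueError(f"weather must be one of {WEATHERS}, got {self.weather!r}")
        for cells, minutes in self.barriers:
            if not 1 <= minutes <= 600:
                raise ValueError(f"barrier minutes must lie in [1, 600], got {minutes}")
        for cells, cid in self.drawn_roads:
            if cid not in ALL_CLASSES:
                raise ValueError(f"drawn-road class id {cid} not in the land-cover schema")

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioSpec":
        kwargs = dict(doc)
        if "road_speed_overrides" in kwargs and kwargs["road_speed_overrides"]:
            kwargs["road_speed_overrides"] = {
                int(k): float(v) for k, v in kwargs["road_speed_overrides"].items()
            }
        for key in ("barriers", "drawn_roads"):
            if key in kwargs and kwargs[key]:
                kwargs[key] = [
                    ([tuple(int(i) for i in c) for c in cells], val)
                    for cells, val in kwargs[key]
                ]
        return cls(**kwargs)

    def with_fields(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Destinations
# ---------------------------------------------------------------------------


@dataclass
class DestinationSet:
    """Destination points in map coordinates with their snapped cell indices."""

    points: list[tuple[float, float]]
    cells: list[tuple[int, int]]

    @classmethod
    def from_points(cls, points, grid: RasterGrid) -> "DestinationSet":
        """Snap map-coordinate points to nearest cell centres on *grid*.

        Two points snapping to the same cell collapse silently (logged).
        """
        pts = [(float(x), float(y)) for x, y in points]
        if not pts:
            raise ValueError("destination set must not be empty")
        cells: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        for x, y in pts:
            cell = grid.index_of(x, y)
            if cell in seen:
                logger.info("destinations collapse onto one cell %s", cell)
                continue
            seen.add(cell)
            cells.append(cell)
        return cls(points=pts, cells=cells)

    @classmethod
    def from_vector(cls, layer: VectorLayer, grid: RasterGrid) -> "DestinationSet":
        pts = [(f.geometry.x, f.geometry.y) for f in layer.features]
        return cls.from_points(pts, grid)


# ---------------------------------------------------------------------------
# Zone table (Table-2 style)
# ---------------------------------------------------------------------------


@dataclass
class ZoneTable:
    """Ordered half-open minute intervals [min, max) -> zone class.

    The intervals must partition [0, top] contiguously; unreachable
    (sentinel) cells classify into the top zone.
    """

    classes: list[int]
    minima: list[float]
    maxima: list[float]

    @classmethod
    def from_rows(cls, rows: list[tuple[int, float, float]]) -> "ZoneTable":
        if not rows:
            raise ValueError("zone table is empty")
        rows = sorted(rows, key=lambda r: r[1])
        classes = [r[0] for r in rows]
        minima = [r[1] for r in rows]
        maxima = [r[2] for r in rows]
        if len(set(classes)) != len(classes):
            raise ValueError("duplicate zone class in table")
        if minima[0] != 0:
            raise ValueError(f"zone intervals must start at 0, got {minima[0]}")
        for i in range(len(rows)):
            if maxima[i] <= minima[i]:
                raise ValueError(f"empty or inverted zone interval {minima[i]}–{maxima[i]}")
            if i + 1 < len(rows) and not math.isclose(maxima[i], minima[i + 1]):
                raise ValueError(
                    f"zone gap/overlap between {maxima[i]} and {minima[i + 1]} minutes"
                )
        return cls(classes=classes, minima=minima, maxima=maxima)

    def classify_minutes(self, minutes: np.ndarray) -> np.ndarray:
        edges = np.array(self.minima[1:])  # interior boundaries
        idx = np.searchsorted(edges, minutes, side="right")
        return np.asarray(self.classes, dtype=np.int64)[idx]

    @property
    def top_class(self) -> int:
        return self.classes[-1]


# ---------------------------------------------------------------------------
# Cost-grid construction
# ---------------------------------------------------------------------------


def build_cost_grid(
    lc: RasterGrid, lookup: SpeedLookup, scenario: ScenarioSpec | None = None
) -> RasterGrid:
    """Per-cell traversal seconds for a land-cover grid under a scenario.

    Modifiers apply in a fixed order so scenario composition is reproducible:
    (1) drawn roads / land-cover edits, (2) road speed overrides,
    (3) the walking-mode factor on off-road classes, (4) weather closures of
    watercourse classes, (5) the night slowdown, (6) drawn barriers — so a
    barrier always wins. Nodata cells are impassable.
    """
    scenario = scenario or ScenarioSpec()

    if scenario.drawn_roads:
        from .landcover import edit_landcover

        lc = edit_landcover(lc, scenario.drawn_roads)

    lut = lookup.with_overrides(scenario.road_speed_overrides)

    seconds: dict[int, float] = {}
    walk_f = WALKING_FACTOR[scenario.walking_mode]
    closed = WEATHER_CLOSED[scenario.weather]
    night = 1.0 / NIGHT_SPEED_FACTOR if scenario.time_of_day == "night" else 1.0
    for cid in ALL_CLASSES:
        s = lut.seconds_per_cell(cid, lc.cell_size)
        is_road = cid in ROAD_CLASSES
        if (not is_road or scenario.walking_factor_on_roads) and walk_f != 1.0:
            if s < IMPASSABLE_SECONDS:
                s = s / walk_f
        if cid in closed:
            s = IMPASSABLE_SECONDS
        if s < IMPASSABLE_SECONDS:
            s = min(s * night, IMPASSABLE_SECONDS)
        seconds[cid] = s

    vals = lc.values
    out = np.full(lc.shape, IMPASSABLE_SECONDS, dtype=float)
    nod = lc.nodata_mask()
    present = sorted(set(np.unique(vals[~nod]).astype(int)))
    unknown = [c for c in present if c not in ALL_CLASSES]
    if unknown:
        raise KeyError(f"land-cover grid contains class ids outside the schema: {unknown}")
    for cid in present:
        out[(vals == cid) & ~nod] = seconds[cid]

    for cells, minutes in scenario.barriers:
        for r, c in cells:
            out[r, c] = minutes * 60.0

    return lc.copy_with(out)


# ---------------------------------------------------------------------------
# Chamfer engine
# ---------------------------------------------------------------------------


@njit(cache=False)
def _chamfer_scan(acc, t, passable, dr, dc, dist, reverse, row_major):  # pragma: no cover
    n_rows, n_cols = acc.shape
    n_moves = dr.shape[0]
    changed = 0
    outer = n_rows if row_major else n_cols
    inner = n_cols if row_major else n_rows
    for oi in range(outer):
        o = outer - 1 - oi if reverse else oi
        for ii in range(inner):
            i = inner - 1 - ii if reverse else ii
            r, c = (o, i) if row_major else (i, o)
            if not passable[r, c]:
                continue
            best = acc[r, c]
            for m in range(n_moves):
                nr = r + dr[m]
                nc = c + dc[m]
                if nr < 0 or nr >= n_rows or nc < 0 or nc >= n_cols:
                    continue
                if not passable[nr, nc]:
                    continue
                cand = acc[nr, nc] + dist[m] * 0.5 * (t[r, c] + t[nr, nc])
                if cand < best:
                    best = cand
            if best < acc[r, c]:
                acc[r, c] = best
                changed += 1
    return changed


def chamfer_travel_time(
    cost: RasterGrid,
    destinations: DestinationSet,
    scan_pairs: int = 2,
    converge: bool = False,
    max_scan_pairs: int = 50,
) -> RasterGrid:
    """Accumulated travel time by the sequential 5x5 chamfer transform.

    All cells start at the sentinel and destinations at zero; four scans
    (forward and backward in row-major order, then forward and backward in
    column-major order) propagate, for each of the 16 mask neighbours, the
    candidate ``neighbour + d * (t_cell + t_neighbour) / 2`` and keep the
    minimum. ``converge=True`` keeps adding scan pairs until no cell changes.
    """
    t, passable, acc = _prepare(cost, destinations)
    n_pairs = max_scan_pairs if converge else scan_pairs
    for p in range(n_pairs):
        row_major = p % 2 == 0
        changed = 0
        for reverse in (False, True):
            changed += _chamfer_scan(
                acc, t, passable, _MOVE_DR, _MOVE_DC, _MOVE_D, reverse, row_major
            )
        if converge and changed == 0:
            break
    return _finalize(cost, acc)


# ---------------------------------------------------------------------------
# Dijkstra engine (exact oracle)
# ---------------------------------------------------------------------------


def dijkstra_travel_time(cost: RasterGrid, destinations: DestinationSet) -> RasterGrid:
    """Exact multi-source shortest travel time on the 16-neighbour graph.

    Same moves and move costs as the chamfer engine; serves as its oracle and
    as the exact engine for scenario work at desk scale.
    """
    t, passable, acc = _prepare(cost, destinations)
    n_rows, n_cols = t.shape
    n = n_rows * n_cols
    rows_idx, cols_idx = np.nonzero(passable)
    src_list, dst_list, w_list = [], [], []
    for dr, dc, d in MOVES:
        nr = rows_idx + dr
        nc = cols_idx + dc
        ok = (nr >= 0) & (nr < n_rows) & (nc >= 0) & (nc < n_cols)
        ok2 = ok.copy()
        ok2[ok] &= passable[nr[ok], nc[ok]]
        src = rows_idx[ok2] * n_cols + cols_idx[ok2]
        dst = nr[ok2] * n_cols + nc[ok2]
        w = d * 0.5 * (t[rows_idx[ok2], cols_idx[ok2]] + t[nr[ok2], nc[ok2]])
        src_list.append(src)
        dst_list.append(dst)
        w_list.append(w)
    graph = coo_matrix(
        (np.concatenate(w_list), (np.concatenate(src_list), np.concatenate(dst_list))),
        shape=(n, n),
    ).tocsr()
    sources = [r * n_cols + c for r, c in destinations.cells]
    dist = _csgraph_dijkstra(graph, directed=True, indices=sources, min_only=True)
    acc = dist.reshape(n_rows, n_cols)
    acc[~passable] = np.inf
    return _finalize(cost, acc)


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------


def _prepare(cost: RasterGrid, destinations: DestinationSet):
    if not destinations.cells:
        raise ValueError("destination set must not be empty")
    t = cost.values.astype(np.float64)
    passable = (t < IMPASSABLE_SECONDS) & (t > 0) & ~cost.nodata_mask()
    for r, c in destinations.cells:
        if not (0 <= r < cost.n_rows and 0 <= c < cost.n_cols):
            raise ValueError(f"destination cell {(r, c)} outside the grid")
        if not passable[r, c]:
            raise ValueError(f"destination cell {(r, c)} lies on an impassable cell")
    acc = np.full(cost.shape, np.inf, dtype=np.float64)
    for r, c in destinations.cells:
        acc[r, c] = 0.0
    return t, passable, acc


def _finalize(cost: RasterGrid, acc: np.ndarray) -> RasterGrid:
    out = np.where(np.isfinite(acc), acc, IMPASSABLE_SECONDS)
    return cost.copy_with(out)


# ---------------------------------------------------------------------------
# Zone classification
# ---------------------------------------------------------------------------


def classify_zones(tt: RasterGrid, zones: ZoneTable) -> RasterGrid:
    """Band accumulated seconds into travel-time (remoteness) zone classes.

    Minutes are classified into half-open intervals [min, max); unreachable
    sentinel cells take the top class.
    """
    minutes = tt.values / 60.0
    zone = zones.classify_minutes(minutes)
    unreachable = tt.values >= IMPASSABLE_SECONDS
    zone[unreachable] = zones.top_class
    zone[tt.nodata_mask()] = zones.top_class
    return tt.copy_with(zone.astype(float))
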