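"""Assembly of the single 12-class land-cover grid.

Roads are burnt from vector polylines into a raster, then roads, stream
classes and vegetation are mosaicked with the fixed precedence
road > stream > vegetation (roads are assumed bridged over watercourses;
a flooded crossing is modelled by drawing a barrier, not by the mosaic).
Interactive edits — drawing roads known to exist, marking damaged sections —
are cell-level overwrites applied in list order.
"""

from __future__ import annotations

import logging

import numpy as np
from shapely.geometry import LineString

from .io_formats import VectorLayer
from .raster import RasterGrid, check_coregistered
from .schema import ALL_CLASSES, ROAD_CLASS_IDS, ROAD_CLASSES, STREAM_CLASSES, VEGETATION_CLASSES

logger = logging.getLogger(__name__)

__all__ = ["rasterize_roads", "compose_landcover", "edit_landcover", "BARRIER"]

#: Edit marker for an impassable cell: mapped to the top watercourse class,
#: the one class no scenario can traverse, keeping the vocabulary closed.
BARRIER = "barrier"
_BARRIER_CLASS = 105


def rasterize_roads(roads: VectorLayer, grid: RasterGrid) -> RasterGrid:
    """Burn road polylines into a raster of road class ids (0 = no road).

    Every cell whose centre lies within half a cell of a polyline receives
    the road's class id; line tracing is all-touched so the rasterised road
    is an 8-connected chain with no diagonal gaps. Where classes cross, the
    faster class (lower id) wins. Geometry outside the grid extent is
    clipped (logged), never an error.
    """
    out = np.zeros(grid.shape, dtype=np.int64)
    feats = []
    for f in roads.features:
        if not isinstance(f.geometry, LineString):
            continue
        cls = f.attributes.get("class")
        if cls not in ROAD_CLASS_IDS:
            raise ValueError(
                f"road feature has class {cls!r}; allowed: {sorted(ROAD_CLASS_IDS)}"
            )
        feats.append((ROAD_CLASS_IDS[cls], f.geometry))
    # apply slowest class first so the fastest overwrites at crossings
    for cid, geom in sorted(feats, key=lambda t: -t[0]):
        clipped = False
        for cell in _trace_cells(geom, grid):
            if cell is None:
                clipped = True
                continue
            out[cell] = cid
        if clipped:
            logger.info("road (class %s) partly outside extent; clipped", cid)
    return grid.copy_with(out.astype(float))


def _trace_cells(line: LineString, grid: RasterGrid):
    """Cells touched by *line*, sampled densely enough to be 8-connected.

    Yields None for samples outside the extent (callers log the clipping).
    Sampling at a quarter cell guarantees consecutive in-extent samples land
    on 8-adjacent cells.
    """
    xmin, ymin, xmax, ymax = grid.extent
    step = grid.cell_size / 4.0
    length = line.length
    n_samples = max(2, int(np.ceil(length / step)) + 1)
    for frac in np.linspace(0.0, 1.0, n_samples):
        p = line.interpolate(frac, normalized=True)
        if not (xmin <= p.x <= xmax and ymin <= p.y <= ymax):
            yield None
            continue
        yield grid.index_of(p.x, p.y)


def compose_landcover(
    vegetation: RasterGrid, stream_classes: RasterGrid, road_classes: RasterGrid
) -> RasterGrid:
    """Mosaic the three layers into the 12-class land-cover grid.

    Per cell the precedence is road > stream > vegetation. A cell with no
    road, no stream and nodata vegetation propagates nodata. The base layer
    may itself be a previously composed grid (any schema class), which makes
    re-composition with the same overlays the identity.
    """
    check_coregistered(vegetation, stream_classes, road_classes)
    veg = vegetation.values.astype(np.int64)
    stream = stream_classes.values.astype(np.int64)
    road = road_classes.values.astype(np.int64)
    _check_values(veg, set(ALL_CLASSES), vegetation.nodata_mask(), "vegetation")
    _check_values(stream, set(STREAM_CLASSES) | {0}, stream_classes.nodata_mask(), "stream")
    _check_values(road, set(ROAD_CLASSES) | {0}, road_classes.nodata_mask(), "road")

    out = veg.astype(float)
    out[vegetation.nodata_mask()] = vegetation.nodata
    stream_on = (stream > 0) & ~stream_classes.nodata_mask()
    out[stream_on] = stream[stream_on]
    road_on = (road > 0) & ~road_classes.nodata_mask()
    out[road_on] = road[road_on]
    return vegetation.copy_with(out)


def _check_values(arr, allowed: set[int], nodata_mask, name: str) -> None:
    bad = sorted(set(np.unique(arr[~nodata_mask]).astype(int)) - allowed)
    if bad:
        raise ValueError(f"{name} raster contains values outside its vocabulary: {bad}")


def edit_landcover(grid: RasterGrid, edits) -> RasterGrid:
    """Overwrite listed cells with new class ids, later edits winning.

    *edits* is a list of ``(cells, new_class)`` where ``cells`` is a list of
    (row, col) pairs and ``new_class`` a schema class id or the ``BARRIER``
    marker (mapped to the impassable class 105). Invalid ids raise before
    any mutation; all unlisted cells are untouched.
    """
    resolved = []
    for cells, new_class in edits:
        if new_class == BARRIER:
            cid = _BARRIER_CLASS
        else:
            cid = int(new_class)
            if cid not in ALL_CLASSES:
                raise ValueError(
                    f"edit class id {new_class!r} is not in the land-cover schema"
                )
        resolved.append((cells, cid))
    out = grid.values.copy()
    for cells, cid in resolved:
        for r, c in cells:
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise ValueError(f"edit cell {(r, c)} outside the grid")
            out[r, c] = cid
    return grid.copy_with(out)
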