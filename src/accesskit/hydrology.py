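"""Watercourse extraction from elevation.

The chain mirrors standard raster hydrology: depressions in the DEM are
filled so every cell drains to the grid edge (priority-flood with an epsilon
gradient across filled flats); each cell then drains to its steepest-descent
D8 neighbour; flow accumulation counts the upstream catchment of every cell;
cells whose accumulation exceeds an initiation threshold form the stream
network, ordered by the Strahler rule; finally orders are binned into the
five watercourse classes of the land-cover schema (order k in 1..4 ->
class 100+k, order >= 5 capped into class 105, the class treated as never
passable).
"""

from __future__ import annotations

import heapq
from collections import deque

import numpy as np

from .raster import RasterGrid

__all__ = [
    "D8_OFFSETS",
    "OUTLET",
    "NODATA_DIR",
    "fill_sinks",
    "d8_flow",
    "flow_accumulation",
    "strahler",
    "streams_to_classes",
]

#: D8 neighbour order used everywhere, including tie-breaking:
#: E, SE, S, SW, W, NW, N, NE.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_D8_DIST = np.array([np.hypot(dr, dc) for dr, dc in D8_OFFSETS])

OUTLET = -1  # edge cell with no lower neighbour: water leaves the grid here
NODATA_DIR = -2


def fill_sinks(dem: RasterGrid, eps: float = 1e-6) -> RasterGrid:
    """Raise interior depressions to their spill elevation (priority flood).

    A tiny increment *eps* is applied across filled flats so that the output
    has a strictly descending 8-neighbour path from every cell to the grid
    edge, which makes steepest-descent flow defined everywhere. Cells not in
    depressions are unchanged; the operation is idempotent.
    """
    z = dem.values.astype(np.float64).copy()
    nod = dem.nodata_mask()
    if nod.all():
        raise ValueError("cannot fill an all-nodata elevation grid")
    n_rows, n_cols = z.shape
    closed = nod.copy()
    heap: list[tuple[float, int, int, int]] = []
    seq = 0
    # seed with the grid edge (and cells bordering nodata, which drains)
    for r in range(n_rows):
        for c in range(n_cols):
            if closed[r, c]:
                continue
            on_edge = r in (0, n_rows - 1) or c in (0, n_cols - 1)
            if not on_edge:
                on_edge = any(
                    nod[r + dr, c + dc]
                    for dr, dc in D8_OFFSETS
                    if 0 <= r + dr < n_rows and 0 <= c + dc < n_cols
                )
            if on_edge:
                heapq.heappush(heap, (z[r, c], seq, r, c))
                seq += 1
                closed[r, c] = True
    while heap:
        zc, _, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols) or closed[nr, nc]:
                continue
            closed[nr, nc] = True
            if z[nr, nc] <= zc:
                z[nr, nc] = zc + eps
            heapq.heappush(heap, (z[nr, nc], seq, nr, nc))
            seq += 1
    z[nod] = dem.values[nod]
    return dem.copy_with(z)


def d8_flow(dem_filled: RasterGrid) -> RasterGrid:
    """Steepest-descent D8 flow directions on a sink-free DEM.

    Each non-nodata cell receives the index (0..7, order E SE S SW W NW N NE)
    of the neighbour with the largest positive slope ``drop / distance``;
    ties take the first neighbour in that fixed order. Edge cells with no
    lower neighbour are outlets (-1). Residual flats (possible on
    user-supplied DEMs filled without an epsilon) are resolved by routing
    across equal elevation toward the flat's spill, never by an error.
    """
    z = dem_filled.values.astype(np.float64)
    nod = dem_filled.nodata_mask()
    n_rows, n_cols = z.shape
    direction = np.full(z.shape, NODATA_DIR, dtype=np.int8)
    unresolved: list[tuple[int, int]] = []
    for r in range(n_rows):
        for c in range(n_cols):
            if nod[r, c]:
                continue
            best_slope = 0.0
            best_dir = -9
            for k, (dr, dc) in enumerate(D8_OFFSETS):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < n_rows and 0 <= nc < n_cols) or nod[nr, nc]:
                    continue
                slope = (z[r, c] - z[nr, nc]) / _D8_DIST[k]
                if slope > best_slope:
                    best_slope = slope
                    best_dir = k
            if best_dir >= 0:
                direction[r, c] = best_dir
            elif r in (0, n_rows - 1) or c in (0, n_cols - 1):
                direction[r, c] = OUTLET
            else:
                direction[r, c] = -9  # flat, resolve below
                unresolved.append((r, c))
    if unresolved:
        _resolve_flats(z, direction, unresolved)
    return dem_filled.copy_with(direction)


def _resolve_flats(z, direction, unresolved) -> None:
    """Route flat interior cells toward already-resolved equal-height cells."""
    n_rows, n_cols = z.shape
    pending = set(unresolved)
    queue = deque()
    for r, c in unresolved:
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            nr, nc = r + dr, c + dc
            if (
                0 <= nr < n_rows
                and 0 <= nc < n_cols
                and (nr, nc) not in pending
                and direction[nr, nc] != NODATA_DIR
                and z[nr, nc] <= z[r, c]
            ):
                direction[r, c] = k
                queue.append((r, c))
                pending.discard((r, c))
                break
    while queue:
        r, c = queue.popleft()
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and (nr, nc) in pending:
                # neighbour flows into (r, c): direction is the reverse offset
                direction[nr, nc] = (k + 4) % 8
                pending.discard((nr, nc))
                queue.append((nr, nc))
    for r, c in pending:  # isolated one-cell basin: treat as internal outlet
        direction[r, c] = OUTLET


def _downstream_index(flowdir: RasterGrid) -> np.ndarray:
    """Flat index of each cell's downstream cell; -1 for outlets/nodata."""
    d = flowdir.values.astype(np.int64)
    n_rows, n_cols = d.shape
    down = np.full(d.size, -1, dtype=np.int64)
    rows, cols = np.nonzero(d >= 0)
    dr = np.array([o[0] for o in D8_OFFSETS])[d[rows, cols]]
    dc = np.array([o[1] for o in D8_OFFSETS])[d[rows, cols]]
    down[rows * n_cols + cols] = (rows + dr) * n_cols + (cols + dc)
    return down


def flow_accumulation(flowdir: RasterGrid) -> RasterGrid:
    """Number of cells draining through each cell, counting the cell itself.

    Computed by Kahn's topological traversal of the flow graph, which also
    verifies acyclicity; accumulation at an outlet equals its catchment size.
    """
    d = flowdir.values.astype(np.int64)
    n_rows, n_cols = d.shape
    n = d.size
    down = _downstream_index(flowdir)
    valid = (d.reshape(-1) != NODATA_DIR)
    acc = np.where(valid, 1.0, 0.0)
    indeg = np.zeros(n, dtype=np.int64)
    has_down = down >= 0
    np.add.at(indeg, down[has_down], 1)
    queue = deque(np.nonzero(valid & (indeg == 0))[0].tolist())
    processed = 0
    while queue:
        i = queue.popleft()
        processed += 1
        j = down[i]
        if j >= 0:
            acc[j] += acc[i]
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if processed != int(valid.sum()):
        raise ValueError("flow-direction graph contains a cycle")
    out = acc.reshape(n_rows, n_cols)
    out[d == NODATA_DIR] = flowdir.nodata
    return flowdir.copy_with(out)


def strahler(
    flowdir: RasterGrid, accumulation: RasterGrid, stream_threshold_cells: int
) -> RasterGrid:
    """Strahler order on stream cells (accumulation >= threshold), 0 elsewhere.

    Headwater stream cells take order 1; where two upstream branches of equal
    order n meet, the downstream order is n + 1; a lower-order tributary
    leaves the order unchanged.
    """
    if stream_threshold_cells < 1:
        raise ValueError("stream threshold must be >= 1 cell")
    d = flowdir.values.astype(np.int64)
    n_rows, n_cols = d.shape
    n = d.size
    acc = accumulation.values.reshape(-1)
    stream = (acc >= stream_threshold_cells) & (d.reshape(-1) != NODATA_DIR)
    down = _downstream_index(flowdir)
    order = np.zeros(n, dtype=np.int64)
    # upstream stream-cell counts drive a topological sweep over stream cells
    indeg = np.zeros(n, dtype=np.int64)
    src = np.nonzero(stream & (down >= 0))[0]
    dst = down[src]
    on_stream = stream[dst]
    np.add.at(indeg, dst[on_stream], 1)
    up_orders: dict[int, list[int]] = {}
    queue = deque(np.nonzero(stream & (indeg == 0))[0].tolist())
    while queue:
        i = queue.popleft()
        ups = up_orders.get(i, [])
        if not ups:
            order[i] = 1
        else:
            m = max(ups)
            order[i] = m + 1 if ups.count(m) >= 2 else m
        j = down[i]
        if j >= 0 and stream[j]:
            up_orders.setdefault(j, []).append(order[i])
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    return flowdir.copy_with(order.reshape(n_rows, n_cols).astype(float))


def streams_to_classes(streams: RasterGrid) -> RasterGrid:
    """Bin Strahler orders into the land-cover stream classes.

    Order k in 1..4 -> class 100+k; order >= 5 -> class 105; non-stream -> 0.
    """
    o = streams.values.astype(np.int64)
    out = np.zeros_like(o)
    on = o >= 1
    out[on] = 100 + np.minimum(o[on], 5)
    return streams.copy_with(out.astype(float))
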