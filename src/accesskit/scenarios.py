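"""Factorial scenario sweeps over travel conditions.

A sweep enumerates the cartesian product of scenario axes (for example three
walking modes x two times of day x three weather states = 18 runs), computes
a travel-time and zone grid for every combination, optionally writes each
grid to disk under a stable spec-derived name, and can render the runs as a
single tiled composite ordered worst conditions first.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path

from .io_formats import VectorLayer, write_ascii_grid
from .raster import RasterGrid
from .travelcost import (
    DestinationSet,
    ScenarioSpec,
    SpeedLookup,
    ZoneTable,
    build_cost_grid,
    chamfer_travel_time,
    classify_zones,
    dijkstra_travel_time,
)

__all__ = [
    "ScenarioAxes",
    "ScenarioMatrix",
    "SweepError",
    "enumerate_scenarios",
    "service_availability",
    "run_sweep",
]


class SweepError(RuntimeError):
    """A sweep aborted; the message names the offending scenario."""


#: Canonical worst-to-best value order per axis, used for the composite
#: layout: higher rank = worse travel conditions.
_SEVERITY_ORDER = {
    "walking_mode": ["walking", "assisted", "stretcher"],
    "time_of_day": ["day", "night"],
    "weather": ["dry", "rainy", "flooding"],
}


@dataclass
class ScenarioAxes:
    """Named scenario axes, each a non-empty list of field values."""

    axes: dict[str, list]

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclass_fields(ScenarioSpec)}
        for name, values in self.axes.items():
            if name not in valid:
                raise ValueError(
                    f"unknown scenario field {name!r}; valid fields: {sorted(valid)}"
                )
            if not values:
                raise ValueError(f"axis {name!r} is empty")

    @property
    def cardinality(self) -> int:
        n = 1
        for values in self.axes.values():
            n *= len(values)
        return n


@dataclass
class ScenarioMatrix:
    """Ordered sweep output: one (spec, travel time, zones) triple per run."""

    entries: list[tuple[ScenarioSpec, RasterGrid, RasterGrid]]
    axes: ScenarioAxes

    def __len__(self) -> int:
        return len(self.entries)


def enumerate_scenarios(axes: ScenarioAxes, base: ScenarioSpec | None = None) -> list[ScenarioSpec]:
    """Full cartesian product of the axes over *base*, lexicographic in the
    axis order given; base fields fill every unlisted axis."""
    base = base or ScenarioSpec()
    names = list(axes.axes)
    specs = []
    for combo in itertools.product(*(axes.axes[n] for n in names)):
        specs.append(base.with_fields(**dict(zip(names, combo))))
    return specs


def severity_score(spec: ScenarioSpec, axes: ScenarioAxes) -> int:
    """Sum of per-axis ranks (0 = best); orders the composite worst-first.

    Fields without a canonical order rank by their position in the axis list.
    """
    score = 0
    for name, values in axes.axes.items():
        value = getattr(spec, name)
        order = _SEVERITY_ORDER.get(name)
        score += order.index(value) if order is not None else values.index(value)
    return score


def service_availability(
    spec: ScenarioSpec, destinations: VectorLayer, grid: RasterGrid
) -> DestinationSet:
    """Destinations open under the scenario's service state, snapped to cells.

    A destination feature with an ``available`` attribute (a service state or
    list of states, e.g. ["doctor_in"]) is open only when the spec's service
    state matches; features without the attribute — and every feature when
    the spec's service is "any" — are always open.
    """
    open_points = []
    for f in destinations.features:
        avail = f.attributes.get("available")
        if spec.service == "any" or avail is None:
            ok = True
        elif isinstance(avail, (list, tuple, set)):
            ok = spec.service in avail
        else:
            ok = spec.service == avail
        if ok:
            open_points.append((f.geometry.x, f.geometry.y))
    if not open_points:
        raise ValueError(
            f"no destination is available under service state {spec.service!r}"
        )
    return DestinationSet.from_points(open_points, grid)


def _spec_filename(prefix: str, spec: ScenarioSpec, axes: ScenarioAxes) -> str:
    parts = [
        f"{name}={re.sub(r'[^A-Za-z0-9_-]', '-', str(getattr(spec, name)))}"
        for name in axes.axes
    ]
    return prefix + "__" + "__".join(parts) + ".asc"


def run_sweep(
    lc: RasterGrid,
    lookup: SpeedLookup,
    zones: ZoneTable,
    axes: ScenarioAxes,
    base: ScenarioSpec | None = None,
    destinations: VectorLayer | None = None,
    engine: str = "chamfer",
    outdir: str | Path | None = None,
    composite: str | Path | None = None,
) -> ScenarioMatrix:
    """One travel-time + zone grid per scenario in the product of *axes*.

    Destinations come from the *destinations* layer (filtered per scenario by
    service availability) or, failing that, from the base spec's own points.
    Any single failing run aborts the sweep with the offending spec named.
    With *outdir* set, every grid is written under a stable spec-derived file
    name; *composite* renders the zone grids as one tiled image ordered
    worst conditions at the top left.
    """
    base = base or ScenarioSpec()
    accumulate = {"chamfer": chamfer_travel_time, "dijkstra": dijkstra_travel_time}
    if engine not in accumulate:
        raise ValueError(f"engine must be chamfer or dijkstra, got {engine!r}")
    entries = []
    for spec in enumerate_scenarios(axes, base):
        try:
            if destinations is not None:
                dest = service_availability(spec, destinations, lc)
            elif spec.destinations:
                dest = DestinationSet.from_points(spec.destinations, lc)
            else:
                raise ValueError("no destinations supplied")
            cost = build_cost_grid(lc, lookup, spec)
            tt = accumulate[engine](cost, dest)
            zg = classify_zones(tt, zones)
        except Exception as exc:
            raise SweepError(f"scenario {spec} failed: {exc}") from exc
        entries.append((spec, tt, zg))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for spec, tt, zg in entries:
            write_ascii_grid(tt, outdir / _spec_filename("tt", spec, axes))
            write_ascii_grid(zg, outdir / _spec_filename("zones", spec, axes))

    matrix = ScenarioMatrix(entries=entries, axes=axes)
    if composite is not None:
        render_composite(matrix, composite)
    return matrix


def render_composite(matrix: ScenarioMatrix, path: str | Path) -> None:
    """Tile the sweep's zone grids into one image, worst scenario first."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sorted(
        range(len(matrix.entries)),
        key=lambda i: -severity_score(matrix.entries[i][0], matrix.axes),
    )
    n = len(order)
    ncols = min(6, max(1, int(round(n**0.5 * 1.2))))
    nrows = -(-n // ncols)
    fig, ax_grid = plt.subplots(
        nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows), squeeze=False
    )
    flat_axes = [a for row in ax_grid for a in row]
    for ax in flat_axes:
        ax.axis("off")
    for ax, i in zip(flat_axes, order):
        spec, _, zg = matrix.entries[i]
        ax.imshow(zg.values, cmap="RdYlBu_r", interpolation="nearest")
        label = ",".join(str(getattr(spec, name)) for name in matrix.axes.axes)
        ax.set_title(label, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
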