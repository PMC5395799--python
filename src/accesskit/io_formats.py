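"""Readers and writers for every external format the toolkit touches.

ESRI ASCII grid (.asc) is the interchange raster format: it is plain text,
diff-able, and understood by every desktop GIS. Vectors (roads, destinations)
travel as GeoJSON FeatureCollections; the speed and zone tables as CSV;
scenario configurations as YAML.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from shapely.geometry import LineString, Point, mapping, shape

from .raster import DEFAULT_NODATA, RasterGrid
from .schema import ROAD_CLASS_IDS

__all__ = [
    "Feature",
    "VectorLayer",
    "FormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_vector",
    "write_vector",
    "read_lookup_csv",
    "read_zone_csv",
    "read_scenario_yaml",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Vector layers
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    geometry: Point | LineString
    attributes: dict[str, Any] = field(default_factory=dict)


@dataclass
class VectorLayer:
    """A list of point or polyline features in map coordinates."""

    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _fmt_number(v: float) -> str:
    """Canonical number formatting: integers bare, floats via repr."""
    fv = float(v)
    if fv == int(fv) and abs(fv) < 1e15:
        return str(int(fv))
    return repr(fv)


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid.

    The six header lines (``ncols nrows xllcorner yllcorner cellsize
    NODATA_value``) are parsed case-insensitively; ``NODATA_value`` is
    optional and defaults to -9999. Values follow row-major from the north
    edge.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (*_HEADER_KEYS, "nodata_value"):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: bad header line {i + 1}: {line!r}") from exc
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: missing header fields {missing}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if n_rows <= 0 or n_cols <= 0:
        raise FormatError(f"{path}: non-positive grid dimensions")
    nodata = header.get("nodata_value", DEFAULT_NODATA)

    rows: list[list[float]] = []
    for j, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        try:
            row = [float(t) for t in line.split()]
        except ValueError as exc:
            raise FormatError(f"{path}: bad value on line {j}: {line!r}") from exc
        if len(row) != n_cols:
            raise FormatError(
                f"{path}: line {j} has {len(row)} values, expected ncols={n_cols}"
            )
        rows.append(row)
    if len(rows) != n_rows:
        raise FormatError(f"{path}: found {len(rows)} data rows, expected nrows={n_rows}")
    return RasterGrid(
        values=np.array(rows, dtype=float),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata=nodata,
    )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write *grid* as a canonical ESRI ASCII file (re-readable to equality)."""
    path = Path(path)
    out = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {_fmt_number(grid.origin_x)}",
        f"yllcorner {_fmt_number(grid.origin_y)}",
        f"cellsize {_fmt_number(grid.cell_size)}",
        f"NODATA_value {_fmt_number(grid.nodata)}",
    ]
    vals = np.where(np.isfinite(grid.values.astype(float)), grid.values, grid.nodata)
    for row in vals:
        out.append(" ".join(_fmt_number(v) for v in row))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# GeoJSON vectors
# ---------------------------------------------------------------------------


def read_vector(path: str | Path) -> VectorLayer:
    """Read a GeoJSON FeatureCollection of points and/or linestrings.

    Features carrying a ``class`` attribute are treated as roads and the
    value must be one of national / provincial / local.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    feats: list[Feature] = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Point, LineString)):
            raise FormatError(
                f"{path}: unsupported geometry type {geom.geom_type}; "
                "only Point and LineString are handled"
            )
        attrs = dict(feat.get("properties") or {})
        if "class" in attrs and attrs["class"] not in ROAD_CLASS_IDS:
            raise FormatError(
                f"{path}: unknown road class {attrs['class']!r}; "
                f"allowed values: {sorted(ROAD_CLASS_IDS)}"
            )
        feats.append(Feature(geometry=geom, attributes=attrs))
    return VectorLayer(features=feats)


def write_vector(layer: VectorLayer, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": f.attributes,
            }
            for f in layer.features
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Lookup tables
# ---------------------------------------------------------------------------


def read_lookup_csv(path: str | Path):
    """Read the 12-row travel-speed table (columns id, cover_class, kmh)."""
    from .travelcost import SpeedLookup

    path = Path(path)
    speeds: dict[int, float] = {}
    names: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "cover_class", "kmh"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            cid = int(row["id"])
            if cid in speeds:
                raise FormatError(f"{path}: duplicate class id {cid}")
            speeds[cid] = float(row["kmh"])
            names[cid] = row["cover_class"]
    return SpeedLookup(kmh=speeds, names=names)


def read_zone_csv(path: str | Path):
    """Read the travel-time zone table (columns class, min_minutes, max_minutes)."""
    from .travelcost import ZoneTable

    path = Path(path)
    rows: list[tuple[int, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"class", "min_minutes", "max_minutes"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            rows.append(
                (int(row["class"]), float(row["min_minutes"]), float(row["max_minutes"]))
            )
    return ZoneTable.from_rows(rows)


def default_speed_table():
    """The packaged 12-class travel-speed table (the toolkit's reference
    parameterisation: walking 1–3 km/h off-road, fordable streams 2 km/h,
    the top stream class impassable, roads 10–50 km/h)."""
    from importlib.resources import files

    return read_lookup_csv(files("accesskit") / "data" / "table1_speeds.csv")


def default_zone_table():
    """The packaged six-zone remoteness table (0–15 … 120+ minutes)."""
    from importlib.resources import files

    return read_zone_csv(files("accesskit") / "data" / "table2_zones.csv")


# ---------------------------------------------------------------------------
# Scenario YAML
# ---------------------------------------------------------------------------


def read_scenario_yaml(path: str | Path):
    """Read a scenario configuration; fields mirror ScenarioSpec one-to-one."""
    from .travelcost import ScenarioSpec

    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: scenario file must be a mapping")
    return ScenarioSpec.from_dict(doc)
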