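"""Geometry plumbing shared by every pipeline stage.

Coordinates are abstract Cartesian metres (a synthetic projected plane);
areas are therefore plain ``geometry.area`` values in m².  No geodesy is
performed anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely import wkt as _wkt
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

VALID_STRATA = ("weekday", "weekend")
VALID_WINDOWS = tuple(range(0, 24, 2))
LAND_TYPES = ("Conservation Area", "Natural Area", "Reserve Area", "Other")

#: Tile CSV column order (WKT geometry keeps the deliverable plain text).
TILE_COLUMNS = (
    "cell_id",
    "wkt_geometry",
    "month",
    "day_stratum",
    "window_start_hour",
    "activity_index",
)


@dataclass
class ActivityCell:
    """One anonymized grid-cell record for a (month, stratum, window) slot.

    ``activity_index`` is strictly positive: sub-threshold records are
    absent from the data, never zero-valued.  ``clipped_geometry`` is
    populated by :func:`clip_cells` and is always contained in
    ``geometry``.
    """

    cell_id: str
    geometry: BaseGeometry
    activity_index: float
    month: str
    day_stratum: str
    window_start_hour: int
    clipped_geometry: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if not self.activity_index > 0:
            raise ValueError(
                f"activity_index must be > 0, got {self.activity_index!r} "
                f"(absent records encode sub-threshold activity)"
            )
        if self.day_stratum not in VALID_STRATA:
            raise ValueError(f"day_stratum must be one of {VALID_STRATA}")
        if self.window_start_hour not in VALID_WINDOWS:
            raise ValueError(
                f"window_start_hour must be an even hour in [0, 22], "
                f"got {self.window_start_hour}"
            )


@dataclass
class GreenSpace:
    """A managed property polygon."""

    id: str
    name: str
    geometry: BaseGeometry
    land_type: str = "Other"
    managed: bool = False

    def __post_init__(self) -> None:
        if self.land_type not in LAND_TYPES:
            raise ValueError(f"land_type must be one of {LAND_TYPES}")
        if not self.geometry.area > 0:
            raise ValueError(f"green space {self.id!r} has zero area")

    @property
    def area(self) -> float:
        """Polygon area in m² (always recomputed from the geometry)."""
        return self.geometry.area


@dataclass
class LandCoverUnit:
    """One land-classification polygon inside a property."""

    property_id: str
    geometry: BaseGeometry
    elc_cc: str


def clip_cells(
    cells: Iterable[ActivityCell],
    space: GreenSpace,
    *,
    repair: bool = False,
) -> list[ActivityCell]:
    """Clip activity cells to a property polygon.

    Returns only the cells with a positive-area intersection, each with
    ``clipped_geometry`` set; the activity index is left untouched (the
    index describes the whole 100 m cell even when the overlap is a
    sliver).  Boundary touching (zero-area intersection) counts as
    non-intersecting because downstream metrics weight by area.

    Invalid (self-intersecting) inputs are repaired with a zero buffer
    when ``repair`` is true and rejected otherwise.
    """
    target = space.geometry
    if not target.is_valid:
        if repair:
            target = target.buffer(0)
        else:
            raise ValueError(f"green space {space.id!r} geometry is invalid")
    tminx, tminy, tmaxx, tmaxy = target.bounds
    # Records share cell geometries across time slots, so intersections
    # are cached per distinct (cell_id, bounds); a bounding-box test
    # rejects far-away cells before any real geometry work.
    cache: dict[tuple, tuple] = {}
    out: list[ActivityCell] = []
    for cell in cells:
        geom = cell.geometry
        b = geom.bounds
        if b[0] >= tmaxx or b[2] <= tminx or b[1] >= tmaxy or b[3] <= tminy:
            continue
        key = (cell.cell_id, b)
        hit = cache.get(key)
        if hit is None:
            if not geom.is_valid:
                if repair:
                    geom = geom.buffer(0)
                else:
                    raise ValueError(f"cell {cell.cell_id!r} geometry is invalid")
            inter = geom.intersection(target)
            hit = (geom, inter if (not inter.is_empty and inter.area > 0) else None)
            cache[key] = hit
        geom, inter = hit
        if inter is None:
            continue
        out.append(dataclasses.replace(cell, geometry=geom, clipped_geometry=inter))
    return out


def union_area(polygons: Sequence[BaseGeometry]) -> float:
    """Area of the geometric union of ``polygons`` (0 for an empty list).

    Never exceeds the sum of the individual areas; overlapping regions
    are counted once.
    """
    polys = [p for p in polygons if p is not None and not p.is_empty]
    if not polys:
        return 0.0
    return unary_union(polys).area


def intersects_trail(
    cell: ActivityCell,
    trails: Sequence[BaseGeometry],
    buffer_m: float = 0.0,
) -> bool:
    """True iff the cell's (clipped) geometry meets any buffered trail.

    ``buffer_m`` = 0 uses the raw polylines.  An empty trail set is
    always false.
    """
    if buffer_m < 0:
        raise ValueError("buffer_m must be nonnegative")
    geom = cell.clipped_geometry if cell.clipped_geometry is not None else cell.geometry
    for trail in trails:
        target = trail.buffer(buffer_m) if buffer_m > 0 else trail
        if geom.intersects(target):
            return True
    return False


# ---------------------------------------------------------------------------
# I/O: GeoJSON layers and the tile CSV
# ---------------------------------------------------------------------------


def write_geojson(path: str | Path, records: Iterable[tuple[BaseGeometry, dict]]) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in records
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


def read_geojson(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return [
        (shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in payload["features"]
    ]


def write_green_spaces(path: str | Path, spaces: Iterable[GreenSpace]) -> None:
    write_geojson(
        path,
        (
            (
                s.geometry,
                {
                    "id": s.id,
                    "name": s.name,
                    "land_type": s.land_type,
                    "managed": s.managed,
                },
            )
            for s in spaces
        ),
    )


def read_green_spaces(path: str | Path) -> list[GreenSpace]:
    return [
        GreenSpace(
            id=str(props["id"]),
            name=str(props.get("name", props["id"])),
            geometry=geom,
            land_type=props.get("land_type", "Other"),
            managed=bool(props.get("managed", False)),
        )
        for geom, props in read_geojson(path)
    ]


def write_trails(path: str | Path, trails: dict[str, list[BaseGeometry]]) -> None:
    records = []
    for property_id in sorted(trails):
        for geom in trails[property_id]:
            records.append((geom, {"property_id": property_id}))
    write_geojson(path, records)


def read_trails(path: str | Path) -> dict[str, list[BaseGeometry]]:
    out: dict[str, list[BaseGeometry]] = {}
    for geom, props in read_geojson(path):
        out.setdefault(str(props["property_id"]), []).append(geom)
    return out


def write_land_cover(path: str | Path, units: Iterable[LandCoverUnit]) -> None:
    write_geojson(
        path,
        (
            (u.geometry, {"property_id": u.property_id, "elc_cc": u.elc_cc})
            for u in units
        ),
    )


def read_land_cover(path: str | Path) -> list[LandCoverUnit]:
    return [
        LandCoverUnit(
            property_id=str(props["property_id"]),
            geometry=geom,
            elc_cc=str(props["elc_cc"]),
        )
        for geom, props in read_geojson(path)
    ]


def cells_to_frame(cells: Iterable[ActivityCell]) -> pd.DataFrame:
    rows = [
        (
            c.cell_id,
            _wkt.dumps(c.geometry, rounding_precision=-1),
            c.month,
            c.day_stratum,
            c.window_start_hour,
            c.activity_index,
        )
        for c in cells
    ]
    return pd.DataFrame(rows, columns=list(TILE_COLUMNS))


def write_tiles(path: str | Path, cells: Iterable[ActivityCell]) -> None:
    cells_to_frame(cells).to_csv(path, index=False)


def read_tiles(path: str | Path) -> list[ActivityCell]:
    df = pd.read_csv(path, dtype={"cell_id": str, "month": str})
    missing = set(TILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tile CSV missing columns {sorted(missing)}")
    return [
        ActivityCell(
            cell_id=row.cell_id,
            geometry=_wkt.loads(row.wkt_geometry),
            activity_index=float(row.activity_index),
            month=row.month,
            day_stratum=row.day_stratum,
            window_start_hour=int(row.window_start_hour),
        )
        for row in df.itertuples()
    ]
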