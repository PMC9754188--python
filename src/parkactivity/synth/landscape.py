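"""Synthetic landscape generation.

Properties are axis-aligned rectangles laid out along the x-axis with a
road corridor between them, each partitioned into vertical land-cover
strips and threaded with random interior trails.  Roads run along every
property boundary, reproducing the contamination mode where boundary
cells pick up through-traffic.  Everything lives on an abstract
projected plane in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon, box

from ..geo import LAND_TYPES, GreenSpace, LandCoverUnit

DEFAULT_ELC_CLASSES = ("forest", "cultural", "talus", "cliff", "marsh", "open water")


@dataclass
class LandscapeConfig:
    n_properties: int = 5
    property_width_range: tuple[float, float] = (600.0, 1200.0)
    property_height_range: tuple[float, float] = (600.0, 1200.0)
    cell_size: float = 100.0
    gap: float = 300.0  # road corridor between adjacent properties
    trails_per_property: tuple[int, int] = (0, 3)
    trail_vertices: tuple[int, int] = (2, 5)
    elc_classes: tuple[str, ...] = DEFAULT_ELC_CLASSES
    classes_per_property: tuple[int, int] = (1, 4)

    def validate(self) -> None:
        if self.n_properties < 1:
            raise ValueError("n_properties must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        for name, (lo, hi) in (
            ("property_width_range", self.property_width_range),
            ("property_height_range", self.property_height_range),
        ):
            if lo > hi:
                raise ValueError(f"{name} is inverted: {lo} > {hi}")
            if lo < self.cell_size:
                raise ValueError(
                    f"infeasible config: {name} minimum {lo} m is smaller "
                    f"than one grid cell ({self.cell_size} m)"
                )
        if self.trails_per_property[0] < 0:
            raise ValueError("trails_per_property must be nonnegative")
        if self.trail_vertices[0] < 2:
            raise ValueError("a trail needs at least 2 vertices")
        lo, hi = self.classes_per_property
        if lo < 1 or hi > len(self.elc_classes):
            raise ValueError(
                "classes_per_property must fit within the class palette"
            )


@dataclass
class SyntheticLandscape:
    green_spaces: list[GreenSpace]
    trails: dict[str, list[LineString]]
    roads: list[LineString]
    land_cover: list[LandCoverUnit]
    grid: dict[str, Polygon]  # cell_id -> cell polygon
    cell_size: float

    def property_by_id(self, property_id: str) -> GreenSpace:
        for space in self.green_spaces:
            if space.id == property_id:
                return space
        raise KeyError(property_id)


def generate_landscape(config: LandscapeConfig, seed: int) -> SyntheticLandscape:
    """Deterministically generate a landscape from ``config`` and ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)

    spaces: list[GreenSpace] = []
    trails: dict[str, list[LineString]] = {}
    roads: list[LineString] = []
    cover: list[LandCoverUnit] = []

    x_cursor = 0.0
    for i in range(config.n_properties):
        width = float(rng.uniform(*config.property_width_range))
        height = float(rng.uniform(*config.property_height_range))
        pid = f"gs{i:03d}"
        poly = box(x_cursor, 0.0, x_cursor + width, height)
        space = GreenSpace(
            id=pid,
            name=f"Synthetic Green Space {i}",
            geometry=poly,
            land_type=LAND_TYPES[i % len(LAND_TYPES)],
            managed=(i % len(LAND_TYPES) == 0),
        )
        spaces.append(space)
        roads.append(LineString(poly.exterior.coords))
        cover.extend(_partition_cover(pid, poly, config, rng))
        trails[pid] = _make_trails(poly, config, rng)
        x_cursor += width + config.gap

    grid = _make_grid(spaces, config.cell_size)
    return SyntheticLandscape(
        green_spaces=spaces,
        trails=trails,
        roads=roads,
        land_cover=cover,
        grid=grid,
        cell_size=config.cell_size,
    )


def _partition_cover(
    pid: str, poly: Polygon, config: LandscapeConfig, rng: np.random.Generator
) -> list[LandCoverUnit]:
    """Split the rectangle into vertical strips, one class per strip.

    The strips share exact breakpoint coordinates, so they are pairwise
    non-overlapping and their union equals the property polygon.
    """
    lo, hi = config.classes_per_property
    k = int(rng.integers(lo, hi + 1))
    classes = rng.choice(config.elc_classes, size=k, replace=False)
    minx, miny, maxx, maxy = poly.bounds
    fractions = rng.dirichlet(np.ones(k))
    cuts = minx + np.concatenate([[0.0], np.cumsum(fractions)]) * (maxx - minx)
    cuts[-1] = maxx  # close the partition exactly
    units = []
    for j in range(k):
        strip = box(cuts[j], miny, cuts[j + 1], maxy)
        units.append(LandCoverUnit(property_id=pid, geometry=strip, elc_cc=str(classes[j])))
    return units


def _make_trails(
    poly: Polygon, config: LandscapeConfig, rng: np.random.Generator
) -> list[LineString]:
    # Vertices are drawn inside an inset rectangle; the property is
    # convex so the polyline is guaranteed to stay within it.
    minx, miny, maxx, maxy = poly.bounds
    margin = 0.05 * min(maxx - minx, maxy - miny)
    lo, hi = config.trails_per_property
    n_trails = int(rng.integers(lo, hi + 1))
    out = []
    for _ in range(n_trails):
        n_vert = int(rng.integers(config.trail_vertices[0], config.trail_vertices[1] + 1))
        xs = rng.uniform(minx + margin, maxx - margin, size=n_vert)
        ys = rng.uniform(miny + margin, maxy - margin, size=n_vert)
        out.append(LineString(np.column_stack([xs, ys])))
    return out


def _make_grid(spaces: list[GreenSpace], cell_size: float) -> dict[str, Polygon]:
    """Axis-aligned square cells tiling the bounding region plus a 1-cell margin."""
    minx = min(s.geometry.bounds[0] for s in spaces)
    miny = min(s.geometry.bounds[1] for s in spaces)
    maxx = max(s.geometry.bounds[2] for s in spaces)
    maxy = max(s.geometry.bounds[3] for s in spaces)
    ix0 = int(np.floor(minx / cell_size)) - 1
    iy0 = int(np.floor(miny / cell_size)) - 1
    ix1 = int(np.ceil(maxx / cell_size)) + 1
    iy1 = int(np.ceil(maxy / cell_size)) + 1
    grid: dict[str, Polygon] = {}
    for ix in range(ix0, ix1):
        for iy in range(iy0, iy1):
            cid = f"c{ix:+04d}_{iy:+04d}"
            grid[cid] = box(
                ix * cell_size, iy * cell_size, (ix + 1) * cell_size, (iy + 1) * cell_size
            )
    return grid
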