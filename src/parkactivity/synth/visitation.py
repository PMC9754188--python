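"""Ground-truth visitation surfaces.

The simulator produces an expected device-presence intensity for every
(cell, month, stratum, window) slot plus daily true visitor counts per
property.  The intensity of a property cell in a daytime window is

    baseline * trail_mult(if the cell meets a trail) * class_mult * stratum_mult

and road cells additionally carry a constant road term in every window,
so road cells show overnight activity while property interiors are
silent between 00:00 and 06:00 — the contamination signature the
downstream filter keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from ..geo import VALID_WINDOWS
from .landscape import SyntheticLandscape

NIGHT_WINDOWS = (0, 2, 4)
DAY_WINDOWS = tuple(w for w in VALID_WINDOWS if w not in NIGHT_WINDOWS)

#: Fixed synthetic calendar: 22 weekdays then 8 weekend days per month.
WEEKDAYS_PER_MONTH = 22
WEEKEND_DAYS_PER_MONTH = 8
DAYS_PER_MONTH = WEEKDAYS_PER_MONTH + WEEKEND_DAYS_PER_MONTH

DEFAULT_MONTHS = ("2020-06", "2020-07", "2020-08")


@dataclass
class VisitationParams:
    baseline: float = 1.0
    trail_multiplier: float = 1.0
    class_multipliers: dict[str, float] = field(default_factory=dict)
    weekend_multiplier: float = 1.0
    road_night_intensity: float = 0.0
    daily_visitor_rate: float = 0.0  # Poisson mean per unit stratum intensity
    months: tuple[str, ...] = DEFAULT_MONTHS

    def validate(self) -> None:
        values = [
            self.baseline,
            self.trail_multiplier,
            self.weekend_multiplier,
            self.road_night_intensity,
            self.daily_visitor_rate,
            *self.class_multipliers.values(),
        ]
        if any(v < 0 for v in values):
            raise ValueError("intensity parameters and multipliers must be nonnegative")
        if not self.months:
            raise ValueError("at least one month is required")


@dataclass
class VisitationTruth:
    intensity: pd.DataFrame  # cell_id, month, day_stratum, window_start_hour, intensity
    road_cells: frozenset[str]
    cell_geometry: dict[str, Polygon]
    cell_property: dict[str, str]  # cell_id -> dominant property id
    property_activity: dict[str, float]  # base (road-free) intensity total
    stratum_activity: dict[tuple[str, str], float]  # (property, stratum) totals
    daily_visitors: pd.DataFrame  # property_id, date, day_stratum, visitors
    months: tuple[str, ...]


def day_stratum_of(day_of_month: int) -> str:
    """Stratum for the fixed 22-weekday/8-weekend synthetic calendar."""
    if not 1 <= day_of_month <= DAYS_PER_MONTH:
        raise ValueError(f"day_of_month must be in [1, {DAYS_PER_MONTH}]")
    return "weekday" if day_of_month <= WEEKDAYS_PER_MONTH else "weekend"


def simulate_visitation(
    landscape: SyntheticLandscape, params: VisitationParams, seed: int
) -> VisitationTruth:
    params.validate()
    rng = np.random.default_rng(seed)

    cell_property: dict[str, str] = {}
    cell_class: dict[str, str] = {}
    cell_on_trail: dict[str, bool] = {}
    road_cells: set[str] = set()

    def _bbox_hits(cell: Polygon, geoms) -> list:
        cminx, cminy, cmaxx, cmaxy = cell.bounds
        out = []
        for g in geoms:
            b = g.bounds
            if not (b[0] > cmaxx or b[2] < cminx or b[1] > cmaxy or b[3] < cminy):
                out.append(g)
        return out

    cover_by_pid: dict[str, list] = {}
    for unit in landscape.land_cover:
        cover_by_pid.setdefault(unit.property_id, []).append(unit)

    for cid in sorted(landscape.grid):
        cell = landscape.grid[cid]
        if any(cell.intersects(road) for road in _bbox_hits(cell, landscape.roads)):
            road_cells.add(cid)
        best_pid, best_area = None, 0.0
        for space in landscape.green_spaces:
            if not _bbox_hits(cell, [space.geometry]):
                continue
            overlap = cell.intersection(space.geometry).area
            if overlap > best_area:
                best_pid, best_area = space.id, overlap
        if best_pid is None:
            continue
        cell_property[cid] = best_pid
        cell_on_trail[cid] = any(
            cell.intersects(t)
            for t in _bbox_hits(cell, landscape.trails.get(best_pid, []))
        )
        best_cls, best_cls_area = None, 0.0
        for unit in cover_by_pid.get(best_pid, []):
            if not _bbox_hits(cell, [unit.geometry]):
                continue
            overlap = cell.intersection(unit.geometry).area
            if overlap > best_cls_area:
                best_cls, best_cls_area = unit.elc_cc, overlap
        cell_class[cid] = best_cls if best_cls is not None else "forest"

    rows = []
    property_activity: dict[str, float] = {s.id: 0.0 for s in landscape.green_spaces}
    stratum_activity: dict[tuple[str, str], float] = {
        (s.id, st): 0.0 for s in landscape.green_spaces for st in ("weekday", "weekend")
    }
    all_cells = sorted(set(cell_property) | road_cells)
    for cid in all_cells:
        pid = cell_property.get(cid)
        base = 0.0
        if pid is not None:
            base = params.baseline
            if cell_on_trail.get(cid, False):
                base *= params.trail_multiplier
            base *= params.class_multipliers.get(cell_class[cid], 1.0)
        for month in params.months:
            for stratum in ("weekday", "weekend"):
                stratum_mult = (
                    params.weekend_multiplier if stratum == "weekend" else 1.0
                )
                for window in VALID_WINDOWS:
                    value = 0.0
                    if window in DAY_WINDOWS and base > 0:
                        value = base * stratum_mult
                        property_activity[pid] += value
                        stratum_activity[(pid, stratum)] += value
                    if cid in road_cells:
                        value += params.road_night_intensity
                    if value > 0:
                        rows.append((cid, month, stratum, window, value))

    intensity = pd.DataFrame(
        rows,
        columns=["cell_id", "month", "day_stratum", "window_start_hour", "intensity"],
    )

    visitor_rows = []
    for space in landscape.green_spaces:
        for month in params.months:
            for day in range(1, DAYS_PER_MONTH + 1):
                stratum = day_stratum_of(day)
                mean = params.daily_visitor_rate * stratum_activity[(space.id, stratum)]
                count = int(rng.poisson(mean)) if mean > 0 else 0
                visitor_rows.append(
                    (space.id, f"{month}-{day:02d}", stratum, count)
                )
    daily_visitors = pd.DataFrame(
        visitor_rows, columns=["property_id", "date", "day_stratum", "visitors"]
    )

    geometry = {cid: landscape.grid[cid] for cid in all_cells}
    return VisitationTruth(
        intensity=intensity,
        road_cells=frozenset(road_cells),
        cell_geometry=geometry,
        cell_property=cell_property,
        property_activity=property_activity,
        stratum_activity=stratum_activity,
        daily_visitors=daily_visitors,
        months=tuple(params.months),
    )
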