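"""Per-property activity metrics.

The two core quantities are *activity density* — the area-weighted sum of
activity indices over retained clipped cells divided by property area —
and *activity coverage* — the percentage of a property's area covered by
cells showing any activity.  Density deliberately uses a sum rather than
a mean: the record count varies over time because sub-threshold records
are suppressed entirely, so a mean would be biased by suppression.

All metrics operate on cells that have already been clipped to the
property and passed through the overnight-contamination filter.
Undefined ratios are reported as NaN, never coerced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .geo import ActivityCell, GreenSpace, LandCoverUnit, intersects_trail, union_area

#: Two-hour windows whose start falls in 00:00–06:00 (half-open windows).
DEFAULT_NIGHT_WINDOWS = frozenset({0, 2, 4})


@dataclass
class ActivitySummary:
    property_id: str
    day_stratum: str  # "weekday", "weekend" or "all"
    activity_density: float
    activity_coverage_pct: float
    trail_density: float  # km of trail per km²; NaN when no trail layer given
    on_trail_pct: float  # NaN when no activity area or no trail layer
    n_cells_retained: int
    n_cells_excluded: int


@dataclass
class LandCoverUsage:
    property_id: str
    elc_cc: str
    prop_activity_by_class: float  # share of the activity area in this class
    prop_class_used: float  # share of this class touched by activity


def flag_overnight_cells(
    cells: Iterable[ActivityCell],
    night_windows: frozenset[int] | set[int] = DEFAULT_NIGHT_WINDOWS,
) -> set[str]:
    """Cell ids with ANY record in an overnight window.

    A flagged cell is excluded from all downstream metrics for all hours
    and months: overnight activity marks road/commercial contamination,
    not in-property visitation, and the contamination is a property of
    the cell, not of the single record.
    """
    night = frozenset(night_windows)
    return {c.cell_id for c in cells if c.window_start_hour in night}


def drop_flagged(
    cells: Iterable[ActivityCell], flagged: set[str]
) -> list[ActivityCell]:
    """Remove every record belonging to a flagged cell."""
    return [c for c in cells if c.cell_id not in flagged]


def _clipped(cell: ActivityCell) -> BaseGeometry:
    if cell.clipped_geometry is None:
        raise ValueError(f"cell {cell.cell_id!r} has not been clipped")
    return cell.clipped_geometry


def activity_density(cells: Sequence[ActivityCell], space: GreenSpace) -> float:
    """Area-weighted sum of activity indices divided by property area.

    The sum runs over every retained record (all windows and months of
    whichever strata the caller passed in).  An empty record list yields
    0: absence means activity below the anonymization threshold.
    """
    total = 0.0
    for cell in cells:
        total += cell.activity_index * _clipped(cell).area
    return total / space.area


def activity_coverage(cells: Sequence[ActivityCell], space: GreenSpace) -> float:
    """Percent of the property covered by cells with at least one record.

    Each distinct cell counts once regardless of how many records it
    has; overlaps between clipped geometries are not double counted.
    """
    geoms = _distinct_cell_geoms(cells)
    return 100.0 * union_area(list(geoms.values())) / space.area


def trail_density(trails: Sequence[BaseGeometry], space: GreenSpace) -> float:
    """Total trail length inside the property per unit area, in km/km².

    Trails are clipped to the property polygon before measuring.  The
    units are a reporting convention: 1 km of trail in 1 km² -> 1.0.
    """
    length_m = 0.0
    for trail in trails:
        length_m += trail.intersection(space.geometry).length
    # m/m² -> km/km² multiplies by 1000
    return 1000.0 * length_m / space.area


def on_trail_activity_pct(
    cells: Sequence[ActivityCell],
    trails: Sequence[BaseGeometry],
    buffer_m: float = 0.0,
) -> float:
    """Share of the activity-bearing area that intersects the trail network.

    Returns NaN when there is no activity area at all (the ratio is
    undefined, and 0 would wrongly claim "all activity is off trail").
    """
    geoms = _distinct_cell_geoms(cells)
    total_area = union_area(list(geoms.values()))
    if total_area <= 0:
        return math.nan
    by_id = {}
    for cell in cells:
        if cell.cell_id in by_id:
            continue
        by_id[cell.cell_id] = cell
    on_trail = [
        _clipped(c) for c in by_id.values() if intersects_trail(c, trails, buffer_m)
    ]
    return 100.0 * union_area(on_trail) / total_area


def landcover_usage(
    cells: Sequence[ActivityCell],
    cover: Sequence[LandCoverUnit],
    space: GreenSpace,
) -> list[LandCoverUsage]:
    """Apportion the activity area over land-classification classes.

    ``prop_activity_by_class`` divides the activity area in each class
    by the total activity area (sums to 1 over a partitioning cover);
    ``prop_class_used`` divides it by the total area of that class.
    Classes with zero area get NaN for ``prop_class_used``; with zero
    total activity both fractions are NaN.
    """
    geoms = _distinct_cell_geoms(cells)
    activity_geom = unary_union(list(geoms.values())) if geoms else None
    total_activity = activity_geom.area if activity_geom is not None else 0.0

    by_class: dict[str, list[BaseGeometry]] = {}
    for unit in cover:
        if unit.property_id != space.id:
            continue
        by_class.setdefault(unit.elc_cc, []).append(unit.geometry)

    out: list[LandCoverUsage] = []
    for elc_cc in sorted(by_class):
        class_geom = unary_union(by_class[elc_cc])
        class_area = class_geom.area
        if activity_geom is None or total_activity <= 0:
            used_area = 0.0
            frac_activity = math.nan
        else:
            used_area = activity_geom.intersection(class_geom).area
            frac_activity = used_area / total_activity
        frac_used = used_area / class_area if class_area > 0 else math.nan
        out.append(
            LandCoverUsage(
                property_id=space.id,
                elc_cc=elc_cc,
                prop_activity_by_class=frac_activity,
                prop_class_used=frac_used,
            )
        )
    return out


def summarize_property(
    cells: Sequence[ActivityCell],
    space: GreenSpace,
    trails: Sequence[BaseGeometry] | None = None,
    *,
    night_windows: frozenset[int] | set[int] = DEFAULT_NIGHT_WINDOWS,
    stratum: str = "all",
    trail_buffer_m: float = 0.0,
) -> ActivitySummary:
    """Filter, select the stratum, and compute the full metric set.

    ``cells`` must already be clipped to ``space``.  The overnight flag
    is computed from ALL records of the property's cells (both strata,
    every window) before the stratum filter, so a road-contaminated
    cell is excluded from weekday and weekend metrics alike.
    """
    if stratum not in ("weekday", "weekend", "all"):
        raise ValueError("stratum must be 'weekday', 'weekend' or 'all'")
    flagged = flag_overnight_cells(cells, night_windows)
    retained = drop_flagged(cells, flagged)
    if stratum != "all":
        retained = [c for c in retained if c.day_stratum == stratum]
    density = activity_density(retained, space)
    coverage = activity_coverage(retained, space)
    if trails is None:
        t_density = math.nan
        on_trail = math.nan
    else:
        t_density = trail_density(trails, space)
        on_trail = on_trail_activity_pct(retained, trails, trail_buffer_m)
    all_ids = {c.cell_id for c in cells}
    return ActivitySummary(
        property_id=space.id,
        day_stratum=stratum,
        activity_density=density,
        activity_coverage_pct=coverage,
        trail_density=t_density,
        on_trail_pct=on_trail,
        n_cells_retained=len(all_ids - flagged),
        n_cells_excluded=len(all_ids & flagged),
    )


def _distinct_cell_geoms(cells: Sequence[ActivityCell]) -> dict[str, BaseGeometry]:
    geoms: dict[str, BaseGeometry] = {}
    for cell in cells:
        geoms.setdefault(cell.cell_id, _clipped(cell))
    return geoms
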