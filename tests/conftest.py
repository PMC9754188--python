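import numpy as np
import pytest
from shapely.geometry import box

from parkactivity.geo import ActivityCell, GreenSpace
from parkactivity.synth import (
    AnonymizationParams,
    LandscapeConfig,
    VisitationParams,
    generate_landscape,
    render_activity_tiles,
    simulate_visitation,
)


def make_cell(cell_id="c0", bounds=(0, 0, 100, 100), index=1.0, month="2020-06",
              stratum="weekday", window=12, clipped=None):
    return ActivityCell(
        cell_id=cell_id,
        geometry=box(*bounds),
        activity_index=index,
        month=month,
        day_stratum=stratum,
        window_start_hour=window,
        clipped_geometry=clipped,
    )


def rect_overlap_area(a, b):
    """Analytic axis-aligned rectangle intersection area (test oracle)."""
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(w, 0.0) * max(h, 0.0)


@pytest.fixture
def small_landscape():
    cfg = LandscapeConfig(
        n_properties=3,
        property_width_range=(500, 800),
        property_height_range=(500, 800),
        trails_per_property=(0, 3),
        classes_per_property=(1, 3),
    )
    return generate_landscape(cfg, seed=42)


@pytest.fixture
def small_truth(small_landscape):
    params = VisitationParams(
        trail_multiplier=3.0,
        weekend_multiplier=2.0,
        road_night_intensity=0.6,
        daily_visitor_rate=0.005,
        class_multipliers={"forest": 1.5, "cultural": 2.0, "marsh": 0.5},
    )
    return simulate_visitation(small_landscape, params, seed=43)


@pytest.fixture
def small_tiles(small_truth):
    return render_activity_tiles(small_truth, AnonymizationParams())
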