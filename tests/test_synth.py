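import numpy as np
import pandas as pd
import pytest
from shapely import wkt

from parkactivity import stats
from parkactivity.synth import (
    AnonymizationParams,
    LandscapeConfig,
    SpeciesResponse,
    VisitationParams,
    day_stratum_of,
    generate_landscape,
    generate_reservations,
    generate_tree_surveys,
    render_activity_tiles,
    simulate_visitation,
    standardized_property_activity,
)
from parkactivity.synth.visitation import DAY_WINDOWS, NIGHT_WINDOWS


class TestGenerateLandscape:
    def test_single_property_single_class(self):
        cfg = LandscapeConfig(
            n_properties=1,
            property_width_range=(1000, 1000),
            property_height_range=(1000, 1000),
            trails_per_property=(0, 0),
            classes_per_property=(1, 1),
        )
        ls = generate_landscape(cfg, seed=0)
        assert len(ls.green_spaces) == 1
        assert ls.green_spaces[0].area == pytest.approx(1_000_000)
        units = [u for u in ls.land_cover if u.property_id == ls.green_spaces[0].id]
        assert len(units) == 1
        assert units[0].geometry.equals(ls.green_spaces[0].geometry)
        assert ls.trails[ls.green_spaces[0].id] == []

    def test_determinism(self):
        cfg = LandscapeConfig(n_properties=3)
        a = generate_landscape(cfg, seed=7)
        b = generate_landscape(cfg, seed=7)
        for sa, sb in zip(a.green_spaces, b.green_spaces):
            assert sa.geometry.equals_exact(sb.geometry, 0)
        for pid in a.trails:
            for ta, tb in zip(a.trails[pid], b.trails[pid]):
                assert ta.equals_exact(tb, 0)
        assert [u.geometry.wkt for u in a.land_cover] == [
            u.geometry.wkt for u in b.land_cover
        ]

    def test_cover_partition_area_oracle(self):
        # Independent area summation from strip bounds, not shapely union.
        ls = generate_landscape(LandscapeConfig(n_properties=5), seed=3)
        for space in ls.green_spaces:
            units = [u for u in ls.land_cover if u.property_id == space.id]
            total = 0.0
            for u in units:
                x0, y0, x1, y1 = u.geometry.bounds
                total += (x1 - x0) * (y1 - y0)
            assert total == pytest.approx(space.area, rel=1e-9)
            # strips are pairwise disjoint in interior
            for i in range(len(units)):
                for j in range(i + 1, len(units)):
                    inter = units[i].geometry.intersection(units[j].geometry)
                    assert inter.area == pytest.approx(0.0, abs=1e-6)

    def test_trails_within_property(self):
        ls = generate_landscape(
            LandscapeConfig(n_properties=4, trails_per_property=(2, 4)), seed=8
        )
        for space in ls.green_spaces:
            for trail in ls.trails[space.id]:
                assert trail.within(space.geometry)

    def test_grid_tiles_without_gaps_or_overlaps(self):
        ls = generate_landscape(LandscapeConfig(n_properties=2), seed=4)
        cells = list(ls.grid.values())
        total = sum(c.area for c in cells)
        minx = min(c.bounds[0] for c in cells)
        miny = min(c.bounds[1] for c in cells)
        maxx = max(c.bounds[2] for c in cells)
        maxy = max(c.bounds[3] for c in cells)
        assert total == pytest.approx((maxx - minx) * (maxy - miny), rel=1e-12)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="smaller than one grid cell"):
            LandscapeConfig(property_width_range=(50, 200)).validate()


class TestSimulateVisitation:
    def _flat_landscape(self, seed=0, n=2):
        cfg = LandscapeConfig(
            n_properties=n,
            property_width_range=(500, 700),
            property_height_range=(500, 700),
            trails_per_property=(1, 2),
            classes_per_property=(1, 2),
        )
        return generate_landscape(cfg, seed=seed)

    def test_identity_parameters_give_baseline_everywhere(self):
        ls = self._flat_landscape()
        truth = simulate_visitation(ls, VisitationParams(baseline=2.5), seed=1)
        df = truth.intensity
        non_road = df[~df.cell_id.isin(truth.road_cells)]
        assert (non_road.window_start_hour >= 6).all()
        assert np.allclose(non_road.intensity, 2.5)

    def test_weekend_ratio_forced_by_construction(self):
        ls = self._flat_landscape(seed=2)
        truth = simulate_visitation(
            ls, VisitationParams(weekend_multiplier=2.0, trail_multiplier=3.0), seed=1
        )
        df = truth.intensity[~truth.intensity.cell_id.isin(truth.road_cells)]
        wide = df.pivot_table(
            index=["cell_id", "month", "window_start_hour"],
            columns="day_stratum",
            values="intensity",
        )
        assert np.allclose(wide["weekend"] / wide["weekday"], 2.0)

    def test_trail_multiplier_cell_by_cell(self):
        # Brute-force loop: every non-road daytime cell is baseline*3 if
        # it intersects a trail of its property, baseline otherwise.
        ls = self._flat_landscape(seed=5)
        b = 1.7
        truth = simulate_visitation(
            ls, VisitationParams(baseline=b, trail_multiplier=3.0), seed=1
        )
        df = truth.intensity[~truth.intensity.cell_id.isin(truth.road_cells)]
        per_cell = df.groupby("cell_id").intensity.first()
        for cid, value in per_cell.items():
            pid = truth.cell_property[cid]
            on_trail = any(
                truth.cell_geometry[cid].intersects(t) for t in ls.trails[pid]
            )
            assert value == pytest.approx(b * 3.0 if on_trail else b)

    def test_night_window_invariants(self):
        ls = self._flat_landscape(seed=6)
        truth = simulate_visitation(
            ls, VisitationParams(road_night_intensity=0.5), seed=1
        )
        df = truth.intensity
        night = df[df.window_start_hour.isin(NIGHT_WINDOWS)]
        assert set(night.cell_id) <= set(truth.road_cells)
        for cid in sorted(truth.road_cells)[:5]:
            sub = night[night.cell_id == cid]
            assert (sub.intensity > 0).all() and len(sub) > 0

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            VisitationParams(trail_multiplier=-1.0).validate()

    def test_intensity_nonnegative(self, small_truth):
        assert (small_truth.intensity.intensity >= 0).all()

    def test_day_stratum_calendar(self):
        assert day_stratum_of(1) == "weekday"
        assert day_stratum_of(22) == "weekday"
        assert day_stratum_of(23) == "weekend"
        assert day_stratum_of(30) == "weekend"
        with pytest.raises(ValueError):
            day_stratum_of(31)


class TestRenderTiles:
    def test_identity_anonymization(self, small_truth):
        tiles = render_activity_tiles(small_truth, AnonymizationParams())
        positive = (small_truth.intensity.intensity > 0).sum()
        assert len(tiles) == positive
        by_key = {
            (t.cell_id, t.month, t.day_stratum, t.window_start_hour): t.activity_index
            for t in tiles
        }
        for row in small_truth.intensity.itertuples():
            key = (row.cell_id, row.month, row.day_stratum, int(row.window_start_hour))
            assert by_key[key] == pytest.approx(row.intensity)

    def test_total_suppression(self, small_truth):
        tau = small_truth.intensity.intensity.max() * 1.01
        assert render_activity_tiles(
            small_truth, AnonymizationParams(threshold=tau)
        ) == []

    def test_threshold_count_matches_brute_force(self, small_truth):
        tau = float(small_truth.intensity.intensity.median())
        tiles = render_activity_tiles(small_truth, AnonymizationParams(threshold=tau))
        expected = int((small_truth.intensity.intensity >= tau).sum())
        assert len(tiles) == expected

    def test_suppression_monotone_in_threshold(self, small_truth):
        grid = np.quantile(small_truth.intensity.intensity, [0, 0.2, 0.5, 0.8, 1.0])
        counts = [
            len(render_activity_tiles(small_truth, AnonymizationParams(threshold=t)))
            for t in grid
        ]
        assert counts == sorted(counts, reverse=True)

    def test_normalization_baseline_scales_index(self, small_truth):
        tiles = render_activity_tiles(
            small_truth, AnonymizationParams(normalization_baseline=4.0)
        )
        raw = render_activity_tiles(small_truth, AnonymizationParams())
        assert len(tiles) == len(raw)
        assert tiles[0].activity_index == pytest.approx(raw[0].activity_index / 4.0)

    def test_noise_deterministic_for_seed(self, small_truth):
        anon = AnonymizationParams(threshold=0.2, noise_sd=0.3, seed=99)
        a = render_activity_tiles(small_truth, anon)
        b = render_activity_tiles(small_truth, anon)
        assert [(t.cell_id, t.activity_index) for t in a] == [
            (t.cell_id, t.activity_index) for t in b
        ]

    def test_property_sum_proportional_to_truth(self, small_truth):
        # With anonymization disabled, summed tile activity per property
        # is proportional (1/baseline) to summed truth intensity.
        baseline = 3.0
        tiles = render_activity_tiles(
            small_truth, AnonymizationParams(normalization_baseline=baseline)
        )
        got = {}
        for t in tiles:
            pid = small_truth.cell_property.get(t.cell_id)
            if pid is not None:
                got[pid] = got.get(pid, 0.0) + t.activity_index
        truth_sum = (
            small_truth.intensity.assign(
                pid=small_truth.intensity.cell_id.map(small_truth.cell_property)
            )
            .dropna(subset=["pid"])
            .groupby("pid")
            .intensity.sum()
        )
        for pid, total in truth_sum.items():
            assert got[pid] == pytest.approx(total / baseline, rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AnonymizationParams(threshold=-1).validate()
        with pytest.raises(ValueError):
            AnonymizationParams(normalization_baseline=0).validate()


class TestReservations:
    def test_zero_visitors_empty_table(self, small_landscape):
        truth = simulate_visitation(
            small_landscape, VisitationParams(daily_visitor_rate=0.0), seed=1
        )
        assert generate_reservations(truth, seed=2).empty

    def test_determinism(self, small_truth):
        a = generate_reservations(small_truth, seed=5)
        b = generate_reservations(small_truth, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_daily_totals_match_truth(self, small_truth):
        # Independent group-and-sum oracle against the truth table.
        res = generate_reservations(small_truth, seed=5)
        got = res.groupby(["property_id", "date"]).party_size.sum()
        want = small_truth.daily_visitors.set_index(["property_id", "date"]).visitors
        want = want[want > 0]
        pd.testing.assert_series_equal(
            got.sort_index(), want.sort_index(), check_names=False
        )

    def test_checkin_hours_in_window(self, small_truth):
        res = generate_reservations(small_truth, seed=5)
        assert res.checkin_hour.between(9, 18).all()


class TestTreeSurveys:
    def test_zero_loadings_identical_composition(self, small_landscape, small_truth):
        eff = SpeciesResponse(loadings={"a": 0.0, "b": 0.0}, noise_sd=0.0)
        trees = generate_tree_surveys(small_landscape, small_truth, eff, seed=1)
        assert np.allclose(trees.to_numpy(), trees.to_numpy()[0])

    def test_positive_loading_monotone_in_activity_rank(
        self, small_landscape, small_truth
    ):
        eff = SpeciesResponse(loadings={"up": 0.9, "flat": 0.0}, noise_sd=0.0)
        trees = generate_tree_surveys(small_landscape, small_truth, eff, seed=1)
        activity = standardized_property_activity(small_truth)
        one_year = trees.xs(eff.years[0], level="year")
        sites = list(one_year.index)
        for i in range(len(sites)):
            for j in range(len(sites)):
                if activity[sites[i]] > activity[sites[j]]:
                    assert one_year.loc[sites[i], "up"] > one_year.loc[sites[j], "up"]

    def test_zero_year_loading_gives_no_year_signal(
        self, small_landscape, small_truth
    ):
        eff = SpeciesResponse(loadings={"a": 0.5, "b": -0.5}, noise_sd=0.0)
        trees = generate_tree_surveys(small_landscape, small_truth, eff, seed=1)
        result, _ = stats.cca_year_check(trees, n_perm=99, seed=0)
        assert result.constrained_inertia < 1e-10

    def test_too_few_species_rejected(self, small_landscape, small_truth):
        with pytest.raises(ValueError, match="2 species"):
            generate_tree_surveys(
                small_landscape, small_truth,
                SpeciesResponse(loadings={"only": 1.0}), seed=1,
            )

    def test_too_few_years_rejected(self, small_landscape, small_truth):
        with pytest.raises(ValueError, match="2 survey years"):
            generate_tree_surveys(
                small_landscape, small_truth,
                SpeciesResponse(loadings={"a": 1.0, "b": 0.0}, years=(2018,)), seed=1,
            )

    def test_too_few_sites_rejected(self):
        cfg = LandscapeConfig(n_properties=1)
        ls = generate_landscape(cfg, seed=1)
        truth = simulate_visitation(ls, VisitationParams(), seed=1)
        with pytest.raises(ValueError, match="2 sites"):
            generate_tree_surveys(
                ls, truth, SpeciesResponse(loadings={"a": 1.0, "b": 0.0}), seed=1
            )
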