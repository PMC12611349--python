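import numpy as np
import pandas as pd
import pytest

from ipcz.gap import (
    GearClassification,
    classify_and_aggregate,
    closed_season_stats,
    effort_hotspots,
    mpa_coverage,
    pressure_overlap,
)
from ipcz.hotspots import PriorityMask


def _effort(spec, rows):
    return pd.DataFrame(rows, columns=["lat", "lon", "year", "month", "gear", "hours"])


def _mask(spec, cells):
    mask = np.zeros(spec.n_cells, dtype=bool)
    mask[list(cells)] = True
    sites = np.zeros(spec.n_cells, dtype=int)
    sites[list(cells)] = 1
    return PriorityMask(mask=mask, sites=sites)


def _geojson(rects):
    feats = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                ],
            },
        }
        for x0, y0, x1, y1 in rects
    ]
    return {"type": "FeatureCollection", "features": feats}


class TestClassifyAndAggregate:
    def test_single_mollusk_record_totals(self, small_spec):
        eff = _effort(small_spec, [[0.5, 100.5, 2023, 1, "dredge_mollusk", 10.0]])
        monthly, grid, log = classify_and_aggregate(eff, spec=small_spec, focal_year=2023)
        assert grid.hours["mollusk"].sum() == 10.0
        assert monthly.loc[0, "effort_class"] == "mollusk"

    def test_unknown_gear_maps_to_ambiguous(self, small_spec):
        eff = _effort(small_spec, [[0.5, 100.5, 2023, 1, "mystery_gear", 5.0]])
        monthly, grid, _ = classify_and_aggregate(eff, spec=small_spec, focal_year=2023)
        assert grid.hours["ambiguous"].sum() == 5.0

    def test_monthly_class_shares(self, small_spec):
        eff = _effort(
            small_spec,
            [
                [0.5, 100.5, 2023, 3, "dredge_mollusk", 60.0],
                [0.5, 100.5, 2023, 3, "purse_seine", 40.0],
            ],
        )
        monthly, _, _ = classify_and_aggregate(eff, spec=small_spec, focal_year=2023)
        march = monthly[monthly["month"] == 3].set_index("effort_class")["hours"]
        shares = march / march.sum()
        assert shares["mollusk"] == pytest.approx(0.6)
        assert shares["non_mollusk"] == pytest.approx(0.4)

    def test_negative_hours_rejected_and_counted(self, small_spec):
        eff = _effort(
            small_spec,
            [
                [0.5, 100.5, 2023, 1, "dredge_mollusk", -3.0],
                [0.5, 100.5, 2023, 1, "dredge_mollusk", 7.0],
            ],
        )
        _, grid, log = classify_and_aggregate(eff, spec=small_spec, focal_year=2023)
        assert log["n_rejected_hours"] == 1
        assert grid.hours["mollusk"].sum() == 7.0

    def test_aggregation_is_row_order_invariant(self, small_spec, scenario):
        from ipcz.synthetic import generate_effort

        eff = generate_effort(scenario, small_spec)
        m1, g1, _ = classify_and_aggregate(eff, spec=small_spec, focal_year=2023)
        shuffled = eff.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2, g2, _ = classify_and_aggregate(shuffled, spec=small_spec, focal_year=2023)
        pd.testing.assert_frame_equal(g1.hours, g2.hours)

    def test_closed_season_toy_year(self, small_spec):
        """May-July mollusk hours of 20 against an annual 100 -> 0.2 of the
        year's mollusk effort falls in the closed season."""
        rows = []
        for month in range(1, 13):
            hours = 20 / 3 if 5 <= month <= 7 else 80 / 9
            rows.append([0.5, 100.5, 2023, month, "dredge_mollusk", hours])
        monthly, _, _ = classify_and_aggregate(
            _effort(small_spec, rows), spec=small_spec, focal_year=2023
        )
        stats = closed_season_stats(monthly)
        assert stats["mollusk_window_fraction"] == pytest.approx(0.2)


class TestClosedSeason:
    def _monthly(self, mollusk_by_month, non_by_month):
        rows = []
        for m in range(1, 13):
            rows.append({"year": 2023, "month": m, "effort_class": "mollusk", "hours": mollusk_by_month[m - 1]})
            rows.append({"year": 2023, "month": m, "effort_class": "non_mollusk", "hours": non_by_month[m - 1]})
        return pd.DataFrame(rows)

    def test_uniform_effort_gives_quarter_window_fraction(self):
        stats = closed_season_stats(self._monthly([10.0] * 12, [5.0] * 12))
        assert stats["mollusk_window_fraction"] == pytest.approx(3 / 12)
        assert stats["non_mollusk_window_fraction"] == pytest.approx(3 / 12)

    def test_all_effort_in_june_gives_unit_window_fraction(self):
        m = [0.0] * 12
        m[5] = 100.0
        stats = closed_season_stats(self._monthly(m, [0.0] * 12))
        assert stats["mollusk_window_fraction"] == 1.0

    def test_shares_match_direct_arithmetic_on_inverted_fixture(self):
        """A table built by inverting the share arithmetic (window share
        0.5406 of in-window effort, annual share 0.6649) recomputes to the
        same values."""
        window_total, annual_total = 1000.0, 4000.0
        w_m = 0.5406 * window_total
        a_m = 0.6649 * annual_total
        m = [(a_m - w_m) / 9] * 12
        n = [((annual_total - a_m) - (window_total - w_m)) / 9] * 12
        for i in (4, 5, 6):
            m[i] = w_m / 3
            n[i] = (window_total - w_m) / 3
        stats = closed_season_stats(self._monthly(m, n))
        assert stats["window_mollusk_share"] == pytest.approx(0.5406)
        assert stats["annual_mollusk_share"] == pytest.approx(0.6649)


class TestEffortHotspots:
    def test_top_quintile_of_ten_distinct_cells_has_two_members(self):
        hours = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        assert effort_hotspots(hours, q=0.80) == {8, 9}

    def test_all_equal_positive_cells_tie_into_the_set(self):
        hours = pd.Series([5.0] * 7)
        assert effort_hotspots(hours) == set(range(7))

    def test_single_positive_cell_is_the_hotspot(self):
        hours = pd.Series([0.0, 0.0, 3.0, 0.0])
        assert effort_hotspots(hours) == {2}

    def test_all_zero_grid_yields_empty_set(self):
        assert effort_hotspots(pd.Series([0.0, 0.0])) == set()

    def test_quantile_zero_returns_all_positive_cells(self):
        hours = pd.Series([0.0, 1.0, 2.0, 3.0])
        assert effort_hotspots(hours, q=0.0) == {1, 2, 3}

    def test_log_transform_never_changes_the_hotspot_set(self, scenario, spec):
        from ipcz.gap import classify_and_aggregate
        from ipcz.synthetic import generate_effort

        _, grid, _ = classify_and_aggregate(
            generate_effort(scenario, spec), spec=spec, focal_year=2023
        )
        raw = grid.annual_cell_totals("mollusk")
        assert effort_hotspots(raw) == effort_hotspots(np.log1p(raw))


class TestMpaCoverage:
    def test_mpa_covering_whole_box_gives_full_coverage(self, small_spec):
        mask = _mask(small_spec, {0, 7, 20})
        gj = _geojson([(100, 0, 105, 5)])
        area, binary, per_cell = mpa_coverage(mask, gj, small_spec)
        assert area == pytest.approx(1.0) and binary == 1.0

    def test_no_mpas_gives_zero(self, small_spec):
        area, binary, per_cell = mpa_coverage(_mask(small_spec, {3}), _geojson([]), small_spec)
        assert area == 0.0 and binary == 0.0

    def test_half_covered_single_priority_cell(self, small_spec):
        # cell (0, 0) spans lat 0-1, lon 100-101; MPA covers its west half
        mask = _mask(small_spec, {small_spec.cell_id(0, 0)})
        gj = _geojson([(100.0, 0.0, 100.5, 1.0)])
        area, binary, _ = mpa_coverage(mask, gj, small_spec)
        assert area == pytest.approx(0.5)
        assert binary == 1.0

    def test_coverage_monotone_in_added_polygons(self, small_spec):
        mask = _mask(small_spec, {0, 1, 2})
        one = _geojson([(100.0, 0.0, 101.0, 1.0)])
        two = _geojson([(100.0, 0.0, 101.0, 1.0), (101.0, 0.0, 102.5, 1.0)])
        a1, _, _ = mpa_coverage(mask, one, small_spec)
        a2, _, _ = mpa_coverage(mask, two, small_spec)
        assert a2 >= a1

    def test_invalid_geometry_fatal_with_index(self, small_spec):
        bowtie = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[100, 0], [101, 1], [101, 0], [100, 1], [100, 0]]
                        ],
                    },
                }
            ],
        }
        with pytest.raises(ValueError, match="index 0"):
            mpa_coverage(_mask(small_spec, {0}), bowtie, small_spec)


class TestPressureOverlap:
    def _report(self, small_spec, priority, covered, hotspots):
        per_cell = pd.Series({c: 1.0 if c in covered else 0.0 for c in priority})
        return pressure_overlap(
            _mask(small_spec, priority), per_cell, hotspots, seasonal={}, focal_year=2023
        )

    def test_disjoint_mpa_and_hotspots_have_empty_overlap(self, small_spec):
        rep = self._report(small_spec, {0, 1, 2}, covered={0}, hotspots={2})
        assert rep.overlap_cells == set()

    def test_identical_sets_overlap_fully(self, small_spec):
        rep = self._report(small_spec, {0, 1}, covered={0, 1}, hotspots={0, 1})
        assert rep.overlap_cells == {0, 1}

    def test_toy_layout_enumerated(self, small_spec):
        """5 priority cells, 2 MPA-covered, 1 of those an effort hotspot."""
        rep = self._report(small_spec, {0, 1, 2, 3, 4}, covered={1, 3}, hotspots={3, 10})
        assert rep.priority_covered_cells == {1, 3}
        assert rep.overlap_cells == {3}
        assert rep.mpa_coverage_fraction_binary == pytest.approx(0.4)


class TestGearClassification:
    def test_unknown_effort_class_in_mapping_rejected(self):
        with pytest.raises(ValueError):
            GearClassification({"trap": "shellfish"})

    def test_round_trip_through_frame(self):
        gc = GearClassification()
        again = GearClassification(dict(zip(gc.to_frame()["gear"], gc.to_frame()["effort_class"])))
        assert again.mapping == gc.mapping
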