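"""Surface-ratio population allocation, typology and person-hours."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from rfmap.exceptions import InvalidConfigError
from rfmap.population import (
    DEFAULT_BUDGETS,
    TimeBudgets,
    allocate_population,
    classify_buildings,
    person_hours,
)
from rfmap.scene import Grid, SceneConfig, gen_district


def _zone(zone_id, geom, child=0, adult=0, workers=0, housing=None):
    return {
        "zone_id": zone_id, "geometry": geom, "pop_child": child,
        "pop_adult": adult, "workers": workers, "housing_area_m2": housing,
    }


def _building(bid, geom, use="dwelling", floors=1, office_share=0.0):
    return {
        "building_id": bid, "geometry": geom, "declared_use": use,
        "floors": floors, "office_share": office_share,
    }


class TestAllocation:
    def test_single_building_receives_whole_zone(self):
        zones = pd.DataFrame([_zone("Z", box(0, 0, 100, 100), adult=250,
                                    housing=400.0)])
        blds = pd.DataFrame([_building("B", box(10, 10, 30, 30))])
        # building housing area 400 = S_j: it holds everything
        out, un = allocate_population(blds, zones)
        assert out["pop_adult"].iloc[0] == pytest.approx(250.0)
        assert un.empty

    def test_proportional_split_between_two_buildings(self):
        # areas 30 and 70 in a 100-person zone give 30 and 70 persons
        zones = pd.DataFrame([_zone("Z", box(0, 0, 100, 100), adult=100,
                                    housing=100.0)])
        blds = pd.DataFrame(
            [
                _building("A", box(5, 5, 35, 6)),  # 30 m2
                _building("B", box(5, 10, 75, 11)),  # 70 m2
            ]
        )
        out, _ = allocate_population(blds, zones)
        assert out["pop_adult"].tolist() == pytest.approx([30.0, 70.0])

    def test_building_straddling_two_zones_sums_contributions(self):
        # half the building's 20 m2 housing area in each zone (10 m2 each),
        # zones of 100 and 200 persons with S_j = 100 each:
        # P = 10/100*100 + 10/100*200 = 30
        zones = pd.DataFrame(
            [
                _zone("Z1", box(0, 0, 100, 100), adult=100, housing=100.0),
                _zone("Z2", box(100, 0, 200, 100), adult=200, housing=100.0),
            ]
        )
        blds = pd.DataFrame([_building("B", box(90, 50, 110, 51))])
        out, _ = allocate_population(blds, zones)
        assert out["pop_adult"].iloc[0] == pytest.approx(30.0)

    def test_conservation_on_fully_covered_synthetic_district(self):
        scene = gen_district(SceneConfig(seed=13))
        out, un = allocate_population(scene.buildings, scene.zones)
        assert un.empty
        assert out["pop_child"].sum() == pytest.approx(
            scene.zones["pop_child"].sum(), abs=1e-8
        )
        assert out["pop_adult"].sum() == pytest.approx(
            scene.zones["pop_adult"].sum(), abs=1e-8
        )
        assert out["workers"].sum() == pytest.approx(
            scene.zones["workers"].sum(), abs=1e-8
        )

    def test_allocation_monotone_in_building_area(self):
        zones = pd.DataFrame([_zone("Z", box(0, 0, 100, 100), adult=100,
                                    housing=1000.0)])
        small = pd.DataFrame(
            [_building("A", box(0, 0, 10, 10)), _building("C", box(50, 50, 60, 60))]
        )
        large = pd.DataFrame(
            [_building("A", box(0, 0, 10, 20)), _building("C", box(50, 50, 60, 60))]
        )
        pa_small, _ = allocate_population(small, zones)
        pa_large, _ = allocate_population(large, zones)
        assert pa_large["pop_adult"].iloc[0] >= pa_small["pop_adult"].iloc[0]

    def test_populated_zone_without_housing_reported(self):
        zones = pd.DataFrame(
            [_zone("Z", box(0, 0, 100, 100), adult=50, housing=0.0)]
        )
        blds = pd.DataFrame([_building("B", box(0, 0, 10, 10))])
        with pytest.warns(UserWarning, match="without housing"):
            out, un = allocate_population(blds, zones)
        assert len(un) == 1
        assert out["pop_adult"].sum() == 0.0


class TestTypology:
    def test_known_uses_mapped(self):
        blds = pd.DataFrame(
            [
                _building("A", box(0, 0, 10, 10), use="dwelling"),
                _building("B", box(0, 0, 10, 10), use="office"),
                _building("C", box(0, 0, 10, 10), use="mixed",
                          office_share=0.4),
            ]
        )
        out = classify_buildings(blds)
        assert out["typology"].tolist() == ["residential", "office", "mixed"]
        assert out["office_share"].tolist() == pytest.approx([0.0, 1.0, 0.4])

    def test_mixed_split_drives_housing_and_office_areas(self):
        zones = pd.DataFrame([_zone("Z", box(0, 0, 100, 100), adult=0,
                                    workers=10, housing=60.0)])
        blds = pd.DataFrame(
            [_building("M", box(0, 0, 10, 10), use="mixed", office_share=0.4)]
        )
        out, _ = allocate_population(blds, zones)
        assert out["housing_area_m2"].iloc[0] == pytest.approx(60.0)
        assert out["office_area_m2"].iloc[0] == pytest.approx(40.0)

    def test_unknown_use_defaults_residential_with_warning(self):
        blds = pd.DataFrame([_building("X", box(0, 0, 5, 5), use="warehouse")])
        with pytest.warns(UserWarning, match="unknown use"):
            out = classify_buildings(blds)
        assert out["typology"].iloc[0] == "residential"


class TestPersonHours:
    GRID = Grid(0.0, 0.0, 100.0, 10, 10)

    def _allocated(self, adult=10.0, child=0.0, workers=0.0):
        return pd.DataFrame(
            [
                {
                    "building_id": "B",
                    "geometry": box(110, 110, 130, 130),
                    "pop_adult": adult,
                    "pop_child": child,
                    "workers": workers,
                }
            ]
        )

    def test_ten_residents_two_hours_outdoor(self):
        budgets = TimeBudgets(
            {
                "residential_adult": {"home": 22.0, "office": 0.0,
                                      "outdoor": 2.0},
            }
        )
        ph = person_hours(self._allocated(adult=10.0), self.GRID, budgets)
        outdoor = ph[ph["microenv"] == "outdoor"]
        assert outdoor["person_hours"].iloc[0] == pytest.approx(20.0)
        assert outdoor["location_type"].iloc[0] == "cell"
        assert outdoor["cell_id"].iloc[0] == self.GRID.cell_of(120, 120)

    def test_zero_outdoor_hours_everywhere(self):
        budgets = TimeBudgets(
            {"residential_adult": {"home": 24.0, "office": 0.0, "outdoor": 0.0}}
        )
        ph = person_hours(self._allocated(), self.GRID, budgets)
        assert (ph["microenv"] != "outdoor").all()

    def test_person_hours_scale_with_population(self):
        a = person_hours(self._allocated(adult=10.0), self.GRID)
        b = person_hours(self._allocated(adult=30.0), self.GRID)
        assert b["person_hours"].sum() == pytest.approx(
            3.0 * a["person_hours"].sum()
        )

    def test_budgets_must_sum_to_24(self):
        with pytest.raises(InvalidConfigError):
            TimeBudgets({"g": {"home": 10.0, "office": 0.0, "outdoor": 2.0}})

    def test_default_budgets_put_about_90pct_indoors(self):
        for group, b in DEFAULT_BUDGETS.budgets.items():
            indoor_frac = (b["home"] + b["office"]) / 24.0
            assert 0.85 <= indoor_frac <= 0.95, group
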