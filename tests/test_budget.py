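"""Field-scale supply/wastage accounting and the insect community summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from floralwastage.budget import (
    BudgetError,
    DayBudget,
    colony_equivalents,
    community_composition,
    day_budget,
    flower_density,
    insect_density,
    packaged_community_table,
    pooled_budget,
)


class TestDensities:
    def test_flower_density_product_of_means(self):
        # study-scale means: 46 racemes m^-2 x 7 flowers per raceme
        assert flower_density([46.0], [7.0]) == pytest.approx(322.0)
        assert flower_density([44, 48], [6, 8]) == pytest.approx(46 * 7)

    def test_zero_racemes(self):
        assert flower_density([0, 0], [5, 9]) == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(BudgetError):
            flower_density([], [7.0])

    def test_insect_density_division(self):
        assert insect_density([1.1], 50.0) == pytest.approx(0.022)
        assert insect_density([0, 0, 0]) == 0.0

    def test_doubling_area_halves_density(self):
        assert insect_density([3.0], 100.0) == pytest.approx(
            insect_density([3.0], 50.0) / 2
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(BudgetError):
            insect_density([1.0], 0.0)


class TestColonyEquivalents:
    @pytest.mark.parametrize(
        "kg,expected_2dp", [(0.14, 0.12), (0.11, 0.09), (1.186, 1.0)]
    )
    def test_lifetime_intake_fractions(self, kg, expected_2dp):
        assert round(colony_equivalents(kg, 1186.0), 2) == expected_2dp

    def test_nonpositive_intake_rejected(self):
        with pytest.raises(BudgetError):
            colony_equivalents(0.1, 0.0)


class TestDayBudget:
    def _budget(self, **kw):
        defaults = dict(
            day="D1",
            flowers_per_m2=322.0,
            insects_per_m2=0.022,
            secretion_uL_flower_h=0.10,
            secretion_ug_sugar_flower_h=47.1,
            uncollected_ug_sugar_flower_h=33.6,
        )
        defaults.update(kw)
        return DayBudget(**defaults)

    def test_per_insect_supply_from_grand_means(self):
        b = self._budget()
        # 322 x 0.10 / 0.022 ~ 1464 uL per insect per hour
        assert b.supply_uL_per_insect_h == pytest.approx(1463.6, abs=0.5)

    def test_uncollected_field_scale(self):
        b = self._budget()
        # 33.6 ug/flower/h x 322 flowers/m2 -> ~0.11 kg sugar/ha/h uncollected
        assert b.uncollected_kg_sugar_per_ha_h == pytest.approx(0.108, abs=0.001)
        assert round(b.uncollected_colony_equiv_per_ha_h, 2) == 0.09

    def test_zero_flowers_zero_supply(self):
        b = self._budget(flowers_per_m2=0.0)
        assert b.supply_uL_per_m2_h == 0.0
        assert b.supply_kg_sugar_per_ha_h == 0.0

    def test_zero_insects_flags_per_insect_fields(self):
        b = self._budget(insects_per_m2=0.0)
        assert b.supply_uL_per_insect_h is None
        assert b.supply_g_sugar_per_insect_h is None
        assert b.supply_kg_sugar_per_ha_h > 0  # others still computed

    def test_per_insect_times_density_identity(self):
        b = self._budget()
        assert b.supply_uL_per_insect_h * b.insects_per_m2 == pytest.approx(
            b.supply_uL_per_m2_h, rel=1e-12
        )

    @given(
        hst.floats(min_value=0.1, max_value=1000),
        hst.floats(min_value=0.1, max_value=100),
        hst.floats(min_value=0.5, max_value=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_flower_density(self, flowers, sugar, c):
        b1 = self._budget(flowers_per_m2=flowers, secretion_ug_sugar_flower_h=sugar)
        b2 = self._budget(flowers_per_m2=c * flowers, secretion_ug_sugar_flower_h=sugar)
        assert b2.supply_ug_sugar_per_m2_h == pytest.approx(
            c * b1.supply_ug_sugar_per_m2_h, rel=1e-9
        )
        assert b2.supply_uL_per_insect_h == pytest.approx(
            c * b1.supply_uL_per_insect_h, rel=1e-9
        )

    def test_unit_chain_exact(self):
        b = self._budget()
        expected = 47.1 * 322.0 * 1e-5
        assert b.supply_kg_sugar_per_ha_h == pytest.approx(expected, rel=1e-12)

    def test_day_budget_from_raw_inputs(self):
        b = day_budget(
            day="D1",
            raceme_counts_per_m2=[46, 46],
            flowers_per_raceme=[7],
            transect_counts=[1, 2, 0, 1, 2, 0, 1, 2, 1, 1],
            secretion_uL_flower_h=0.10,
            secretion_ug_sugar_flower_h=47.1,
            uncollected_ug_sugar_flower_h=33.6,
        )
        assert b.flowers_per_m2 == pytest.approx(322.0)
        assert b.insects_per_m2 == pytest.approx(1.1 / 50.0)


class TestPooling:
    def _b(self, day, insects=0.022):
        return DayBudget(
            day=day, flowers_per_m2=322.0, insects_per_m2=insects,
            secretion_uL_flower_h=0.10, secretion_ug_sugar_flower_h=47.1,
            uncollected_ug_sugar_flower_h=33.6,
        )

    def test_single_day_pooled_equals_day(self):
        b = self._b("D1")
        pooled = pooled_budget([b])
        assert pooled["supply_kg_sugar_per_ha_h"] == pytest.approx(
            b.supply_kg_sugar_per_ha_h
        )

    def test_identical_days_pool_to_same(self):
        pooled = pooled_budget([self._b("D1"), self._b("D2")])
        assert pooled["supply_uL_per_insect_h"] == pytest.approx(
            self._b("x").supply_uL_per_insect_h
        )

    def test_per_insect_mean_over_defined_days_only(self):
        b1 = self._b("D1", insects=322.0 * 0.10 / 1000.0)  # 1000 uL/insect/h
        b2 = self._b("D2", insects=322.0 * 0.10 / 3000.0)  # 3000 uL/insect/h
        b3 = self._b("D3", insects=0.0)  # undefined
        pooled = pooled_budget([b1, b2, b3])
        assert pooled["supply_uL_per_insect_h"] == pytest.approx(2000.0)
        assert pooled["n_days_undefined_per_insect"] == 1

    def test_empty_pool_rejected(self):
        with pytest.raises(BudgetError):
            pooled_budget([])


class TestCommunity:
    def test_packaged_survey_composition(self):
        comp = community_composition(packaged_community_table())
        assert comp["total"] == 638
        assert comp["bumblebees"] == 122
        assert comp["non_apid_bees"] == 22
        assert round(comp["honeybee_pct"]) == 71
        assert round(comp["honeybee_plus_bumblebee_pct"]) == 90

    def test_shares_sum_to_one(self):
        comp = community_composition(packaged_community_table())
        parts = (
            comp["honeybees"] + comp["bumblebees"]
            + comp["non_apid_bees"] + comp["non_bees"]
        )
        assert parts == comp["total"]
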