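"""The footprint engine: weighted group emissions, totals, controlled rows."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietfootprint import (
    CommodityConversion,
    CompositionEntry,
    CompositionTable,
    ConsumptionPattern,
    EmptyGroupError,
    GroupRecommendation,
    GuidelineSet,
    ImpactFactorTable,
    MissingReferenceError,
    ValidationError,
    apply_discretionary,
    controlled_comparison,
    diet_footprint,
    group_footprint,
    reference_ratio,
)
from dietfootprint.footprint import per_commodity_frame
from dietfootprint.synthetic import TABLE3_PRINTED, TABLE4_PRINTED


def _random_instance(rng, n):
    shares = rng.dirichlet(np.ones(n))
    names = [f"c{i}" for i in range(n)]
    pattern = ConsumptionPattern("x", "protein_foods", dict(zip(names, shares)))
    conv = {
        name: CommodityConversion(name, unit_to_kg=float(rng.uniform(0.05, 0.3)),
                                  cooked_to_raw=float(rng.uniform(0.8, 1.5)))
        for name in names
    }
    impacts = ImpactFactorTable(
        {name: float(rng.lognormal(0, 0.8)) for name in names}
    )
    return pattern, conv, impacts


class TestGroupFootprint:
    def test_published_fruit_worked_example(self, fruit_fixture):
        fx = fruit_fixture
        total, contribs = group_footprint(
            fx.rec.amount, fx.pattern, fx.conversions, fx.impacts
        )
        assert total == pytest.approx(fx.printed_total, abs=5e-4)
        for commodity, printed in fx.printed_contributions.items():
            # the grapefruit row prints one unit low at the third decimal;
            # all rows agree within +-0.001
            assert contribs[commodity] == pytest.approx(printed, abs=1e-3)

    def test_zero_recommendation_gives_zero(self, fruit_fixture):
        fx = fruit_fixture
        total, contribs = group_footprint(0.0, fx.pattern, fx.conversions, fx.impacts)
        assert total == 0.0
        assert all(v == 0.0 for v in contribs.values())

    def test_single_commodity_trivial_product(self):
        pattern = ConsumptionPattern("x", "grains", {"rice": 1.0})
        conv = {"rice": CommodityConversion("rice", unit_to_kg=1.0)}
        impacts = ImpactFactorTable({"rice": 2.0})
        total, _ = group_footprint(1.0, pattern, conv, impacts)
        assert total == pytest.approx(2.0)

    def test_matches_per_commodity_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 9))
            pattern, conv, impacts = _random_instance(rng, n)
            rec = float(rng.uniform(0, 5))
            total, contribs = group_footprint(rec, pattern, conv, impacts)
            oracle = 0.0
            for c, share in pattern.shares.items():
                oracle += rec * share * conv[c].unit_to_kg * conv[c].cooked_to_raw \
                    * impacts.intensities[c]
            assert math.isclose(total, oracle, rel_tol=1e-9, abs_tol=1e-12)
            assert math.isclose(sum(contribs.values()), total, rel_tol=1e-9,
                                abs_tol=1e-12)

    def test_convex_combination_bounds(self, rng):
        for _ in range(50):
            pattern, conv, impacts = _random_instance(rng, int(rng.integers(2, 9)))
            rec = float(rng.uniform(0.1, 5))
            total, _ = group_footprint(rec, pattern, conv, impacts)
            unit_costs = [conv[c].factor * impacts.intensities[c]
                          for c in pattern.shares]
            assert min(unit_costs) - 1e-12 <= total / rec <= max(unit_costs) + 1e-12

    def test_linear_in_recommendation(self, rng):
        pattern, conv, impacts = _random_instance(rng, 6)
        t1, _ = group_footprint(1.7, pattern, conv, impacts)
        t2, _ = group_footprint(3.4, pattern, conv, impacts)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_missing_conversion_or_intensity_raises(self, fruit_fixture):
        fx = fruit_fixture
        conv = dict(fx.conversions)
        conv.pop("bananas")
        with pytest.raises(MissingReferenceError, match="bananas"):
            group_footprint(2.0, fx.pattern, conv, fx.impacts)
        impacts = ImpactFactorTable(
            {c: v for c, v in fx.impacts.intensities.items() if c != "dates"}
        )
        with pytest.raises(MissingReferenceError, match="dates"):
            group_footprint(2.0, fx.pattern, fx.conversions, impacts)


class TestApplyDiscretionary:
    def test_reproduces_published_us_total(self):
        base = sum(TABLE3_PRINTED["United States"]["per_group"].values())
        assert base == pytest.approx(3.31)
        total = apply_discretionary(base, 270.0, 2000.0)
        assert total == pytest.approx(3.83, abs=0.005)

    def test_identity_at_zero_and_doubling_at_half(self):
        assert apply_discretionary(2.5, 0.0, 2000.0) == 2.5
        assert apply_discretionary(1.0, 1000.0, 2000.0) == pytest.approx(2.0)

    def test_rejects_discretionary_at_or_above_diet(self):
        with pytest.raises(ValidationError):
            apply_discretionary(1.0, 2000.0, 2000.0)

    @given(d=st.floats(min_value=0, max_value=1999.0))
    def test_increasing_and_continuous_at_zero(self, d):
        base = 1.7
        assert apply_discretionary(base, d, 2000.0) >= base
        eps = apply_discretionary(base, 1e-9, 2000.0)
        assert eps == pytest.approx(base, rel=1e-8)


class TestDietFootprint:
    def _two_group_inputs(self):
        gs = GuidelineSet(
            "testland", 2000.0,
            (GroupRecommendation("grains", 100.0, "g"),
             GroupRecommendation("dairy", 200.0, "ml")),
            discretionary_kcal=200.0,
        )
        patterns = {
            "grains": ConsumptionPattern("testland", "grains",
                                         {"rice": 0.6, "wheat": 0.4}),
            "dairy": ConsumptionPattern("testland", "dairy", {"milk": 1.0}),
        }
        cooked_to_raw = {"rice": 1 / 2.5, "wheat": 1 / 2.0}
        impacts = ImpactFactorTable({"rice": 4.0, "wheat": 1.5, "milk": 1.32})
        return gs, patterns, cooked_to_raw, impacts

    def test_hand_computed_two_group_total(self):
        gs, patterns, cooked_to_raw, impacts = self._two_group_inputs()
        fp = diet_footprint(gs, patterns, cooked_to_raw, impacts)
        grains = 0.1 * (0.6 * (1 / 2.5) * 4.0 + 0.4 * (1 / 2.0) * 1.5)
        dairy = 0.2 * 1.0305 * 1.32
        assert fp.per_group["grains"] == pytest.approx(grains, rel=1e-12)
        assert fp.per_group["dairy"] == pytest.approx(dairy, rel=1e-12)
        assert fp.base_total == pytest.approx(grains + dairy, rel=1e-12)
        assert fp.total == pytest.approx((grains + dairy) * 2000 / 1800, rel=1e-12)

    def test_all_zero_amounts_yield_zero_footprint(self):
        gs = GuidelineSet(
            "testland", 2000.0,
            (GroupRecommendation("grains", 0.0, "g"),),
        )
        patterns = {"grains": ConsumptionPattern("testland", "grains", {"rice": 1.0})}
        fp = diet_footprint(gs, patterns, impacts=ImpactFactorTable({"rice": 4.0}))
        assert fp.total == 0.0

    def test_fruit_only_guideline_reproduces_worked_example(self, fruit_fixture):
        fx = fruit_fixture
        comp = CompositionTable({
            c: CompositionEntry(kcal_per_cup=cc.unit_to_kg * 500.0, kcal_per_100g=50.0)
            for c, cc in fx.conversions.items()
        })
        gs = GuidelineSet("United States", 2000.0, (fx.rec,))
        fp = diet_footprint(gs, {"fruit": fx.pattern}, None, fx.impacts, comp)
        assert fp.total == pytest.approx(0.165, abs=5e-4)

    def test_sugar_added_as_single_commodity_group(self):
        gs = GuidelineSet(
            "testland", 2000.0,
            (GroupRecommendation("grains", 100.0, "g"),
             GroupRecommendation("sugar", 32.0, "g")),
        )
        patterns = {"grains": ConsumptionPattern("testland", "grains", {"rice": 1.0})}
        impacts = ImpactFactorTable({"rice": 4.0, "sugar & sweeteners": 0.5})
        fp = diet_footprint(gs, patterns, impacts=impacts)
        assert fp.sugar_ghge == pytest.approx(0.032 * 0.5, rel=1e-12)
        assert fp.base_total == pytest.approx(0.4 + 0.016, rel=1e-12)

    def test_allowed_commodities_restrict_the_pattern(self):
        gs = GuidelineSet(
            "testland", 2000.0,
            (GroupRecommendation("protein_foods", 100.0, "g",
                                 allowed_commodities=("beans",)),),
        )
        patterns = {"protein_foods": ConsumptionPattern(
            "testland", "protein_foods", {"beef": 0.8, "beans": 0.2})}
        impacts = ImpactFactorTable({"beef": 30.0, "beans": 1.0})
        fp = diet_footprint(gs, patterns, impacts=impacts)
        assert fp.per_group["protein_foods"] == pytest.approx(0.1 * 1.0, rel=1e-12)

    def test_missing_pattern_raises_empty_group(self):
        gs = GuidelineSet(
            "testland", 2000.0, (GroupRecommendation("fruit", 100.0, "g"),)
        )
        with pytest.raises(EmptyGroupError, match="fruit"):
            diet_footprint(gs, {}, impacts=ImpactFactorTable({}))

    def test_contributions_resum_to_groups(self):
        gs, patterns, cooked_to_raw, impacts = self._two_group_inputs()
        fp = diet_footprint(gs, patterns, cooked_to_raw, impacts)
        for group, value in fp.per_group.items():
            resum = sum(v for (g, _), v in fp.per_commodity.items() if g == group)
            assert resum == pytest.approx(value, rel=1e-9)
        frame = per_commodity_frame([fp])
        assert frame["ghge_kg_co2e_per_d"].sum() == pytest.approx(fp.base_total)

    def test_doubling_recommendations_doubles_base_total(self):
        gs, patterns, cooked_to_raw, impacts = self._two_group_inputs()
        doubled = GuidelineSet(
            gs.country, gs.diet_kcal,
            tuple(GroupRecommendation(r.group, 2 * r.amount, r.unit)
                  for r in gs.recommendations),
            discretionary_kcal=gs.discretionary_kcal,
        )
        fp1 = diet_footprint(gs, patterns, cooked_to_raw, impacts)
        fp2 = diet_footprint(doubled, patterns, cooked_to_raw, impacts)
        assert fp2.base_total == pytest.approx(2 * fp1.base_total, rel=1e-12)


class TestControlledComparison:
    def _guidelines(self):
        return [
            GuidelineSet("refland", 2000.0,
                         (GroupRecommendation("grains", 100.0, "g"),)),
            GuidelineSet("otherland", 2000.0,
                         (GroupRecommendation("grains", 100.0, "g"),)),
        ]

    reference_patterns = {
        "grains": ConsumptionPattern("refland", "grains", {"rice": 0.5, "wheat": 0.5})
    }
    impacts = ImpactFactorTable({"rice": 4.0, "wheat": 1.0})

    def test_reference_row_equals_own_diet_footprint_exactly(self):
        gs = self._guidelines()[0]
        fp = diet_footprint(gs, self.reference_patterns, impacts=self.impacts)
        table = controlled_comparison(
            self._guidelines(), self.reference_patterns, impacts=self.impacts,
            reference_country="refland", decimals=None,
        )
        row = table[table["country"] == "refland"].iloc[0]
        assert row["total"] == fp.total  # bitwise: same code path, same inputs
        assert row["reference_ratio"] == 1.0

    def test_identical_guidelines_have_unit_ratio(self):
        table = controlled_comparison(
            self._guidelines(), self.reference_patterns, impacts=self.impacts,
            reference_country="refland", decimals=2,
        )
        assert list(table["reference_ratio"]) == [1.0, 1.0]

    def test_missing_reference_country_rejected(self):
        with pytest.raises(ValidationError, match="nowhere"):
            controlled_comparison(
                self._guidelines(), self.reference_patterns, impacts=self.impacts,
                reference_country="nowhere",
            )

    @pytest.mark.parametrize("country, expected", [
        ("EAT-Lancet", 2.82),
        ("US Vegetarian", 2.13),
        ("United States", 1.00),
    ])
    def test_published_ratio_column_from_printed_totals(self, country, expected):
        ref_total = TABLE4_PRINTED["United States"]["total"]
        ratio = reference_ratio(ref_total, TABLE4_PRINTED[country]["total"])
        assert round(ratio, 2) == expected

    def test_published_reference_row_unchanged_by_controlling(self):
        # controlling with a country's own pattern cannot change its row
        assert TABLE4_PRINTED["United States"] == {
            **TABLE3_PRINTED["United States"], "ratio": 1.00,
        }
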