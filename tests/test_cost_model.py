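"""Product-chain arithmetic, extrapolation indices and the cost ledger."""

import dataclasses

import pytest

from sqlns_cea.cost_model import (
    ActivityCostItem,
    DistrictProfile,
    build_cost_ledger,
    cost_per_sachet,
    extrapolation_index,
    incentive_cost_per_child,
    product_cost_per_child,
    read_activity_items,
    read_districts,
    scale_activity_costs,
    supply_chain_cost_per_child,
    write_activity_items,
    write_districts,
)
from sqlns_cea.demography import CohortProjection
from sqlns_cea.parameters import CostParameters, InterventionDesign, default_uganda_config

DESIGN = InterventionDesign()
COSTS = CostParameters()

BASE = DistrictProfile("Namutumba", 820.0, 15000.0, 1300.0, "Busoga")
OTHER = DistrictProfile("Other", 1585.0, 30000.0, 2600.0, "Tooro")


class TestUnitCosts:
    def test_cost_per_sachet(self):
        assert cost_per_sachet(COSTS) == pytest.approx(0.0610, abs=5e-5)

    def test_cost_per_sachet_degenerate(self):
        assert cost_per_sachet(
            CostParameters(price_per_carton_usd=546)) == 1.0
        assert cost_per_sachet(CostParameters(price_per_carton_usd=0)) == 0.0
        with pytest.raises(ValueError):
            cost_per_sachet(CostParameters(sachets_per_carton=0))

    def test_product_cost_per_child(self):
        assert product_cost_per_child(COSTS, DESIGN) \
            == pytest.approx(365 * 33.30 / 546)
        assert product_cost_per_child(COSTS, DESIGN) \
            == pytest.approx(22.26, abs=0.005)

    def test_product_cost_linearity_in_price(self):
        doubled = CostParameters(price_per_carton_usd=66.60)
        assert product_cost_per_child(doubled, DESIGN) \
            == pytest.approx(2 * product_cost_per_child(COSTS, DESIGN))

    def test_product_cost_zero_sachets(self):
        design = InterventionDesign(sachets_per_day=0)
        assert product_cost_per_child(COSTS, design) == 0.0

    def test_supply_chain_cost_per_child(self):
        # (0.31 + 1.01 + 0.17) USD/kg x 7.3 kg/child-year
        assert supply_chain_cost_per_child(COSTS, DESIGN) \
            == pytest.approx(1.49 * 7.3)
        assert supply_chain_cost_per_child(COSTS, DESIGN) \
            == pytest.approx(10.88, abs=0.005)

    def test_supply_chain_component_sum(self):
        no_customs = CostParameters(customs_usd_per_kg=0.0)
        assert supply_chain_cost_per_child(no_customs, DESIGN) \
            == pytest.approx((0.31 + 0.17) * 7.3)

    def test_supply_chain_zero_mass(self):
        design = InterventionDesign(sachet_mass_g=1e-12)
        assert supply_chain_cost_per_child(COSTS, design) \
            == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("rate, deliveries, expected", [
        (0.44, 4, 1.76), (0.87, 4, 3.48), (0.44, 0, 0.0),
    ])
    def test_incentive_cost(self, rate, deliveries, expected):
        costs = CostParameters(vht_incentive_usd_per_delivery=rate)
        design = InterventionDesign(deliveries_per_year=deliveries) \
            if deliveries else dataclasses.replace(
                DESIGN, deliveries_per_year=0)
        assert incentive_cost_per_child(costs, design) \
            == pytest.approx(expected)


class TestExtrapolationIndex:
    def test_spatial_index(self):
        assert extrapolation_index(OTHER, BASE, "spatial") \
            == pytest.approx(1585 / 820)
        assert extrapolation_index(OTHER, BASE, "spatial") \
            == pytest.approx(1.93, abs=0.005)

    @pytest.mark.parametrize("kind", ["spatial", "child_pop", "vht_pop",
                                      "vht_child_ratio", "none"])
    def test_self_index_is_one(self, kind):
        assert extrapolation_index(BASE, BASE, kind) == 1.0

    def test_ratio_of_ratios(self):
        # children and VHTs both doubled: the VHT-per-child ratio is equal
        assert extrapolation_index(OTHER, BASE, "vht_child_ratio") \
            == pytest.approx(1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            extrapolation_index(OTHER, BASE, "galactic")


class TestScaleActivityCosts:
    ITEM = ActivityCostItem("capacity_building", "transport", "recurring",
                            1000.0, "spatial")

    def test_base_district_unchanged(self):
        out = scale_activity_costs([self.ITEM], [BASE], BASE)
        assert out.loc[0, "cost_usd"] == pytest.approx(1000.0)

    def test_spatial_scaling(self):
        out = scale_activity_costs([self.ITEM], [BASE, OTHER], BASE)
        other = out[out["district"] == "Other"]["cost_usd"].iloc[0]
        assert other == pytest.approx(1000.0 * 1585 / 820)

    def test_identical_districts_double_national_total(self):
        twin = dataclasses.replace(BASE, name="Twin")
        out = scale_activity_costs([self.ITEM], [BASE, twin], BASE)
        assert out["cost_usd"].sum() == pytest.approx(2000.0)

    def test_missing_base_rejected(self):
        with pytest.raises(ValueError, match="Namutumba"):
            scale_activity_costs([self.ITEM], [OTHER], BASE)


class TestCostLedger:
    def test_per_child_components_on_fixture(self, base_results):
        comp = base_results.ledger.per_child_components()
        assert comp["product"] == pytest.approx(22.26, abs=0.005)
        assert comp["product_supply_chain"] == pytest.approx(10.88, abs=0.005)
        assert comp["total"] == pytest.approx(
            comp["product"] + comp["product_supply_chain"]
            + comp["nonproduct_programmatic"])

    def test_totals_equal_component_sums(self, base_results):
        ledger = base_results.ledger
        assert ledger.annual_totals().sum() == pytest.approx(
            ledger.total(), rel=1e-9)
        assert ledger.district_totals().sum() == pytest.approx(
            ledger.total(), rel=1e-9)

    def test_ledger_linear_in_carton_price(self, fixture):
        districts, items, cohorts = fixture
        config = default_uganda_config()
        base_ledger = build_cost_ledger(config, districts, [], cohorts)
        doubled = config.copy()
        doubled.costs.price_per_carton_usd *= 2
        doubled_ledger = build_cost_ledger(doubled, districts, [], cohorts)
        product = base_ledger.table.groupby("activity")["cost_usd"].sum()
        product2 = doubled_ledger.table.groupby("activity")["cost_usd"].sum()
        assert product2["product"] == pytest.approx(
            2 * product["product"], rel=1e-12)
        assert product2["product_supply_chain"] == pytest.approx(
            product["product_supply_chain"], rel=1e-12)

    def test_zero_base_costs_leaves_product_chain_only(self):
        config = default_uganda_config()
        config.costs.vht_incentive_usd_per_delivery = 0.0
        cohorts = CohortProjection(
            {y: 1000.0 for y in range(2022, 2032)})
        ledger = build_cost_ledger(config, [BASE], [], cohorts)
        expected = (product_cost_per_child(config.costs, config.design)
                    + supply_chain_cost_per_child(config.costs,
                                                  config.design))
        assert ledger.cost_per_child() == pytest.approx(expected)

    def test_split_district_invariance_for_population_indices(self):
        """Splitting a district in two (proportional area/children/VHTs)
        leaves the national total unchanged for population-type indices."""
        config = default_uganda_config()
        cohorts = CohortProjection({y: 30000.0 for y in range(2022, 2032)})
        item = ActivityCostItem("overhead", "other", "recurring",
                                5000.0, "child_pop")
        whole = [BASE, OTHER]
        half = dataclasses.replace(OTHER, name="Other-A",
                                   area_km2=OTHER.area_km2 / 2,
                                   eligible_children=OTHER.eligible_children / 2,
                                   vht_count=OTHER.vht_count / 2)
        other_half = dataclasses.replace(half, name="Other-B")
        split = [BASE, half, other_half]
        ledger_whole = build_cost_ledger(config, whole, [item], cohorts)
        ledger_split = build_cost_ledger(config, split, [item], cohorts)
        assert ledger_split.cost_per_child() == pytest.approx(
            ledger_whole.cost_per_child(), rel=1e-12)

    def test_empty_district_list_rejected(self):
        config = default_uganda_config()
        cohorts = CohortProjection({y: 1.0 for y in range(2022, 2032)})
        with pytest.raises(ValueError):
            build_cost_ledger(config, [], [], cohorts)

    def test_startup_costs_annualised(self):
        config = default_uganda_config()
        cohorts = CohortProjection({y: 0.001 for y in range(2022, 2032)})
        item = ActivityCostItem("sbcc", "materials", "startup",
                                1000.0, "none")
        ledger = build_cost_ledger(config, [BASE], [item], cohorts)
        startup_year = ledger.table[ledger.table["year"] == 2021]
        assert startup_year["cost_usd"].sum() == pytest.approx(1000.0)
        # annualised over the 10-year horizon
        assert ledger.activity_totals()["sbcc"] == pytest.approx(100.0)


class TestTableIO:
    def test_district_round_trip(self, tmp_path):
        path = tmp_path / "districts.csv"
        write_districts([BASE, OTHER], path)
        assert read_districts(path) == [BASE, OTHER]

    def test_activity_round_trip(self, tmp_path):
        items = [ActivityCostItem("logistics", "transport", "recurring",
                                  123.45, "spatial")]
        path = tmp_path / "items.csv"
        write_activity_items(items, path)
        assert read_activity_items(path) == items
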