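"""Scenario engine, cost-effectiveness ratios and geographic targeting."""

import pytest

from sqlns_cea.parameters import default_uganda_config
from sqlns_cea.scenario_cea import (
    ScenarioSpec,
    TARGETING_SUB_REGIONS,
    apply_scenario,
    apply_targeting,
    cer,
    default_scenarios,
    run_model,
    run_sensitivity,
)


class TestCer:
    def test_published_aggregate_ratios(self):
        assert cer(58.7e6, 242_292) == pytest.approx(242.3, abs=0.05)
        assert cer(58.7e6, 3_689) == pytest.approx(15_912, abs=1)

    def test_zero_cost(self):
        assert cer(0.0, 100.0) == 0.0

    def test_zero_effect_is_absent_not_infinite(self):
        assert cer(100.0, 0.0) is None


class TestApplyScenario:
    def test_empty_overrides_is_identity(self, config):
        out = apply_scenario(config, ScenarioSpec("noop", {}))
        out.scenario_name = config.scenario_name
        assert out == config

    def test_original_untouched(self, config):
        apply_scenario(config, ScenarioSpec(
            "zero_customs", {"costs.customs_usd_per_kg": 0.0}))
        assert config.costs.customs_usd_per_kg == 1.01

    def test_idempotent(self, config):
        spec = ScenarioSpec("x", {"costs.customs_usd_per_kg": 0.0})
        once = apply_scenario(config, spec)
        twice = apply_scenario(once, spec)
        assert once == twice

    def test_price_per_sachet_alias(self, config):
        out = apply_scenario(config, ScenarioSpec(
            "expensive", {"costs.price_per_sachet_usd": 0.09}))
        assert out.costs.price_per_carton_usd == pytest.approx(0.09 * 546)

    def test_outcome_path(self, config):
        out = apply_scenario(config, ScenarioSpec(
            "weak", {"outcomes.mortality.relative_reduction": 0.18}))
        assert out.outcome("mortality").relative_reduction == 0.18

    def test_unknown_path_named_in_error(self, config):
        with pytest.raises(KeyError, match="costs.price_of_tea"):
            apply_scenario(config, ScenarioSpec(
                "bad", {"costs.price_of_tea": 1.0}))

    def test_best_and_worst_cases_compose(self, config):
        by_name = {s.name: s for s in default_scenarios(config)}
        best = apply_scenario(config, by_name["best_case"])
        assert best.costs.customs_usd_per_kg == 0.0
        assert best.costs.price_per_carton_usd == pytest.approx(33.30 * 0.9)
        assert best.costs.vht_incentive_usd_per_delivery == 0.29
        worst = apply_scenario(config, by_name["worst_case"])
        assert worst.outcome("mortality").relative_reduction == 0.18
        assert worst.costs.price_per_carton_usd == pytest.approx(0.09 * 546)
        assert worst.costs.vht_incentive_usd_per_delivery == 0.87


class TestRunModel:
    def test_ratios_consistent_with_totals(self, base_results):
        for rate in base_results.rates:
            m = base_results.metrics[rate]
            assert m["cost_per_daly"] == pytest.approx(
                m["total_cost"] / m["dalys_averted"], rel=1e-9)
            assert m["cost_per_death"] == pytest.approx(
                m["total_cost"] / m["effects_averted"]["mortality"],
                rel=1e-9)

    def test_deterministic(self, config, fixture):
        districts, items, cohorts = fixture
        a = run_model(config, districts, items, cohorts)
        b = run_model(config, districts, items, cohorts)
        assert a.metrics == b.metrics

    def test_zero_effects_give_absent_ratios(self, fixture):
        districts, items, cohorts = fixture
        null = default_uganda_config()
        for spec in null.outcomes:
            spec.relative_reduction = 0.0
        res = run_model(null, districts, items, cohorts)
        assert res.metric("cost_per_daly") is None
        assert res.metric("cost_per_death") is None

    def test_summary_mentions_review_parameters(self, base_results):
        text = base_results.summary()
        assert "cost per DALY averted" in text
        assert "review" in text


@pytest.fixture(scope="module")
def sensitivity_table(config, fixture):
    districts, items, cohorts = fixture
    return run_sensitivity(config, default_scenarios(config),
                           districts, items, cohorts)


class TestRunSensitivity:
    def test_nine_rows_base_first(self, sensitivity_table):
        assert len(sensitivity_table) == 9
        assert sensitivity_table["scenario"].iloc[0] == "base"

    def test_duplicate_names_rejected(self, config, fixture):
        districts, items, cohorts = fixture
        dupes = [ScenarioSpec("a", {}), ScenarioSpec("a", {})]
        with pytest.raises(ValueError, match="duplicate"):
            run_sensitivity(config, dupes, districts, items, cohorts)

    def test_customs_elimination_lowers_cost_per_daly(self, sensitivity_table):
        t = sensitivity_table.set_index("scenario")
        assert t.loc["customs_eliminated", "cost_per_daly"] \
            < t.loc["base", "cost_per_daly"]

    def test_mortality_scenario_rescales_cost_per_death(self,
                                                        sensitivity_table):
        t = sensitivity_table.set_index("scenario")
        assert t.loc["mortality_rr_18", "cost_per_death"] == pytest.approx(
            t.loc["base", "cost_per_death"] * 27 / 18, rel=1e-9)

    def test_best_base_worst_ordering(self, sensitivity_table):
        t = sensitivity_table.set_index("scenario")
        for col in ("cost_per_daly", "cost_per_death"):
            assert t.loc["best_case", col] <= t.loc["base", col] \
                <= t.loc["worst_case", col]


class TestTargeting:
    def test_all_sub_regions_matches_untargeted(self, config, fixture,
                                                base_results):
        districts, items, cohorts = fixture
        everything = sorted({d.sub_region for d in districts})
        subset, res, comparison = apply_targeting(
            districts, everything, config, items, cohorts)
        assert len(subset) == len(districts)
        assert comparison["cohort_share"] == pytest.approx(1.0)
        assert res.metric("average_annual_cost") == pytest.approx(
            base_results.metric("average_annual_cost"), rel=1e-9)

    def test_high_mortality_sub_regions(self, config, fixture):
        districts, items, cohorts = fixture
        subset, res, comparison = apply_targeting(
            districts, list(TARGETING_SUB_REGIONS), config, items, cohorts)
        children = sum(d.eligible_children for d in subset)
        assert children == pytest.approx(396_808)
        assert comparison["cohort_share"] == pytest.approx(0.3548, abs=0.001)
        # ~65% cost reduction: 58.7M -> ~20.8M
        assert comparison["targeted_average_annual_cost"] \
            == pytest.approx(20.8e6, rel=0.05)

    def test_per_child_unit_components_unchanged(self, config, fixture,
                                                 base_results):
        districts, items, cohorts = fixture
        _, res, _ = apply_targeting(
            districts, list(TARGETING_SUB_REGIONS), config, items, cohorts)
        full = base_results.ledger.per_child_components()
        targeted = res.ledger.per_child_components()
        for key in ("product", "product_supply_chain"):
            assert targeted[key] == pytest.approx(full[key], rel=1e-12)
        assert targeted["total"] == pytest.approx(full["total"], rel=0.02)

    def test_empty_selection_rejected(self, config, fixture):
        districts, items, cohorts = fixture
        with pytest.raises(ValueError):
            apply_targeting(districts, [], config, items, cohorts)

    def test_unknown_sub_region_rejected(self, config, fixture):
        districts, items, cohorts = fixture
        with pytest.raises(ValueError, match="Atlantis"):
            apply_targeting(districts, ["Atlantis"], config, items, cohorts)
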