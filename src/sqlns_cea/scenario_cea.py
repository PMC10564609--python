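"""Cost-effectiveness assembly, sensitivity scenarios and geographic
targeting.

The central object is :class:`SqlnsCeaModel`, built from a
:class:`~sqlns_cea.parameters.ModelConfig` plus the district table, the
base-district activity-cost items and the cohort projection. ``fit()``
runs the cost, effectiveness and DALY models and returns a
:class:`CeaResults` carrying, at each discount rate, the programme cost,
effects averted, DALYs averted and every cost-per-unit ratio, with a
``summary()`` table.

Ratios are computed on summed totals over the modelled intervention period
(2021-2031 by default), not as means of annual ratios. Under discounting,
costs and effects share identical per-year factors; health burdens are
additionally discounted within their duration (see daly_model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .cost_model import (
    ActivityCostItem,
    CostLedger,
    DistrictProfile,
    build_cost_ledger,
)
from .daly_model import dalys_averted
from .demography import CohortProjection
from .effectiveness_model import annual_effect_table
from .parameters import ModelConfig, validate

__all__ = [
    "TARGETING_SUB_REGIONS", "ScenarioSpec", "CeaResults", "SqlnsCeaModel",
    "cer", "apply_scenario", "default_scenarios", "run_model",
    "run_sensitivity", "apply_targeting",
]

#: Sub-regions with the highest under-five mortality in the 2016 DHS; the
#: default geographic-targeting selection.
TARGETING_SUB_REGIONS = ("West Nile", "Busoga", "Tooro", "Ankole", "Karamoja")


def cer(total_cost: float, effect: float) -> float | None:
    """Cost-effectiveness ratio: cost per unit of effect.

    A non-positive effect has no defined ratio and returns ``None``
    (absent), never infinity.
    """
    if total_cost < 0:
        raise ValueError("total_cost must be >= 0")
    if effect <= 0:
        return None
    return total_cost / effect


# ---------------------------------------------------------------------------
# Scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides (dotted config paths -> values).

    ``costs.price_per_sachet_usd`` is accepted as a derived path and is
    translated to a carton price.
    """

    name: str
    overrides: dict[str, Any] = field(default_factory=dict)


def _resolve_parent(config: ModelConfig, path: str):
    """Return (object, attribute name) for a dotted override path."""
    parts = path.split(".")
    obj: Any = config
    if parts[0] == "outcomes":
        if len(parts) != 3:
            raise KeyError(f"unknown override path {path!r}")
        try:
            obj = config.outcome(parts[1])
        except KeyError as exc:
            raise KeyError(f"unknown override path {path!r}") from exc
        parts = parts[2:]
    else:
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise KeyError(f"unknown override path {path!r}")
            obj = getattr(obj, part)
        parts = parts[-1:]
    if not hasattr(obj, parts[0]):
        raise KeyError(f"unknown override path {path!r}")
    return obj, parts[0]


def apply_scenario(config: ModelConfig, spec: ScenarioSpec) -> ModelConfig:
    """Return a new config with the scenario's overrides applied.

    The input config is untouched; unknown paths raise ``KeyError`` naming
    the offending path; the result must pass validation.
    """
    new = config.copy()
    for path, value in spec.overrides.items():
        if path == "costs.price_per_sachet_usd":
            new.costs.price_per_carton_usd = (
                value * new.costs.sachets_per_carton)
            continue
        obj, attr = _resolve_parent(new, path)
        setattr(obj, attr, value)
    new.scenario_name = spec.name
    problems = validate(new)
    if problems:
        raise ValueError(
            f"scenario {spec.name!r} produced an invalid config: "
            + "; ".join(problems)
        )
    return new


def default_scenarios(config: ModelConfig) -> list[ScenarioSpec]:
    """The six single-parameter sensitivity scenarios plus best/worst cases.

    Single-parameter scenarios: mortality reduction 18% instead of 27%;
    customs clearance eliminated; product price -10%; product price raised
    to $0.09/sachet; VHT incentive lowered to $0.29/delivery; VHT incentive
    raised to $0.87/delivery. Best case combines the three favourable cost
    changes; worst case combines the 18% mortality reduction with the price
    and incentive increases.
    """
    price = config.costs.price_per_carton_usd
    return [
        ScenarioSpec("mortality_rr_18",
                     {"outcomes.mortality.relative_reduction": 0.18}),
        ScenarioSpec("customs_eliminated", {"costs.customs_usd_per_kg": 0.0}),
        ScenarioSpec("price_minus_10pct",
                     {"costs.price_per_carton_usd": price * 0.9}),
        ScenarioSpec("price_9c_per_sachet",
                     {"costs.price_per_sachet_usd": 0.09}),
        ScenarioSpec("incentive_lower",
                     {"costs.vht_incentive_usd_per_delivery": 0.29}),
        ScenarioSpec("incentive_higher",
                     {"costs.vht_incentive_usd_per_delivery": 0.87}),
        ScenarioSpec("best_case", {
            "costs.customs_usd_per_kg": 0.0,
            "costs.price_per_carton_usd": price * 0.9,
            "costs.vht_incentive_usd_per_delivery": 0.29,
        }),
        ScenarioSpec("worst_case", {
            "outcomes.mortality.relative_reduction": 0.18,
            "costs.price_per_sachet_usd": 0.09,
            "costs.vht_incentive_usd_per_delivery": 0.87,
        }),
    ]


# ---------------------------------------------------------------------------
# Results


@dataclass
class CeaResults:
    """Fitted cost-effectiveness results for one scenario.

    ``metrics`` maps each discount rate to a dict with keys
    ``total_cost``, ``average_annual_cost``, ``cost_per_child``,
    ``effects_averted`` (per-outcome totals over the horizon),
    ``dalys_averted``, ``cost_per_daly``, ``cost_per_death`` and
    ``cost_per_case`` (per outcome; ``None`` when the effect is zero).
    Undiscounted cost-efficiency figures are always computed at rate 0.
    """

    scenario_name: str
    config: ModelConfig = field(repr=False)
    ledger: CostLedger = field(repr=False)
    effects: pd.DataFrame = field(repr=False)
    metrics: dict[float, dict[str, Any]]
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def rates(self) -> list[float]:
        return sorted(self.metrics)

    def metric(self, name: str, rate: float = 0.0):
        return self.metrics[rate][name]

    def annual_average(self, name: str, rate: float = 0.0) -> float:
        """Per-year average of a horizon total (effects or DALYs)."""
        value = self.metrics[rate][name]
        horizon = self.config.design.horizon_years
        if isinstance(value, dict):
            return {k: v / horizon for k, v in value.items()}
        return value / horizon

    def summary(self) -> str:
        """Plain-text summary table in the style of the headline results."""
        lines = [
            f"SQ-LNS cost-effectiveness results — scenario "
            f"'{self.scenario_name}'",
            "=" * 64,
        ]
        comp = self.ledger.per_child_components()
        lines += [
            "Cost-efficiency (2020 USD, undiscounted)",
            f"  cost per child, product            {comp['product']:10.2f}",
            f"  cost per child, supply chain       "
            f"{comp['product_supply_chain']:10.2f}",
            f"  cost per child, non-product        "
            f"{comp['nonproduct_programmatic']:10.2f}",
            f"  cost per child, total              {comp['total']:10.2f}",
            f"  average annual cost (million USD)  "
            f"{self.metric('average_annual_cost') / 1e6:10.2f}",
            "",
        ]
        for rate in self.rates:
            m = self.metrics[rate]
            lines.append(f"Cost-effectiveness at discount rate "
                         f"{rate:.0%} (totals over "
                         f"{self.config.design.horizon_years} years)")
            avg = {k: v / self.config.design.horizon_years
                   for k, v in m["effects_averted"].items()}
            lines.append(f"  deaths averted per year            "
                         f"{avg.get('mortality', 0.0):10.0f}")
            lines.append(f"  DALYs averted per year             "
                         f"{m['dalys_averted'] / self.config.design.horizon_years:10.0f}")
            for label, key in (("cost per DALY averted",
                                "cost_per_daly"),
                               ("cost per death averted",
                                "cost_per_death")):
                value = m[key]
                text = "absent" if value is None else f"{value:10.0f}"
                lines.append(f"  {label:<34} {text}")
            lines.append("")
        if self.metadata:
            lines.append("Metadata / review flags:")
            for key, value in self.metadata.items():
                lines.append(f"  {key}: {value}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The model


class SqlnsCeaModel:
    """Deterministic SQ-LNS cost-effectiveness model for a district set.

    Parameters
    ----------
    config : ModelConfig
        Full parameter set (validated at construction).
    districts : list of DistrictProfile
        Rural districts receiving the intervention.
    items : list of ActivityCostItem
        Base-district activity costs to extrapolate.
    cohorts : CohortProjection
        Annual eligible-child counts, one per intervention year.
    base : DistrictProfile, optional
        Extrapolation base; defaults to the district named ``Namutumba``.
    """

    def __init__(self, config: ModelConfig,
                 districts: list[DistrictProfile],
                 items: list[ActivityCostItem],
                 cohorts: CohortProjection,
                 base: DistrictProfile | None = None):
        problems = validate(config)
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))
        self.config = config
        self.districts = list(districts)
        self.items = list(items)
        self.cohorts = cohorts
        self.base = base

    def fit(self, rates: tuple[float, ...] | None = None) -> CeaResults:
        """Run the full pipeline and return results at each discount rate.

        Default rates are 0 and the configured discount rate (the two
        reported scenarios). Identical inputs give identical outputs.
        """
        config = self.config
        if rates is None:
            rates = tuple(sorted({0.0, config.discount.rate}))
        ledger = build_cost_ledger(config, self.districts, self.items,
                                   self.cohorts, base=self.base)
        effects = annual_effect_table(config, self.cohorts)
        ref = config.discount.reference_year

        metrics: dict[float, dict[str, Any]] = {}
        for rate in rates:
            year_factor = {
                y: (1.0 + rate) ** -(y - ref) for y in self.cohorts.years
            }
            eff_totals: dict[str, float] = {}
            for outcome, group in effects.groupby("outcome"):
                eff_totals[outcome] = float(sum(
                    row["cases_averted"] * year_factor[row["year"]]
                    for _, row in group.iterrows()
                ))
            daly_rows = dalys_averted(effects, config, rate)
            daly_total = sum(
                r.total_dalys_averted * year_factor[r.year]
                for r in daly_rows
            )
            total_cost = ledger.discounted_total(rate, ref)
            metrics[rate] = {
                "total_cost": total_cost,
                "average_annual_cost": ledger.average_annual_total(),
                "cost_per_child": ledger.cost_per_child(),
                "effects_averted": eff_totals,
                "dalys_averted": daly_total,
                "cost_per_daly": cer(total_cost, daly_total),
                "cost_per_death": cer(total_cost,
                                      eff_totals.get("mortality", 0.0)),
                "cost_per_case": {
                    name: cer(total_cost, value)
                    for name, value in eff_totals.items()
                },
            }
        metadata = {
            "remaining_life_expectancy_years":
                config.life_table.remaining_life_expectancy_years,
            "dev_disability_weight":
                config.outcome("developmental_disability").disability_weight
                if any(o.name == "developmental_disability"
                       for o in config.outcomes) else None,
            "anaemia_severity_split": config.anaemia_severity_split,
            "review_note": (
                "remaining life expectancy, anaemia severity split and the "
                "developmental-disability weight are modelling defaults, "
                "not published inputs; review before policy use"
            ),
        }
        return CeaResults(
            scenario_name=config.scenario_name,
            config=config,
            ledger=ledger,
            effects=effects,
            metrics=metrics,
            metadata=metadata,
        )


def run_model(config: ModelConfig, districts: list[DistrictProfile],
              items: list[ActivityCostItem],
              cohorts: CohortProjection,
              base: DistrictProfile | None = None) -> CeaResults:
    """Convenience wrapper: construct the model and fit it."""
    return SqlnsCeaModel(config, districts, items, cohorts, base=base).fit()


def run_sensitivity(config: ModelConfig,
                    scenarios: list[ScenarioSpec],
                    districts: list[DistrictProfile],
                    items: list[ActivityCostItem],
                    cohorts: CohortProjection) -> pd.DataFrame:
    """One row of headline ratios per scenario, base case first.

    Scenario order is preserved; duplicate scenario names are rejected.
    """
    if not scenarios:
        raise ValueError("at least one scenario required")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate scenario names: {', '.join(dupes)}")

    rows = []
    results = [("base", run_model(config, districts, items, cohorts))]
    for spec in scenarios:
        scenario_config = apply_scenario(config, spec)
        results.append(
            (spec.name, run_model(scenario_config, districts, items,
                                  cohorts)))
    for name, res in results:
        rate_disc = max(res.rates)
        m0, md = res.metrics[0.0], res.metrics[rate_disc]
        rows.append({
            "scenario": name,
            "cost_per_child": m0["cost_per_child"],
            "average_annual_cost": m0["average_annual_cost"],
            "deaths_averted_per_year":
                m0["effects_averted"].get("mortality", 0.0)
                / config.design.horizon_years,
            "dalys_averted_per_year":
                m0["dalys_averted"] / config.design.horizon_years,
            "cost_per_daly": m0["cost_per_daly"],
            "cost_per_death": m0["cost_per_death"],
            "cost_per_daly_discounted": md["cost_per_daly"],
            "cost_per_death_discounted": md["cost_per_death"],
        })
    return pd.DataFrame(rows)


def apply_targeting(
    districts: list[DistrictProfile],
    selected_sub_regions: list[str] | tuple[str, ...],
    config: ModelConfig,
    items: list[ActivityCostItem],
    cohorts: CohortProjection,
    base: DistrictProfile | None = None,
) -> tuple[list[DistrictProfile], CeaResults, dict[str, float]]:
    """Restrict the programme to districts in the selected sub-regions.

    The cohort projection is scaled by the selected districts' share of
    eligible children and the full model re-run on the subset; the
    comparison dict reports that share and the targeted-to-untargeted
    cost ratio. The extrapolation base district keeps its role even if its
    sub-region is not selected.
    """
    if not selected_sub_regions:
        raise ValueError("at least one sub-region must be selected")
    available = {d.sub_region for d in districts}
    missing = set(selected_sub_regions) - available
    if missing:
        raise ValueError(
            f"sub-region(s) not in district table: {', '.join(sorted(missing))}")

    subset = [d for d in districts if d.sub_region in selected_sub_regions]
    if base is None:
        base = next((d for d in districts if d.name == "Namutumba"),
                    districts[0])
    share = (sum(d.eligible_children for d in subset)
             / sum(d.eligible_children for d in districts))

    full = run_model(config, districts, items, cohorts, base=base)
    targeted = run_model(config, subset, items, cohorts.scaled(share),
                         base=base)
    comparison = {
        "cohort_share": share,
        "cost_ratio": (targeted.metric("average_annual_cost")
                       / full.metric("average_annual_cost")),
        "untargeted_average_annual_cost":
            full.metric("average_annual_cost"),
        "targeted_average_annual_cost":
            targeted.metric("average_annual_cost"),
    }
    return subset, targeted, comparison
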