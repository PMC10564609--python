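"""Programme cost model: product, supply chain, incentives and
activity-based costs extrapolated from a base district.

Costs have three layers:

* analytic per-child components — product price (carton price / sachets per
  carton x 365 sachets/child-year), the per-kg supply chain (international
  shipping + customs clearance + domestic transport, storage and handling),
  and quarterly VHT delivery incentives;
* activity-based programmatic costs — base-district (Namutumba-like) costs
  per activity x input category x phase, extrapolated to every rural
  district through one of four indices (district area, eligible-child
  population, VHT count, or VHT-to-child ratio, each relative to the base
  district);
* a year dimension — start-up activities occur once in the start-up year(s);
  recurring activities, product, supply chain and incentives occur in each
  intervention year, the per-child pieces scaled by that year's cohort.

"Average annual" figures annualise start-up costs by spreading them evenly
over the intervention horizon. All monetary values are 2020 USD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .demography import CohortProjection
from .parameters import CostParameters, InterventionDesign, ModelConfig, validate

__all__ = [
    "ACTIVITIES", "INPUT_CATEGORIES", "INDEX_KINDS", "PHASES",
    "DistrictProfile", "ActivityCostItem", "CostLedger",
    "cost_per_sachet", "product_cost_per_child",
    "annual_product_mass_kg", "supply_chain_cost_per_child",
    "shipping_customs_cost_per_child", "incentive_cost_per_child",
    "extrapolation_index", "scale_activity_costs", "build_cost_ledger",
    "read_districts", "write_districts",
    "read_activity_items", "write_activity_items",
]

ACTIVITIES = (
    "sbcc", "capacity_building", "logistics", "monitoring_evaluation",
    "overhead", "capital", "caregiver_opportunity", "vht_incentives",
    "product", "product_supply_chain",
)
INPUT_CATEGORIES = ("personnel", "transport", "materials", "in_kind", "other")
INDEX_KINDS = ("spatial", "child_pop", "vht_pop", "vht_child_ratio", "none")
PHASES = ("startup", "recurring")


@dataclass(frozen=True)
class DistrictProfile:
    """One rural district's size, eligible children and VHT workforce."""

    name: str
    area_km2: float
    eligible_children: float
    vht_count: float
    sub_region: str

    def __post_init__(self) -> None:
        if self.area_km2 <= 0 or self.eligible_children <= 0 \
                or self.vht_count <= 0:
            raise ValueError(
                f"district {self.name!r}: area, children and VHT count "
                "must be positive"
            )


@dataclass(frozen=True)
class ActivityCostItem:
    """One base-district cost line: activity x input x phase x index kind."""

    activity: str
    input_category: str
    phase: str
    base_cost_usd: float
    index_kind: str

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.input_category not in INPUT_CATEGORIES:
            raise ValueError(
                f"unknown input category {self.input_category!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.index_kind not in INDEX_KINDS:
            raise ValueError(f"unknown index kind {self.index_kind!r}")
        if self.base_cost_usd < 0:
            raise ValueError("base_cost_usd must be >= 0")


# ---------------------------------------------------------------------------
# Analytic per-child components


def cost_per_sachet(costs: CostParameters) -> float:
    """2020 USD per 20-g sachet: carton price / sachets per carton."""
    if costs.sachets_per_carton <= 0:
        raise ValueError("sachets_per_carton must be positive")
    return costs.price_per_carton_usd / costs.sachets_per_carton


def product_cost_per_child(costs: CostParameters,
                           design: InterventionDesign) -> float:
    """Product cost of one child-year of daily supplementation."""
    return cost_per_sachet(costs) * design.sachets_per_day * 365


def annual_product_mass_kg(design: InterventionDesign) -> float:
    """Mass of SQ-LNS consumed per child-year, in kg."""
    return 365 * design.sachets_per_day * design.sachet_mass_g / 1000.0


def supply_chain_cost_per_child(costs: CostParameters,
                                design: InterventionDesign) -> float:
    """Shipping + customs + domestic transport per child-year."""
    rate = (costs.intl_shipping_usd_per_kg + costs.customs_usd_per_kg
            + costs.domestic_usd_per_kg)
    return rate * annual_product_mass_kg(design)


def shipping_customs_cost_per_child(costs: CostParameters,
                                    design: InterventionDesign) -> float:
    """International shipping + customs only (the headline share excludes
    domestic transport, storage and handling)."""
    rate = costs.intl_shipping_usd_per_kg + costs.customs_usd_per_kg
    return rate * annual_product_mass_kg(design)


def incentive_cost_per_child(costs: CostParameters,
                             design: InterventionDesign) -> float:
    """VHT delivery incentives per child-year."""
    return costs.vht_incentive_usd_per_delivery * design.deliveries_per_year


# ---------------------------------------------------------------------------
# District extrapolation


def extrapolation_index(district: DistrictProfile, base: DistrictProfile,
                        kind: str) -> float:
    """Scale factor for a district's activity cost relative to the base.

    ``spatial`` scales with district area, ``child_pop`` with eligible
    children, ``vht_pop`` with VHT count, ``vht_child_ratio`` with the
    VHT-per-child ratio, and ``none`` applies the base cost unchanged.
    """
    if kind == "none":
        return 1.0
    if kind == "spatial":
        num, den = district.area_km2, base.area_km2
    elif kind == "child_pop":
        num, den = district.eligible_children, base.eligible_children
    elif kind == "vht_pop":
        num, den = district.vht_count, base.vht_count
    elif kind == "vht_child_ratio":
        num = district.vht_count / district.eligible_children
        den = base.vht_count / base.eligible_children
    else:
        raise ValueError(f"unknown index kind {kind!r}")
    if den <= 0:
        raise ValueError(f"base value for index {kind!r} must be positive")
    return num / den


def scale_activity_costs(
    items: list[ActivityCostItem],
    districts: list[DistrictProfile],
    base: DistrictProfile,
    require_base: bool = True,
) -> pd.DataFrame:
    """Extrapolate base-district items to every district.

    Returns a tidy frame (district, activity, phase, cost_usd) with item
    costs summed within activity x phase. ``require_base=False`` permits a
    base profile outside the district list (used when a geographic subset
    excludes the base district but its cost structure still anchors the
    indices).
    """
    if require_base and base.name not in {d.name for d in districts}:
        raise ValueError(
            f"base district {base.name!r} not present in district list")
    rows = []
    for d in districts:
        for item in items:
            idx = extrapolation_index(d, base, item.index_kind)
            rows.append((d.name, item.activity, item.phase,
                         item.base_cost_usd * idx))
    df = pd.DataFrame(rows,
                      columns=["district", "activity", "phase", "cost_usd"])
    return (df.groupby(["district", "activity", "phase"], as_index=False)
              .agg(cost_usd=("cost_usd", "sum")))


# ---------------------------------------------------------------------------
# The ledger


@dataclass
class CostLedger:
    """Year x district x activity cost matrix with per-child summaries."""

    table: pd.DataFrame          # year, district, activity, cost_usd
    horizon_years: int
    average_annual_cohort: float
    config: ModelConfig = field(repr=False, default=None)

    def total(self) -> float:
        """Grand total over all years (start-up included once)."""
        return float(self.table["cost_usd"].sum())

    def annual_totals(self) -> pd.Series:
        return self.table.groupby("year")["cost_usd"].sum()

    def average_annual_total(self) -> float:
        """Average cost per intervention year, start-up annualised."""
        return self.total() / self.horizon_years

    def cost_per_child(self) -> float:
        """Cost-efficiency: average annual total / average annual cohort."""
        if self.average_annual_cohort <= 0:
            raise ValueError("average annual cohort must be positive")
        return self.average_annual_total() / self.average_annual_cohort

    def activity_totals(self) -> pd.Series:
        """Average annual cost by activity (start-up annualised)."""
        return (self.table.groupby("activity")["cost_usd"].sum()
                / self.horizon_years)

    def activity_shares(self) -> pd.Series:
        """Share of the average annual total by activity."""
        totals = self.activity_totals()
        return totals / totals.sum()

    def district_totals(self) -> pd.Series:
        return self.table.groupby("district")["cost_usd"].sum()

    def per_child_components(self) -> dict[str, float]:
        """Per-child breakdown mirroring the cost-efficiency summary."""
        cfg = self.config
        product = product_cost_per_child(cfg.costs, cfg.design)
        supply = supply_chain_cost_per_child(cfg.costs, cfg.design)
        total = self.cost_per_child()
        return {
            "product": product,
            "product_supply_chain": supply,
            "nonproduct_programmatic": total - product - supply,
            "total": total,
        }

    def discounted_total(self, rate: float, reference_year: int) -> float:
        """Present value of the full cost stream at the reference year."""
        if rate < 0:
            raise ValueError("rate must be >= 0")
        annual = self.annual_totals()
        factors = (1.0 + rate) ** -(annual.index.values - reference_year)
        return float((annual.values * factors).sum())

    def to_file(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_cost_ledger(
    config: ModelConfig,
    districts: list[DistrictProfile],
    items: list[ActivityCostItem],
    cohorts: CohortProjection,
    base: DistrictProfile | None = None,
) -> CostLedger:
    """Assemble the full year x district x activity cost ledger.

    ``base`` defaults to the first district named ``Namutumba`` (or the
    first district) and is the reference for every extrapolation index.
    """
    if not districts:
        raise ValueError("district list must not be empty")
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    if len(cohorts.years) != config.design.horizon_years:
        raise ValueError(
            f"cohort projection covers {len(cohorts.years)} years but the "
            f"design horizon is {config.design.horizon_years}"
        )
    explicit_base = base is not None
    if base is None:
        base = next((d for d in districts if d.name == "Namutumba"),
                    districts[0])

    design, costs = config.design, config.costs
    startup_years = list(range(design.start_year,
                               design.start_year + design.startup_years))
    intervention_years = sorted(cohorts.years)

    ppc_product = product_cost_per_child(costs, design)
    ppc_supply = supply_chain_cost_per_child(costs, design)
    ppc_incentive = incentive_cost_per_child(costs, design)

    total_children = sum(d.eligible_children for d in districts)
    shares = {d.name: d.eligible_children / total_children for d in districts}

    scaled = scale_activity_costs(
        items, districts, base, require_base=not explicit_base
    ) if items else \
        pd.DataFrame(columns=["district", "activity", "phase", "cost_usd"])
    startup_rows = scaled[scaled["phase"] == "startup"]
    recurring_rows = scaled[scaled["phase"] == "recurring"]

    records: list[tuple[int, str, str, float]] = []
    for year in startup_years:
        for _, r in startup_rows.iterrows():
            records.append((year, r["district"], r["activity"],
                            r["cost_usd"] / design.startup_years))
    for year in intervention_years:
        cohort = cohorts.years[year]
        for d in districts:
            n = cohort * shares[d.name]
            records.append((year, d.name, "product", ppc_product * n))
            records.append((year, d.name, "product_supply_chain",
                            ppc_supply * n))
            records.append((year, d.name, "vht_incentives",
                            ppc_incentive * n))
        for _, r in recurring_rows.iterrows():
            records.append((year, r["district"], r["activity"],
                            r["cost_usd"]))

    table = pd.DataFrame(
        records, columns=["year", "district", "activity", "cost_usd"])
    table = (table.groupby(["year", "district", "activity"], as_index=False)
                  .agg(cost_usd=("cost_usd", "sum"))
                  .sort_values(["year", "district", "activity"])
                  .reset_index(drop=True))
    return CostLedger(
        table=table,
        horizon_years=design.horizon_years,
        average_annual_cohort=cohorts.average_annual_cohort,
        config=config,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O

_DISTRICT_COLS = ["name", "area_km2", "eligible_children", "vht_count",
                  "sub_region"]
_ITEM_COLS = ["activity", "input_category", "phase", "base_cost_usd",
              "index_kind"]


def read_districts(path) -> list[DistrictProfile]:
    df = pd.read_csv(path)
    missing = set(_DISTRICT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"district table missing columns: {missing}")
    return [
        DistrictProfile(r["name"], float(r["area_km2"]),
                        float(r["eligible_children"]), float(r["vht_count"]),
                        r["sub_region"])
        for _, r in df.iterrows()
    ]


def write_districts(districts: list[DistrictProfile], path) -> None:
    pd.DataFrame(
        [(d.name, d.area_km2, d.eligible_children, d.vht_count, d.sub_region)
         for d in districts],
        columns=_DISTRICT_COLS,
    ).to_csv(path, index=False)


def read_activity_items(path) -> list[ActivityCostItem]:
    df = pd.read_csv(path)
    missing = set(_ITEM_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"activity-cost table missing columns: {missing}")
    return [
        ActivityCostItem(r["activity"], r["input_category"], r["phase"],
                         float(r["base_cost_usd"]), r["index_kind"])
        for _, r in df.iterrows()
    ]


def write_activity_items(items: list[ActivityCostItem], path) -> None:
    pd.DataFrame(
        [(i.activity, i.input_category, i.phase, i.base_cost_usd,
          i.index_kind) for i in items],
        columns=_ITEM_COLS,
    ).to_csv(path, index=False)
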