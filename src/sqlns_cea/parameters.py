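"""Validated model parameters and the default rural-Uganda parameterisation.

The model estimates the cost and cost-effectiveness of providing daily
small-quantity lipid-based nutrient supplements (SQ-LNS, 20 g/d) to children
6-18 months of age in rural Uganda, delivered through the Village Health
Team (VHT) volunteer system. Every tunable quantity lives in a
:class:`ModelConfig`: intervention design, per-outcome effectiveness
parameters, unit costs, discounting, and the life-table input used for
years-of-life-lost.

Configs round-trip through a strict YAML document (unknown keys are an
error); the packaged ``data/uganda_2020.config`` encodes
:func:`default_uganda_config`.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

__all__ = [
    "InterventionDesign",
    "OutcomeSpec",
    "CostParameters",
    "DiscountSpec",
    "LifeTable",
    "ModelConfig",
    "OUTCOME_NAMES",
    "MODERATE_ANAEMIA_WEIGHT",
    "SEVERE_ANAEMIA_WEIGHT",
    "default_uganda_config",
    "derived_dev_disability_baseline",
    "validate",
    "load_config",
    "save_config",
]

#: GBD disability weights for moderate and severe anaemia; the anaemia YLD
#: weight is their average weighted by the moderate/severe severity split.
MODERATE_ANAEMIA_WEIGHT = 0.052
SEVERE_ANAEMIA_WEIGHT = 0.149

#: Sentinel for "duration of disability equals remaining life expectancy".
REMAINING_LIFE = "remaining_life_expectancy"

OUTCOME_NAMES = (
    "mortality",
    "anaemia_mod_sev",
    "developmental_disability",
    "stunting",
    "wasting_cross_sectional",
    "wasting_longitudinal",
)

ANAEMIA_PERSON_BASES = ("band_occupancy", "full_cohort_per_band")


@dataclass
class InterventionDesign:
    """Who receives SQ-LNS, for how long, and over what programme horizon."""

    start_age_months: int = 6
    duration_months: int = 12
    sachets_per_day: int = 1
    sachet_mass_g: float = 20.0
    deliveries_per_year: int = 4
    start_year: int = 2021
    horizon_years: int = 10
    startup_years: int = 1


@dataclass
class OutcomeSpec:
    """One health outcome: baseline burden, effect size and effect window.

    ``baseline`` is either a single prevalence/risk fraction applied across
    the whole effect window, or a mapping of ``(start_month, end_month)``
    age bands to band-specific prevalences (used for anaemia).
    ``disability_weight`` / ``disability_duration_years`` are present only
    for outcomes counted in DALYs; duration may be the sentinel
    ``"remaining_life_expectancy"``. ``correction_factors`` holds the
    (lower, upper) cross-sectional-to-longitudinal multipliers for
    longitudinal wasting.
    """

    name: str
    baseline: float | dict[tuple[int, int], float]
    relative_reduction: float
    effect_window: tuple[int, int]
    counted_in_dalys: bool = False
    disability_weight: float | None = None
    disability_duration_years: float | str | None = None
    correction_factors: tuple[float, float] | None = None


@dataclass
class CostParameters:
    """Unit costs of the product and its supply chain, in 2020 USD."""

    price_per_carton_usd: float = 33.30
    sachets_per_carton: int = 546
    intl_shipping_usd_per_kg: float = 0.31
    customs_usd_per_kg: float = 1.01
    domestic_usd_per_kg: float = 0.17
    vht_incentive_usd_per_delivery: float = 0.44
    #: year -> implicit GDP price deflator relative to 2020; applied only
    #: when ingesting base activity costs quoted in non-2020 dollars.
    deflator_table: dict[int, float] = field(default_factory=dict)


@dataclass
class DiscountSpec:
    """Annual discount rate and the year future flows are discounted to."""

    rate: float = 0.03
    reference_year: int = 2021


@dataclass
class LifeTable:
    """Remaining life expectancy at the modelled age of death/onset.

    Not printed in the source material for Uganda; defaults to 62.5 years
    (approximate Ugandan remaining life expectancy in early childhood) and
    is flagged as a required-review parameter in output metadata.
    """

    remaining_life_expectancy_years: float = 62.5


@dataclass
class ModelConfig:
    """The full parameter set for one model run."""

    design: InterventionDesign = field(default_factory=InterventionDesign)
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    costs: CostParameters = field(default_factory=CostParameters)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    life_table: LifeTable = field(default_factory=LifeTable)
    #: (moderate, severe) fractions among moderate-or-severe anaemia cases.
    anaemia_severity_split: tuple[float, float] = (0.9, 0.1)
    #: Person base used for the 9-24-month anaemia window: age-band
    #: occupancy of the annual cohort, or the full cohort in every band.
    anaemia_person_base: str = "band_occupancy"
    scenario_name: str = "base"

    def outcome(self, name: str) -> OutcomeSpec:
        for spec in self.outcomes:
            if spec.name == name:
                return spec
        raise KeyError(f"no outcome named {name!r}")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


def derived_dev_disability_baseline(
    prev_under5: float, predictive_validity: float
) -> float:
    """Baseline developmental-disability prevalence in the effect window.

    The under-5 prevalence of developmental disability is attenuated by the
    predictive validity of the early language assessment used to detect it
    (lowest-decile language score predicting later language delay).
    """
    for label, x in (("prev_under5", prev_under5),
                     ("predictive_validity", predictive_validity)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{label} must be in [0, 1], got {x}")
    return prev_under5 * predictive_validity


def weighted_anaemia_weight(split: tuple[float, float]) -> float:
    """Anaemia disability weight averaged over the moderate/severe split."""
    moderate, severe = split
    if abs(moderate + severe - 1.0) > 1e-9 or moderate < 0 or severe < 0:
        raise ValueError(
            f"severity split must be non-negative and sum to 1, got {split}"
        )
    return MODERATE_ANAEMIA_WEIGHT * moderate + SEVERE_ANAEMIA_WEIGHT * severe


def default_uganda_config() -> ModelConfig:
    """Base-case parameterisation for rural Uganda (2020 USD).

    Effectiveness inputs: 1.22% baseline mortality risk over the 6-18-month
    supplementation window with a 27% relative reduction; moderate-or-severe
    anaemia prevalences of 59% (6-9 mo), 41% (9-18 mo) and 31% (18-24 mo)
    with a 28% reduction applied from 9 to 24 months; developmental
    disability baseline 10% x 65.6% predictive validity = 6.56% with a 16%
    reduction at 18-24 months; stunting 42% / 12%; cross-sectional wasting
    7.8% / 14%; longitudinal wasting from correction factors 2.6 and 6 with
    a 30% reduction.
    """
    split = (0.9, 0.1)
    outcomes = [
        OutcomeSpec(
            name="mortality",
            baseline=0.0122,
            relative_reduction=0.27,
            effect_window=(6, 18),
            counted_in_dalys=True,
            disability_weight=1.0,
            disability_duration_years=REMAINING_LIFE,
        ),
        OutcomeSpec(
            name="anaemia_mod_sev",
            baseline={(6, 9): 0.59, (9, 18): 0.41, (18, 24): 0.31},
            relative_reduction=0.28,
            effect_window=(9, 24),
            counted_in_dalys=True,
            disability_weight=weighted_anaemia_weight(split),
            disability_duration_years=1.25,
        ),
        OutcomeSpec(
            name="developmental_disability",
            baseline=derived_dev_disability_baseline(0.10, 0.656),
            relative_reduction=0.16,
            effect_window=(18, 24),
            counted_in_dalys=True,
            disability_weight=0.011,
            disability_duration_years=REMAINING_LIFE,
        ),
        OutcomeSpec(
            name="stunting",
            baseline=0.42,
            relative_reduction=0.12,
            effect_window=(6, 18),
        ),
        OutcomeSpec(
            name="wasting_cross_sectional",
            baseline=0.078,
            relative_reduction=0.14,
            effect_window=(6, 18),
        ),
        OutcomeSpec(
            name="wasting_longitudinal",
            baseline=0.078,
            relative_reduction=0.30,
            effect_window=(6, 18),
            correction_factors=(2.6, 6.0),
        ),
    ]
    return ModelConfig(
        design=InterventionDesign(),
        outcomes=outcomes,
        costs=CostParameters(),
        discount=DiscountSpec(rate=0.03, reference_year=2021),
        life_table=LifeTable(),
        anaemia_severity_split=split,
        scenario_name="base",
    )


# ---------------------------------------------------------------------------
# Validation


def _check_fraction(violations: list[str], label: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        violations.append(f"{label} must be in [0, 1], got {x}")


def validate(config: ModelConfig) -> list[str]:
    """Return a list of invariant violations (empty iff the config is valid).

    Violations are returned, never raised, so callers can report them all.
    """
    v: list[str] = []
    d = config.design
    for name in ("start_age_months", "duration_months", "sachets_per_day",
                 "sachet_mass_g", "deliveries_per_year", "horizon_years",
                 "startup_years"):
        if getattr(d, name) <= 0:
            v.append(f"design.{name} must be positive")
    if d.start_age_months + d.duration_months > 24:
        v.append("design: start_age_months + duration_months must be <= 24")

    seen: set[str] = set()
    for spec in config.outcomes:
        prefix = f"outcomes.{spec.name}"
        if spec.name not in OUTCOME_NAMES:
            v.append(f"{prefix}: unknown outcome name")
        if spec.name in seen:
            v.append(f"{prefix}: duplicate outcome name")
        seen.add(spec.name)
        _check_fraction(v, f"{prefix}.relative_reduction",
                        spec.relative_reduction)
        if isinstance(spec.baseline, dict):
            for band, prev in spec.baseline.items():
                _check_fraction(v, f"{prefix}.baseline[{band}]", prev)
                if not band[0] < band[1]:
                    v.append(f"{prefix}.baseline band {band} must have "
                             "start < end")
        else:
            _check_fraction(v, f"{prefix}.baseline", spec.baseline)
        if not spec.effect_window[0] < spec.effect_window[1]:
            v.append(f"{prefix}.effect_window start must be < end")
        if spec.counted_in_dalys:
            if spec.disability_weight is None:
                v.append(f"{prefix}.disability_weight required when "
                         "counted_in_dalys")
            else:
                _check_fraction(v, f"{prefix}.disability_weight",
                                spec.disability_weight)
            if spec.disability_duration_years is None:
                v.append(f"{prefix}.disability_duration_years required "
                         "when counted_in_dalys")
            elif (spec.disability_duration_years != REMAINING_LIFE
                  and spec.disability_duration_years <= 0):
                v.append(f"{prefix}.disability_duration_years must be "
                         "positive")
        else:
            if (spec.disability_weight is not None
                    or spec.disability_duration_years is not None):
                v.append(f"{prefix}: disability fields present but outcome "
                         "not counted_in_dalys")

    c = config.costs
    for name in ("price_per_carton_usd", "intl_shipping_usd_per_kg",
                 "customs_usd_per_kg", "domestic_usd_per_kg",
                 "vht_incentive_usd_per_delivery"):
        if getattr(c, name) < 0:
            v.append(f"costs.{name} must be >= 0")
    if c.sachets_per_carton <= 0:
        v.append("costs.sachets_per_carton must be positive")

    if config.discount.rate < 0:
        v.append("discount.rate must be >= 0")
    if config.life_table.remaining_life_expectancy_years <= 0:
        v.append("life_table.remaining_life_expectancy_years must be "
                 "positive")

    mod, sev = config.anaemia_severity_split
    if abs(mod + sev - 1.0) > 1e-9 or mod < 0 or sev < 0:
        v.append("anaemia_severity_split must be non-negative and sum to 1")
    if config.anaemia_person_base not in ANAEMIA_PERSON_BASES:
        v.append("anaemia_person_base must be one of "
                 f"{ANAEMIA_PERSON_BASES}")
    return v


# ---------------------------------------------------------------------------
# Config document I/O (strict YAML; unknown keys are an error)


def _band_key(band: tuple[int, int]) -> str:
    return f"{band[0]}-{band[1]}"


def _parse_band_key(key: str) -> tuple[int, int]:
    lo, hi = key.split("-")
    return int(lo), int(hi)


def _outcome_to_dict(spec: OutcomeSpec) -> dict[str, Any]:
    out: dict[str, Any] = {"name": spec.name}
    if isinstance(spec.baseline, dict):
        out["baseline"] = {_band_key(b): p for b, p in spec.baseline.items()}
    else:
        out["baseline"] = spec.baseline
    out["relative_reduction"] = spec.relative_reduction
    out["effect_window"] = list(spec.effect_window)
    out["counted_in_dalys"] = spec.counted_in_dalys
    if spec.disability_weight is not None:
        out["disability_weight"] = spec.disability_weight
    if spec.disability_duration_years is not None:
        out["disability_duration_years"] = spec.disability_duration_years
    if spec.correction_factors is not None:
        out["correction_factors"] = list(spec.correction_factors)
    return out


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    return {
        "design": dataclasses.asdict(config.design),
        "outcomes": [_outcome_to_dict(s) for s in config.outcomes],
        "costs": dataclasses.asdict(config.costs),
        "discount": dataclasses.asdict(config.discount),
        "life_table": dataclasses.asdict(config.life_table),
        "anaemia_severity_split": list(config.anaemia_severity_split),
        "anaemia_person_base": config.anaemia_person_base,
        "scenario_name": config.scenario_name,
    }


def _strict_kwargs(cls, data: dict[str, Any], context: str) -> dict[str, Any]:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in {context}: {', '.join(sorted(unknown))}"
        )
    return data


def _outcome_from_dict(data: dict[str, Any]) -> OutcomeSpec:
    data = dict(data)
    _strict_kwargs(OutcomeSpec, data, f"outcome {data.get('name', '?')!r}")
    if isinstance(data.get("baseline"), dict):
        data["baseline"] = {
            _parse_band_key(k): v for k, v in data["baseline"].items()
        }
    if "effect_window" in data:
        data["effect_window"] = tuple(data["effect_window"])
    if data.get("correction_factors") is not None:
        data["correction_factors"] = tuple(data["correction_factors"])
    return OutcomeSpec(**data)


def config_from_dict(data: dict[str, Any]) -> ModelConfig:
    data = dict(data)
    _strict_kwargs(ModelConfig, data, "config")
    kwargs: dict[str, Any] = {}
    if "design" in data:
        kwargs["design"] = InterventionDesign(
            **_strict_kwargs(InterventionDesign, data["design"], "design"))
    if "outcomes" in data:
        kwargs["outcomes"] = [_outcome_from_dict(o) for o in data["outcomes"]]
    if "costs" in data:
        costs = dict(data["costs"])
        _strict_kwargs(CostParameters, costs, "costs")
        if "deflator_table" in costs:
            costs["deflator_table"] = {
                int(k): float(x) for k, x in costs["deflator_table"].items()
            }
        kwargs["costs"] = CostParameters(**costs)
    if "discount" in data:
        kwargs["discount"] = DiscountSpec(
            **_strict_kwargs(DiscountSpec, data["discount"], "discount"))
    if "life_table" in data:
        kwargs["life_table"] = LifeTable(
            **_strict_kwargs(LifeTable, data["life_table"], "life_table"))
    if "anaemia_severity_split" in data:
        kwargs["anaemia_severity_split"] = tuple(
            data["anaemia_severity_split"])
    for key in ("anaemia_person_base", "scenario_name"):
        if key in data:
            kwargs[key] = data[key]
    return ModelConfig(**kwargs)


def save_config(config: ModelConfig, path) -> None:
    """Write a config as a hierarchical YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    """Read a config document; unknown keys raise ValueError (fail fast)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def packaged_uganda_config() -> ModelConfig:
    """Load the bundled ``uganda_2020.config`` document."""
    ref = resources.files("sqlns_cea").joinpath("data/uganda_2020.config")
    with resources.as_file(ref) as path:
        return load_config(path)
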