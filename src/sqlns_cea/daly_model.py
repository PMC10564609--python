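"""DALYs averted: years of life lost plus years lived with disability.

DALYs averted are the sum of years of life lost (YLL) from deaths averted
and years lived with disability (YLD) from cases of moderate-or-severe
anaemia and developmental disability averted. Each component is
cases x duration x disability weight; death uses weight 1 and duration
equal to remaining life expectancy L. Stunting and wasting carry no
disability weight (stunting is not a GBD disability; moderate wasting's
weight is zero) and mild anaemia is excluded, so none of them contribute.

Discounting uses the continuous-time factor without age weighting: a
stream of one year of healthy life over ``duration`` years discounted at
rate r has present value (1/r)(1 - e^(-r.duration)). Within a model year
all of that year's effects share the year's discount factor; cross-year
discounting is applied by the scenario layer so costs and effects use
identical year factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .parameters import (
    REMAINING_LIFE,
    ModelConfig,
    weighted_anaemia_weight,
)

__all__ = ["DalyResult", "weighted_anaemia_weight", "burden_years",
           "dalys_averted"]


@dataclass(frozen=True)
class DalyResult:
    """DALYs averted in one model year at one discount rate."""

    year: int
    yll_averted: float
    yld_averted_by_outcome: dict[str, float]
    discount_rate: float

    @property
    def total_dalys_averted(self) -> float:
        return self.yll_averted + sum(self.yld_averted_by_outcome.values())


def burden_years(cases: float, duration: float, weight: float,
                 r: float = 0.0) -> float:
    """Disability burden in years for ``cases`` of a health state.

    Undiscounted: cases x duration x weight. Discounted at r > 0:
    cases x weight x (1/r)(1 - e^(-r.duration)). YLL is the special case
    weight = 1, duration = remaining life expectancy.
    """
    if cases < 0 or duration <= 0 or r < 0:
        raise ValueError("cases >= 0, duration > 0 and r >= 0 required")
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {weight}")
    if r == 0.0:
        return cases * duration * weight
    # -expm1(-r*d)/r is stable as r -> 0+ (plain exp cancels catastrophically)
    return cases * weight * -math.expm1(-r * duration) / r


def _duration_years(spec_duration, life_expectancy: float) -> float:
    if spec_duration == REMAINING_LIFE:
        return life_expectancy
    return float(spec_duration)


def dalys_averted(effects: pd.DataFrame, config: ModelConfig,
                  rate: float = 0.0) -> list[DalyResult]:
    """Convert an annual effect table into per-year DALYs averted.

    ``rate`` applies the within-duration discount to each case's burden
    stream; it does not apply cross-year factors (see module docstring).
    The anaemia disability weight is always derived from the configured
    moderate/severe severity split.
    """
    life = config.life_table.remaining_life_expectancy_years
    results: list[DalyResult] = []
    for year, group in effects.groupby("year"):
        yll = 0.0
        yld: dict[str, float] = {}
        for _, row in group.iterrows():
            name = row["outcome"]
            try:
                spec = config.outcome(name)
            except KeyError:
                continue  # derived rows (e.g. longitudinal wasting bounds)
            if not spec.counted_in_dalys:
                continue
            duration = _duration_years(spec.disability_duration_years, life)
            if name == "mortality":
                yll = burden_years(row["cases_averted"], duration, 1.0, rate)
            else:
                if name == "anaemia_mod_sev":
                    weight = weighted_anaemia_weight(
                        config.anaemia_severity_split)
                else:
                    weight = spec.disability_weight
                yld[name] = burden_years(
                    row["cases_averted"], duration, weight, rate)
        results.append(DalyResult(int(year), yll, yld, rate))
    return results


def daly_table(results: list[DalyResult]) -> pd.DataFrame:
    """Tidy export: year, component, years_averted, discount_rate."""
    rows = []
    for r in results:
        rows.append((r.year, "yll", r.yll_averted, r.discount_rate))
        for name, years in r.yld_averted_by_outcome.items():
            rows.append((r.year, f"yld_{name}", years, r.discount_rate))
        rows.append((r.year, "total", r.total_dalys_averted, r.discount_rate))
    return pd.DataFrame(
        rows, columns=["year", "component", "years_averted", "discount_rate"])
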