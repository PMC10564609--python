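"""Deaths and cases averted: baseline x relative reduction x population.

Each outcome's annual effect is the baseline prevalence (or risk) of the
adverse outcome, multiplied by the relative reduction attributable to
SQ-LNS, multiplied by the population resident in the outcome's effect
window that year. Mortality, stunting and wasting use the full 6-18-month
supplementation window (i.e. the whole annual cohort); anaemia uses its
band-specific prevalences over 9-24 months; developmental disability uses
the 18-24-month band. Longitudinal wasting is reported as a (lower, upper)
pair from the two cross-sectional-to-longitudinal correction factors and is
never summed with the cross-sectional estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .demography import AgeBand, CohortProjection, band_person_count
from .parameters import ModelConfig, OutcomeSpec, validate

__all__ = ["EffectResult", "averted", "longitudinal_prevalence",
           "deaths_averted", "annual_effect_table"]


@dataclass(frozen=True)
class EffectResult:
    """Cases (or deaths) averted for one outcome in one year."""

    outcome: str
    year: int
    population_base: float
    cases_averted: float


def averted(baseline: float, relative_reduction: float,
            population: float) -> float:
    """Cases averted = baseline x relative reduction x population."""
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline must be in [0, 1], got {baseline}")
    if not 0.0 <= relative_reduction <= 1.0:
        raise ValueError(
            f"relative_reduction must be in [0, 1], got {relative_reduction}")
    if population < 0:
        raise ValueError("population must be >= 0")
    return baseline * relative_reduction * population


def longitudinal_prevalence(cross_sectional: float,
                            correction_factor: float) -> float:
    """Longitudinal (cumulative-episode) wasting prevalence.

    Point-in-time prevalence underestimates the share of children who
    experience a wasting episode; a correction factor (2.6-6) converts
    cross-sectional to longitudinal prevalence.
    """
    if cross_sectional < 0 or correction_factor < 0:
        raise ValueError("inputs must be >= 0")
    prev = cross_sectional * correction_factor
    if prev > 1.0:
        raise ValueError(
            f"corrected prevalence {prev:.3f} exceeds 1; "
            "correction factor too large for this baseline"
        )
    return prev


def deaths_averted(config: ModelConfig, cohort: float) -> float:
    """Annual deaths averted by supplementing one annual cohort."""
    spec = config.outcome("mortality")
    return averted(spec.baseline, spec.relative_reduction, cohort)


def _banded_effect(spec: OutcomeSpec, cohort: float,
                   config: ModelConfig) -> tuple[float, float]:
    """(population base, cases averted) summed over the outcome's bands."""
    design = config.design
    window_lo, window_hi = spec.effect_window
    if isinstance(spec.baseline, dict):
        bands = spec.baseline.items()
    else:
        bands = [((window_lo, window_hi), spec.baseline)]
    pop_total = 0.0
    cases = 0.0
    for (lo, hi), prevalence in bands:
        lo, hi = max(lo, window_lo), min(hi, window_hi)
        if hi <= lo:
            continue
        if (spec.name == "anaemia_mod_sev"
                and config.anaemia_person_base == "full_cohort_per_band"):
            pop = cohort
        else:
            pop = band_person_count(cohort, AgeBand(lo, hi), design)
        pop_total += pop
        cases += averted(prevalence, spec.relative_reduction, pop)
    return pop_total, cases


def annual_effect_table(config: ModelConfig,
                        cohorts: CohortProjection) -> pd.DataFrame:
    """Per-year, per-outcome effects as a tidy frame.

    Columns: year, outcome, population_base, cases_averted. Longitudinal
    wasting appears as two rows per year, ``wasting_longitudinal_lower``
    and ``wasting_longitudinal_upper``.
    """
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    rows: list[EffectResult] = []
    for year in sorted(cohorts.years):
        cohort = cohorts.years[year]
        for spec in config.outcomes:
            if spec.name == "wasting_longitudinal":
                lo_f, hi_f = spec.correction_factors or (1.0, 1.0)
                for label, factor in (("lower", lo_f), ("upper", hi_f)):
                    prev = longitudinal_prevalence(spec.baseline, factor)
                    rows.append(EffectResult(
                        outcome=f"wasting_longitudinal_{label}",
                        year=year,
                        population_base=cohort,
                        cases_averted=averted(
                            prev, spec.relative_reduction, cohort),
                    ))
                continue
            pop, cases = _banded_effect(spec, cohort, config)
            rows.append(EffectResult(spec.name, year, pop, cases))
    return pd.DataFrame(
        [(r.year, r.outcome, r.population_base, r.cases_averted)
         for r in rows],
        columns=["year", "outcome", "population_base", "cases_averted"],
    )
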