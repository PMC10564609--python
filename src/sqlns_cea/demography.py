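"""Cohort projections and steady-state age-band occupancy.

The effectiveness and cost models both need "how many children are resident
in a given month-of-age band in a given year". The annual eligible cohort is
assumed uniformly distributed over the supplementation months (steady
state), so each one-month age slice holds ``annual_cohort / duration_months``
children; bands outside the supplementation window (e.g. 18-24 months for
developmental disability and late anaemia) use the same slice size — the
cohort that has aged out of supplementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .parameters import InterventionDesign

__all__ = ["AgeBand", "CohortProjection", "monthly_cohort",
           "band_person_count", "band_person_count_bruteforce"]


@dataclass(frozen=True)
class AgeBand:
    """Half-open month-of-age interval [start_month, end_month)."""

    start_month: int
    end_month: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_month < self.end_month <= 60:
            raise ValueError(
                f"age band must satisfy 0 <= start < end <= 60, got "
                f"[{self.start_month}, {self.end_month})"
            )

    @property
    def width_months(self) -> int:
        return self.end_month - self.start_month


@dataclass
class CohortProjection:
    """Annual eligible-child counts (children aged 6-18 months per year)."""

    years: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, n in self.years.items():
            if n < 0:
                raise ValueError(f"cohort for {year} must be >= 0, got {n}")

    @property
    def average_annual_cohort(self) -> float:
        if not self.years:
            return 0.0
        return sum(self.years.values()) / len(self.years)

    def scaled(self, factor: float) -> "CohortProjection":
        return CohortProjection({y: n * factor for y, n in self.years.items()})

    @classmethod
    def from_file(cls, path) -> "CohortProjection":
        """Read a two-column delimited file (year, eligible_children)."""
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["year", "eligible_children"]:
            raise ValueError(
                "cohort file must have columns year, eligible_children; "
                f"got {list(df.columns)}"
            )
        return cls(dict(zip(df["year"].astype(int),
                            df["eligible_children"].astype(float))))

    def to_file(self, path) -> None:
        pd.DataFrame(
            {"year": sorted(self.years),
             "eligible_children": [self.years[y] for y in sorted(self.years)]}
        ).to_csv(path, index=False)


def monthly_cohort(annual_cohort: float,
                   design: InterventionDesign) -> float:
    """Children per one-month age slice at steady state."""
    if annual_cohort < 0:
        raise ValueError("annual_cohort must be >= 0")
    if design.duration_months <= 0:
        raise ValueError("duration_months must be positive")
    return annual_cohort / design.duration_months


def band_person_count(annual_cohort: float, band: AgeBand,
                      design: InterventionDesign) -> float:
    """Persons resident in an age band at steady state (closed form)."""
    return band.width_months * monthly_cohort(annual_cohort, design)


def band_person_count_bruteforce(annual_cohort: float, band: AgeBand,
                                 design: InterventionDesign) -> float:
    """Month-by-month enumeration oracle for :func:`band_person_count`."""
    return sum(
        monthly_cohort(annual_cohort, design)
        for _ in range(band.start_month, band.end_month)
    )
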