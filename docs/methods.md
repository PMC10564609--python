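# Methods

## Scope and structure

`sqlns_cea` is a deterministic scenario model: no parameter is estimated
from data, so `SqlnsCeaModel.fit()` carries no sampling uncertainty —
uncertainty is explored through named scenarios (`run_sensitivity`) rather
than probabilistic analysis. The pipeline is

```
ModelConfig ─┐
districts ───┼─> cost_model ──┐
items ───────┘                ├─> scenario_cea (ratios, scenarios, targeting)
cohorts ──> effectiveness ──> daly_model ──┘
```

## Demographic convention

The annual eligible cohort (children supplemented 6–18 months of age in a
calendar year) is assumed uniformly distributed over the 12 supplementation
months, so one month of age holds `N/12` children. Age bands outside the
supplementation window (18–24 months, used by developmental disability and
late anaemia) reuse the same slice size — the cohort that has aged out.
This closed form equals month-by-month enumeration exactly (tested) and is
additive over band partitions.

The person base for the 9–24-month anaemia window is ambiguous in the
source analysis: band occupancy of the annual cohort gives ≈145k cases
averted per year while the published figure exceeds 160k (the full cohort
per band overshoots at ≈225k). The switch
`ModelConfig.anaemia_person_base` (`band_occupancy`, the default, or
`full_cohort_per_band`) exposes both conventions; no intermediate
convention reproduces the published count from the printed prevalences, so
the discrepancy is documented rather than hidden.

## Cost model

Mass-based supply-chain costs are derived from sachet mass
(546 × 20 g = 10.92 kg/carton ⇒ $3.05/kg); all product arithmetic uses
carton price ÷ sachet count, never a rounded per-kg price. The customs
rate is the printed $1.01/kg taken as a direct parameter: the underlying
VAT/withholding arithmetic is not reconstructible and is not modelled.

Activity-based costs follow the activity × input-category × phase
structure of the underlying micronutrient-powder costing study. Transport
inputs scale with district area, personnel/materials with eligible-child
population, workforce-linked inputs with VHT counts or the VHT-per-child
ratio. Start-up items are booked once (2021) and annualised by dividing by
the 10-year horizon in "average annual" figures; under discounting they
sit at the reference year (factor 1). Deflators
(`CostParameters.deflator_table`) exist for ingesting non-2020 base costs
and default to empty — the bundled parameterisation is already in 2020 USD.

Cost-efficiency is `average annual total ÷ average annual cohort`. Because
per-child components are constant and activity costs are year-constant,
this equals the per-child component sum plus the activity budget per child
exactly.

## DALYs

DALYs averted = YLL + YLD. YLL = deaths averted × L; YLD =
cases × duration × disability weight for moderate-or-severe anaemia and
developmental disability only. Stunting carries no GBD disability weight
and moderate wasting's weight is zero, so neither enters DALYs; mild
anaemia is excluded.

Unprinted parameters, all configurable and flagged in results metadata:

| parameter | default | rationale |
|---|---|---|
| remaining life expectancy L | 62.5 y | approximate Ugandan remaining life expectancy in early childhood |
| anaemia YLD duration | 1.25 y | the 9–24-month effect window (effects persist ~6 months post-supplementation) |
| anaemia severity split | 0.9 moderate / 0.1 severe | moderate anaemia dominates the moderate-or-severe pool in young Ugandan children |
| anaemia weight | 0.9×0.052 + 0.1×0.149 = 0.0617 | split-weighted mean of the GBD moderate/severe weights |
| developmental-disability weight | 0.011 | GBD borderline idiopathic developmental intellectual disability |
| developmental-disability duration | L | lifelong condition |

With these defaults the model averts ≈245k DALYs/year — within 1.5% of the
published ≈242k, which cannot be matched exactly because L, durations and
the severity split are not printed. The published discounted $413/DALY
implies L ≈ 52 y under continuous discounting; with L = 62.5 the model
yields ≈$505/DALY. Only the direction (discounting raises cost/DALY, since
life-years lost far in the future are discounted while costs are near-term)
is a model property; the discounted level tracks L.

Discounting is continuous-time without age weighting:
`(1/r)(1 − e^(−rT))` per case (implemented with `expm1` for stability as
r→0), with all of a year's effects and costs sharing that year's factor
`(1+r)^−(y−2021)` — annual granularity, no within-year onset lag. Ratios
divide 10-year (discounted) totals, not means of annual ratios.

## Scenarios and targeting

Scenario overrides are dotted config paths applied to a deep copy
(`costs.price_per_sachet_usd` is translated to a carton price). The eight
bundled scenarios: mortality RR 27%→18%; customs elimination; product
price −10%; price to $0.09/sachet; VHT incentive $0.29 or $0.87; best case
(three favourable cost changes combined) and worst case (18% mortality RR
+ both cost increases). Whether the published best/worst band uses
discounted or undiscounted flows is unstated; both are reported.

Geographic targeting filters districts to the selected sub-regions
(default: West Nile, Busoga, Tooro, Ankole, Karamoja — the highest
under-five-mortality sub-regions in the 2016 DHS), scales the cohort by the
subset's eligible-child share and re-runs the model. The base district
anchors extrapolation indices even when its sub-region is not selected.
Per-child product/supply/incentive components are exactly invariant under
targeting; the activity component varies slightly with the subset's
area-to-child ratio.

## Synthetic fixture

The generator emulates the unpublished inputs, not their item-level truth:

- **districts** — areas log-normal around the 820 km² base (σ = 0.55, 95%
  range ≈0.34–2.9× — a plausible spread for Ugandan districts); child
  counts log-normal (σ = 0.5) rescaled by largest-remainder rounding so the
  national sum is exactly 1,118,340 and, when all fifteen DHS sub-regions
  are represented, the five targeting sub-regions hold exactly 396,808;
  VHT counts proportional to children with σ = 0.2 multiplicative noise;
  sub-regions assigned cyclically. Deterministic given the seed.
- **activity costs** — a closed-form rescaling, no fitting: the $19
  non-product-per-child target minus the analytic $1.76 incentive fixes
  the national activity budget; capacity building (15.3%) and logistics
  (6%) shares of the average annual total are pinned; the residual splits
  over the remaining activities by fixed weights; each template row's base
  cost is its national requirement divided by its summed extrapolation
  index. Product (42.7%) and shipping+customs (18.5%) shares emerge from
  the analytic unit costs, within 0.3 percentage points of the published
  42.5% / 18.7% (the published supply-chain share excludes domestic
  transport, which stays inside the supply-chain cost component here).
- **cohorts** — 2.5%/year growth over 2022–2031 rescaled so the mean is
  exactly 1,118,340.

Because calibration pins the national aggregates, headline outputs are
seed-invariant; seeds only move the district-level decomposition. The
fixture does not reproduce real Ugandan district geography, item-level
cost truth, or year-specific subnational mortality projections — tests
passing on it validate the model arithmetic and calibration machinery, not
the realism of any one district's cost.

## Numerical choices and edge cases

- Cost-effectiveness ratios with zero effect are reported as absent
  (`None`), never infinity; zero cost gives 0.
- Config parsing is strict: unknown keys raise immediately (typo safety).
- `validate()` returns all violations rather than raising on the first.
- Ledger totals aggregate exactly (grouped sums); tests require 1e-6
  relative agreement between district sums and national totals and 1e-9
  for ratio identities.
- Problem sizes: the default fixture uses 120 districts × 10 years, which
  runs the full pipeline including all sensitivity scenarios in seconds.

## Limitations

- Urban delivery platforms, facility-based distribution, local production,
  caregiver-side illness costs and cost-sharing/willingness-to-pay are out
  of scope.
- No cohort thinning by mortality between age bands.
- Adherence is implicit in the meta-analytic effect sizes; no separate
  adherence parameter.
- Effects are linear in cohort and relative reduction by construction;
  the model cannot represent saturation or threshold effects.
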