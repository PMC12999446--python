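# Methods

## Scope and structure

The package estimates the all-cause burden of disease in Swiss pork
production as an Animal Health Loss Envelope (AHLE): the difference in
gross margin between current Average production and a simulated
disease-free Ideal, evaluated per kg liveweight, per animal, per
herd-year and at national population scale, plus the demographic
consequences of disease-freedom for a fixed slaughter output. The industry
is represented as two farm types — combined breeding/rearing (priced per
sow-year) and fattening (priced per slaughter pig produced) — which is a
deliberate simplification of the heterogeneous Swiss farm structure
(segmented piglet production and multi-stage farms are not modelled).

## Scenarios and input principles

Average and Top10 are empiric scenarios built from 2023 industry
aggregates. The Ideal scenario is a simulated state of perfect health:
each input is (A) set to zero (all mortalities, return-to-oestrus),
(B) maximized (farrowing rate = 1), (C) given PERT(min, mode, max)
uncertainty (litters/sow/yr, born alive/litter, replacement rate, rearing
ADG/FCR, fattening FCR and duration), (D) taken from the comparison
scenario, (E) held constant (gestation and lactation length, weaning and
sale weights — biology or regulation), or (F) derived. Config files store
percentages as fractions in [0, 1] (table-style % values are converted at
fixture build time, removing a class of 100× errors), and the schema is
strict: unknown keys are rejected. The USD exchange rate is metadata only.

The `validate_scenario_set` report enforces the principles, the
weaned-per-sow-year identity (aggregate vs component product within 1%),
and weak dominance of the Ideal over the Average on every health-driven
parameter.

## Demographic model

For the fixed 2023 slaughter count S = 2,433,981, requirements are
back-calculated through the five multipliers: fattening mortality, rearing
mortality, litters per sow-year, piglets born alive per litter, preweaning
mortality. The sow requirement uses the component product (2.17 × 13.0 ×
0.895 = 25.248 weaned/sow/yr for Average), not the rounded printed
aggregate 25.3; the two differ by 0.2%. Counts stay real-valued internally;
rounding (half-up) happens only in report writers. The Ideal keeps the same
slaughter target by design — increased supply would depress prices, so the
question is how many fewer animals the same output needs.

## Gross margins

Revenue and variable-cost lines follow the published table structure.
Notable accounting choices, each required to reproduce the printed lines:

- **Reared-piglet revenue** = litters × born alive × (1 − preweaning
  mortality) × (1 − rearing mortality) × unit price. Deriving weaned
  output from components (rather than the printed aggregate row) makes a
  single piglet price (116.96 CHF) consistent across all three scenarios.
- **Insemination** charges every service: litters / farrowing rate ×
  price, so failed services are paid. The return-to-oestrus rate is not
  costed separately (subsumed in the farrowing rate); no published cost
  line isolates it.
- **Sow feed** splits the year into lactating days (lactation length ×
  litters) and gestating/empty days (365 − lactating), at different daily
  rates.
- **Veterinary (breeding)**: herd-health visits are a fixed price per farm
  (209.19 CHF) plus a per-sow rate (115.61 Average / 136.61 Top10), so
  larger herds pay less per sow; the printed per-sow figures correspond to
  the 150-sow herd. The Ideal pays only a flat 39 CHF/sow for piglet
  castration and iron injections, which persist without disease.
- **Fattening replacement** loads the piglet purchase price by
  1/(1 − mortality): dead pigs are paid for but incur no feed cost (feed
  is charged per finished pig). This is what makes the Ideal replacement
  line cheaper than Average at the same start weight.
- **Ear tags** scale with weaned piglets per sow-year; all other
  miscellaneous lines are constant per sow-year or per pig.
- **Herd-year fattening margins** read the published herd sizes as
  finishing *places* cycled through `365/(duration + service)` batches per
  year, with a 16-day service period. This reconstruction is the only
  reading that reconciles the per-pig margins with the published herd-year
  and population figures; it is a documented interpretation, not a printed
  parameter.

All engine arithmetic is unrounded and broadcasts over numpy arrays, so
the same code prices deterministic scenarios and Monte Carlo draws.

## Price book reconstruction

The unit prices behind the published aggregates are not printed. Each
price multiplies a known physical coefficient, so it is recovered from the
three scenario columns by a min–max (Chebyshev) residual fit; the
veterinary fixed/variable split is solved from the spread of per-sow
margins across the 20/50/150-sow herds, and the fattening feed price from
the Average feed line (cost / (FCR × gain)). The solved book reproduces
every itemized printed line within ±1 CHF, ±1.5 CHF for the reared-piglet
revenue line (whose printed inputs are mutually rounded), and ±2.5 CHF for
totals (sums of independently rounded lines — the published tables
disagree with their own line sums by up to 1 CHF). The solved values are
frozen in the packaged fixture for stability; `solve_price_book` remains
the executable audit and regression check. The solution is not unique to
the last rappen — e.g. the solved cull-sow price (172.6 CHF) is low for a
200 kg sow and may net off culling losses — but it reproduces all three
scenarios simultaneously.

One known inconsistency in the source tables is *not* reproducible: the
published Top10 fattening cost lines sum to a per-pig margin of 27.5 CHF
while the printed margin row says 32 (the published herd-year rows are
consistent with 32). The engine matches every itemized Top10 line; the
printed Top10 margin row is excluded from the line-level regression test.

## Monte Carlo simulation

PERT inputs use the standard shape λ = 4 (mean = (min + 4·mode + max)/6),
sampled as rescaled Beta variates; degenerate triples collapse to point
masses. Draws are joint and independent across parameters (no correlation
structure is specified for the Ideal frontier), 10,000 iterations by
default, plain Monte Carlo with a fixed default seed (20230); iteration
count, seed and percentiles (default 5th/95th) are configurable.
Percentiles are empirical quantiles with linear interpolation. Identical
seed and settings give bit-identical results.

Per-animal Ideal table lines are also reported deterministically at the
PERT expected values; because every line is linear in each uncertain
input and inputs are independent, this equals the Monte Carlo mean up to
sampling error.

## AHLE levels

Per draw: AHLE_ANIMAL = GM_ideal − GM_average (per sow-year at each herd
size — the 50-sow herd is the reporting and population basis — and per
slaughter pig); AHLE_KG divides by 200 kg (sow) or 115.9 kg (pig);
AHLE_HERD multiplies by herd size (breeding) or places × turns
(fattening); AHLE_POP multiplies the 50-sow-herd per-sow value by 100,878
sows, and the per-place-year fattening difference by 2,433,981. The
per-place-year basis is the default because it is the only reading
consistent with the published fattening population figure (the per-pig
basis gives ~70 M instead of ~275 M CHF); both bases are reported and
flagged in the output tables. The per-sow population basis uses the
50-sow herd because veterinary cost, hence margin, depends on herd size.

## Sensitivity analysis

13 base inputs (9 breeding/rearing: born alive/litter, preweaning and
rearing mortality, farrowing rate, return-to-oestrus rate,
weaning-to-oestrus interval, litters/sow/yr, replacement rate, rearing
FCR; 4 fattening: FCR, duration, mortality, ADG) are each swept from the
Ideal value — the maximum-performance bound for PERT inputs — to the
Average value, over 7 linearly spaced increments (inclusive endpoints)
of 1,000 iterations. During a sweep the swept parameter is pinned to a
point in the Ideal scenario while the other stochastic inputs keep
sampling; each (parameter, increment) gets a fresh RNG substream derived
from the master seed, so adding parameters never perturbs other sweeps.
Tornado rank orders parameters by the spread of increment means, ties
broken lexicographically. The exact membership of the 13 is a documented
reconstruction (the set is configurable): some listed parameters
(weaning-to-oestrus, return-to-oestrus, the ADGs) do not enter the margin
equations directly and correctly show ~zero range, bounded by Monte Carlo
noise in the tests.

## Synthetic data generator

`generate_synthetic_scenarios` emulates the statistical shape the analysis
assumes — an Average scenario with Beta-distributed mortalities in
[0, 0.25], lognormal reproduction and feed-conversion rates around the
Swiss fixture, and an Ideal that applies the zero/maximize principles with
uplift factors and tight PERT bands; prices are drawn uniformly within
±30% of the reference book, with draws rejected (and redrawn) if they give
the Average scenario a negative margin, since the analysis presumes a
viable baseline. It emulates the model's assumptions, not Swiss market
realism: passing property tests demonstrate internal consistency
(dominance ⇒ non-negative AHLE at every level, determinism, monotonicity),
not agreement with any real farm population.

## Problem sizes and numerical choices

Default runs use 10,000 Monte Carlo iterations for AHLE and 7 × 1,000 for
sensitivity; at these sizes the total-population mean is stable to ~±0.5%
across seeds. The test suite uses scaled runs (hundreds of iterations, or
200 per increment for ranking checks) chosen so that every assertion's
tolerance is several Monte Carlo standard errors wide. Stage operations
reject mortalities ≥ 1 and non-positive reproduction rates; PERT triples
must be finite and ordered; degenerate (min = mode = max) specs are exact
point masses, so a fully degenerate simulation reduces to the
deterministic engine.

## Known limitations

- No labor costs, fixed/overhead costs, or label-programme premiums; no
  currency conversion or inflation adjustment.
- Two-farm-type abstraction; no within-year cohort dynamics, seasonality
  or farm-network structure.
- The price book and the places × turns herd reading are reconstructions
  constrained by the published aggregates, not primary price data.
- Ideal-scenario PERT inputs are sampled independently; any correlation
  between biological frontiers would change the uncertainty bands (not
  the means).
- The AHLE is an upper envelope for all single-cause disease burdens, not
  a producer benchmark; attribution to individual causes is out of scope.
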