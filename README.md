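# swine-ahle

Burden-of-disease analysis for Swiss pork production: the **Animal Health
Loss Envelope (AHLE)** — the gross-margin gap between current average
production and a simulated disease-free ideal — estimated from a demographic
back-calculation, per-animal gross-margin accounting, PERT Monte Carlo
simulation, and one-at-a-time sensitivity analysis.

The package is aimed at veterinary economists and animal-health analysts who
want a tested, reproducible alternative to the usual spreadsheet-based
AHLE workflow: every computation lives in an importable library
(`src/swine_ahle`), the study itself is a sequence of thin numbered drivers
under `analysis/`, and all inputs are plain-text configs.

## The model

Three production scenarios are priced: **Average** (Swiss 2023 industry
aggregates), **Top10** (top-decile farms), and a simulated disease-free
**Ideal** in which every input is set by one of six principles — mortalities
zero, farrowing rate maximized, uncertain biological frontiers as
PERT(min, mode, max) distributions, the rest constant or derived.

**Demographics.** For a fixed slaughter output `S` (2,433,981 pigs in 2023),
requirements are back-calculated through the loss multipliers:

```
reared = S / (1 − m_fat)
weaned = reared / (1 − m_rear)
sows   = weaned / (L · B · (1 − m_pre))
```

with `L` litters/sow/yr, `B` piglets born alive/litter and `m_*` the stage
mortalities.

**Gross margins.** Per sow-year (breeding/rearing) and per slaughter pig
(fattening), gross margin = revenue − variable costs (labor and overheads
excluded). Unit prices come from a price book reconstructed by inverting the
published per-animal cost aggregates (`swine_ahle.fixtures.solve_price_book`
is the executable audit). Veterinary cost per sow is herd-size dependent
(fixed visit price per farm + per-sow rate); fattening herd-years convert
per-pig margins via annual batch turns `365/(duration + 16 d service)`.

**AHLE.** Per Monte Carlo draw (10,000 joint, independent PERT draws of the
Ideal inputs), AHLE_ANIMAL = GM_ideal − GM_average, divided by liveweight
(200 kg sow, 115.9 kg pig) for AHLE_KG, scaled by herd size (× turns for
fattening) for AHLE_HERD, and by the national herd (100,878 sows; 2,433,981
slaughter pigs on the per-place-year basis) for AHLE_POP. Summaries report
the mean and 5th–95th percentile band.

**Sensitivity.** Each of 13 base inputs is swept from its best-performance
(Ideal) value to its Average value over 7 increments × 1,000 iterations;
parameters are tornado-ranked by the spread of the increment means.

## Worked example

```python
import swine_ahle as sa

cfg = sa.swiss_2023_fixture()          # packaged, validated Swiss-2023 inputs
sim = sa.run_simulation(cfg.scenarios, cfg.price_book, cfg.simulation,
                        target_slaughter=float(cfg.population.slaughter_pigs))
summaries = sa.compute_ahle(sim, pop=cfg.population)
s = sa.find_summary(summaries, "per_animal", "breeding")
print(f"AHLE per sow-year: {s.mean:.0f} CHF ({s.p5:.0f}-{s.p95:.0f})")
```

prints

```
AHLE per sow-year: 1854 CHF (1737-1971)
```

i.e. a disease-free sow-year would yield ~CHF 1,854 more gross margin than
the current average (5th–95th percentile of the Ideal-scenario uncertainty
in parentheses). Running the numbered drivers end to end:

```sh
python analysis/01_validate_inputs.py   # input invariants + price-book audit
python analysis/02_demographics.py      # 41% fewer sows for the same output
python analysis/03_gross_margins.py     # 469 / 1079 / 2323 CHF per sow-year
python analysis/04_ahle.py              # total burden ~CHF 463 million
python analysis/05_sensitivity.py       # tornado: born alive & fattening FCR
```

writes the report tables under `results/`. The same pipeline is exposed as a
CLI (`ahle run --config <file> --out <dir> --iterations N --seed S`), with
subcommands `validate`, `demographics`, `margins`, `ahle` and `sensitivity`.

## Layout

- `src/swine_ahle/` — library: `model_inputs` (types, YAML config I/O,
  validation), `demographics`, `economics`, `mc_ahle`, `sensitivity`,
  `fixtures` (Swiss-2023 fixture + price-book solver), `synthetic`
  (generator for property tests), `pipeline`, `cli`.
- `analysis/` — the numbered study drivers.
- `docs/methods.md` — model assumptions, parameter provenance, numerical
  choices and known limitations.
- `tests/` — unit, property (hypothesis) and acceptance suites.
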