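#!/usr/bin/env python
"""Validate the Swiss-2023 inputs and audit the reconstructed price book.

Loads the packaged scenario fixture, runs the full invariant report
(ranges, Ideal principles, Ideal-over-Average dominance), then re-solves
every unit price from the printed per-animal aggregates and writes the
residuals.  Finding: the fixture validates cleanly and the solved book
reproduces every itemized printed line within +/-1 CHF (+/-1.5 for the
reared-piglet revenue line).
"""

from pathlib import Path

from swine_ahle.fixtures import load_aggregates, solve_price_book, swiss_2023_fixture
from swine_ahle.model_inputs import validate_config

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = swiss_2023_fixture()
    problems = validate_config(cfg)
    assert not problems, problems
    print(f"fixture OK: {len(cfg.scenarios)} scenarios, "
          f"{cfg.population.breeding_sows:,} sows / {cfg.population.slaughter_pigs:,} slaughter pigs")

    book, report = solve_price_book(cfg.scenarios, load_aggregates())
    OUT.mkdir(exist_ok=True)
    report.to_csv(OUT / "price_book_residuals.csv", index=False)
    worst = report.loc[report["residual"].abs().idxmax()]
    print(f"price book solved: {len(report)} line checks, "
          f"worst residual {worst['residual']:+.2f} CHF "
          f"({worst['table']}/{worst['line']}, {worst['scenario']})")
    print(f"wrote {OUT / 'price_book_residuals.csv'}")


if __name__ == "__main__":
    main()
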