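#!/usr/bin/env python
"""How many pigs does disease cost? Back-calculate herd requirements.

Fixes the 2023 slaughter output (2,433,981 pigs) and back-calculates the
reared piglets, weaned piglets and breeding sows required under current
Average losses versus the disease-free Ideal (10,000 Monte Carlo draws of
the Ideal reproduction inputs).  Finding: the Ideal needs ~41% fewer sows
(~40.7k head), 3.5% fewer weaned and 1.5% fewer reared piglets for the
same output.
"""

from pathlib import Path

from swine_ahle.fixtures import swiss_2023_fixture
from swine_ahle.demographics import demographic_delta
from swine_ahle.mc_ahle import run_simulation
from swine_ahle.model_inputs import ScenarioName
from swine_ahle.pipeline import write_report_tables

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = swiss_2023_fixture()
    sim = run_simulation(
        cfg.scenarios, cfg.price_book, cfg.simulation,
        target_slaughter=float(cfg.population.slaughter_pigs),
    )
    write_report_tables({"simulation": sim}, OUT)
    delta = demographic_delta(
        sim[ScenarioName.AVERAGE].demographics,
        sim[ScenarioName.IDEAL].demographics,
        percentiles=cfg.simulation.percentiles,
    )
    for stage, d in delta.stages.items():
        band = f" (5th-95th: {d.p5:,.0f}-{d.p95:,.0f})" if d.p5 is not None else ""
        print(f"{stage:>15}: {d.absolute:>12,.0f} fewer ({d.percent:.1f}%){band}")
    print(f"wrote {OUT / 'demographics.csv'}")


if __name__ == "__main__":
    main()
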