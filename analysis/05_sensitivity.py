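#!/usr/bin/env python
"""Which inputs drive the disease burden? OAT sweeps and tornado ranking.

Sweeps each of the 13 base input parameters (9 breeding/rearing, 4
fattening) from its Ideal-scenario (best-performance) value to its
Average value over 7 increments of 1,000 iterations each, and ranks
parameters by the spread of the resulting AHLE means.  Finding: piglets
born alive per litter dominates the per-sow AHLE; feed conversion ratio
dominates the per-pig AHLE; and fattening FCR dominates the total
population AHLE, followed by piglets born alive and fattening duration.
If matplotlib is importable a tornado chart is also rendered.
"""

from pathlib import Path

from swine_ahle.fixtures import swiss_2023_fixture
from swine_ahle.pipeline import write_report_tables
from swine_ahle.sensitivity import default_parameter_set, run_all_sweeps, tornado_ranking

OUT = Path(__file__).resolve().parents[1] / "results"


def plot_tornado(ranked, path: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping tornado chart")
        return
    fig, axes = plt.subplots(1, len(ranked), figsize=(5 * len(ranked), 4))
    for ax, output_id in zip(axes, sorted(ranked)):
        entries = ranked[output_id][::-1]
        ax.barh([e.parameter_id for e in entries], [e.range for e in entries])
        ax.set_title(output_id)
        ax.set_xlabel("AHLE range (CHF)")
        ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    print(f"wrote {path}")


def main() -> None:
    cfg = swiss_2023_fixture()
    specs = default_parameter_set(
        cfg.scenarios,
        increments=cfg.sensitivity.increments,
        iterations_per_increment=cfg.sensitivity.iterations_per_increment,
    )
    entries = run_all_sweeps(
        specs, cfg.scenarios, cfg.price_book, pop=cfg.population,
        master_seed=cfg.simulation.seed,
    )
    write_report_tables({"tornado": entries}, OUT)
    ranked = tornado_ranking(entries)
    for output_id in sorted(ranked):
        top = ranked[output_id][:3]
        print(f"{output_id}: " + " > ".join(
            f"{e.parameter_id} ({e.range:,.0f})" for e in top
        ))
    plot_tornado(ranked, OUT / "tornado.png")
    print(f"wrote {OUT / 'sensitivity_sweeps.csv'} and tornado.csv")


if __name__ == "__main__":
    main()
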