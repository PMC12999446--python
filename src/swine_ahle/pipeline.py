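"""End-to-end analysis driver and report writers.

Runs validation, demographics, gross margins, Monte Carlo AHLE and the
tornado sensitivity analysis from one config, writing deterministic CSV
reports plus a JSON run manifest (config digest, seed, versions).
Rounding happens only in this layer; engines stay unrounded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .demographics import demographic_delta
from .economics import BREEDING_HERD_SIZES
from .fixtures import regenerate_aggregates
from .mc_ahle import AhleSummary, SimulationResult, compute_ahle, run_simulation
from .model_inputs import ScenarioName, SimulationSettings, load_scenario_config
from .sensitivity import (
    TornadoEntry,
    default_parameter_set,
    run_all_sweeps,
    tornado_ranking,
)

__all__ = ["RunManifest", "StageError", "run_full_analysis", "write_report_tables"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config_path: str
    config_sha256: str
    seed: int
    iterations: int
    sensitivity_iterations: int
    package_version: str
    timestamp: str
    outputs: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round(x: float, rounding: int | None) -> float:
    if rounding is None:
        return float(x)
    # round-half-up, matching how head counts and CHF are reported
    q = 10.0**rounding
    return float(np.floor(x * q + 0.5) / q)


def write_report_tables(
    results: dict,
    out_dir: Path,
    rounding: int | None = None,
) -> list[Path]:
    """Write the demographics, margin, AHLE and tornado CSVs; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    sim: SimulationResult | None = results.get("simulation")
    if sim is not None and ScenarioName.IDEAL in sim.scenarios:
        avg = sim[ScenarioName.AVERAGE].demographics
        ideal = sim[ScenarioName.IDEAL].demographics
        delta = demographic_delta(avg, ideal, percentiles=sim.settings.percentiles)
        rows = []
        for stage in ("slaughter_pigs", "reared_piglets", "weaned_piglets", "breeding_sows"):
            sd = delta.stages[stage]
            ideal_draws = np.asarray(getattr(ideal, stage), dtype=float)
            lo, hi = np.percentile(ideal_draws, sim.settings.percentiles)
            rows.append({
                "stage": stage,
                "average": _round(float(np.mean(np.asarray(getattr(avg, stage)))), rounding),
                "ideal_mean": _round(float(ideal_draws.mean()), rounding),
                "ideal_p5": _round(float(lo), rounding),
                "ideal_p95": _round(float(hi), rounding),
                "delta": _round(sd.absolute, rounding),
                "delta_pct": round(sd.percent, 1),
            })
        _emit(pd.DataFrame(rows), "demographics.csv")

    agg = results.get("aggregates")
    if agg is not None:
        tbl = agg.copy()
        if rounding is not None:
            for col in ("average", "top10", "ideal"):
                tbl[col] = tbl[col].map(lambda v: _round(v, rounding))
        _emit(tbl[tbl["table"] == "breeding"], "table3_breeding_margins.csv")
        _emit(tbl[tbl["table"] == "fattening"], "table4_fattening_margins.csv")

    summaries: Sequence[AhleSummary] | None = results.get("ahle")
    if summaries is not None:
        rows = [
            {
                "level": s.level,
                "segment": s.segment,
                "herd_size": s.herd_size,
                "basis": s.basis,
                "mean": _round(s.mean, rounding),
                "p5": _round(s.p5, rounding),
                "p95": _round(s.p95, rounding),
            }
            for s in summaries
        ]
        cols = ["level", "segment", "herd_size", "basis", "mean", "p5", "p95"]
        _emit(pd.DataFrame(rows, columns=cols), "table5_ahle.csv")

    entries: Sequence[TornadoEntry] | None = results.get("tornado")
    if entries is not None:
        sweep_rows = []
        for e in entries:
            for v, m in zip(e.increment_values, e.increment_means):
                sweep_rows.append({
                    "parameter_id": e.parameter_id,
                    "output_id": e.output_id,
                    "increment_value": v,
                    "mean_output": _round(m, rounding),
                })
        _emit(
            pd.DataFrame(
                sweep_rows,
                columns=["parameter_id", "output_id", "increment_value", "mean_output"],
            ),
            "sensitivity_sweeps.csv",
        )
        ranked = tornado_ranking(list(entries))
        rank_rows = []
        for output_id in sorted(ranked):
            for e in ranked[output_id]:
                rank_rows.append({
                    "output_id": output_id,
                    "parameter_id": e.parameter_id,
                    "low_end": _round(e.low_end, rounding),
                    "high_end": _round(e.high_end, rounding),
                    "range": _round(e.range, rounding),
                    "rank": e.rank,
                })
        _emit(
            pd.DataFrame(
                rank_rows,
                columns=["output_id", "parameter_id", "low_end", "high_end", "range", "rank"],
            ),
            "tornado.csv",
        )
    return written


def run_full_analysis(
    config_path: str | Path,
    out_dir: str | Path,
    iterations: int | None = None,
    seed: int | None = None,
    herd_sizes: Sequence[int] | None = None,
    skip_sensitivity: bool = False,
    rounding: int | None = None,
) -> RunManifest:
    """Execute every stage and write all report tables plus a manifest.

    Any stage failure removes the partial outputs and raises
    :class:`StageError` naming the stage.
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    cfg = load_scenario_config(config_path)
    settings = SimulationSettings(
        iterations=iterations or cfg.simulation.iterations,
        seed=cfg.simulation.seed if seed is None else seed,
        percentiles=cfg.simulation.percentiles,
    )
    breeding_sizes = tuple(herd_sizes) if herd_sizes else BREEDING_HERD_SIZES
    written: list[Path] = []
    stage = "simulation"
    try:
        sim = run_simulation(
            cfg.scenarios,
            cfg.price_book,
            settings,
            target_slaughter=float(cfg.population.slaughter_pigs),
            herd_sizes=breeding_sizes,
        )
        stage = "margins"
        aggregates = regenerate_aggregates(cfg.scenarios, cfg.price_book)
        stage = "ahle"
        summaries = compute_ahle(sim, pop=cfg.population)
        results: dict = {"simulation": sim, "aggregates": aggregates, "ahle": summaries}
        if not skip_sensitivity:
            stage = "sensitivity"
            specs = default_parameter_set(
                cfg.scenarios,
                increments=cfg.sensitivity.increments,
                iterations_per_increment=cfg.sensitivity.iterations_per_increment,
            )
            if cfg.sensitivity.parameters:
                wanted = set(cfg.sensitivity.parameters)
                specs = [s for s in specs if s.parameter_id in wanted]
            results["tornado"] = run_all_sweeps(
                specs, cfg.scenarios, cfg.price_book, pop=cfg.population,
                master_seed=settings.seed,
            )
        stage = "report"
        written = write_report_tables(results, out_dir, rounding=rounding)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    manifest = RunManifest(
        config_path=str(config_path),
        config_sha256=_sha256(config_path),
        seed=settings.seed,
        iterations=settings.iterations,
        sensitivity_iterations=0 if skip_sensitivity else cfg.sensitivity.iterations_per_increment,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        outputs=[p.name for p in written],
    )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
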