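"""Monte Carlo propagation of Ideal-scenario uncertainty and AHLE levels.

The Animal Health Loss Envelope (AHLE) is the gross-margin difference
between the simulated disease-free Ideal scenario and current Average
production.  Ideal inputs carrying PERT uncertainty are sampled jointly
and independently per draw; the deterministic engines then price each
draw.  AHLE is reported per kg liveweight, per animal, per herd-year and
at national population level, each summarized by the mean and a 5th-95th
percentile band.

Population scaling follows the per-animal bases: breeding uses the
per-sow margin in a 50-sow herd times the national sow count; fattening
converts per-pig margins to per-place-year margins via annual batch
turns before scaling by the national slaughter count (the per-pig basis
is also reported, flagged, for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._sampling import sample_param, sample_pert  # re-exported  # noqa: F401
from .demographics import (
    DemographicResult,
    required_reared,
    required_sows,
    required_weaned,
)
from .economics import (
    BREEDING_HERD_SIZES,
    FATTENING_HERD_SIZES,
    GrossMarginBreakdown,
    HerdKind,
    HerdSpec,
    annual_turns,
    breeding_gross_margin,
    fattening_gross_margin,
)
from .model_inputs import (
    PopulationCounts,
    PriceBook,
    ScenarioName,
    ScenarioSet,
    SimulationSettings,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "AhleSummary",
    "run_simulation",
    "compute_ahle",
    "SOW_LIVEWEIGHT_KG",
    "PIG_LIVEWEIGHT_KG",
]

# liveweight bases for AHLE per kg
SOW_LIVEWEIGHT_KG = 200.0
PIG_LIVEWEIGHT_KG = 115.9

# population AHLE for breeding uses the mid-size herd's per-sow margin
POPULATION_BREEDING_HERD = 50

SimulationConfig = SimulationSettings

_BREEDING_STOCHASTIC = (
    "litters_per_sow_year",
    "piglets_born_alive_per_litter",
    "sow_replacement_rate",
    "rearing_fcr",
)
_FATTENING_STOCHASTIC = ("fcr", "fattening_duration")


@dataclass
class ScenarioOutput:
    """Per-scenario engine output; Ideal entries are per-draw arrays."""

    breeding_gm: dict[int, float | np.ndarray]
    breeding_breakdown: dict[int, GrossMarginBreakdown]
    fattening_gm: float | np.ndarray
    fattening_breakdown: GrossMarginBreakdown
    turns: float | np.ndarray
    demographics: DemographicResult


@dataclass
class SimulationResult:
    settings: SimulationSettings
    target_slaughter: float
    scenarios: dict[ScenarioName, ScenarioOutput] = field(default_factory=dict)

    def __getitem__(self, name: ScenarioName) -> ScenarioOutput:
        return self.scenarios[name]


def _evaluate_scenario(
    sc: ScenarioSet,
    book: PriceBook,
    target_slaughter: float,
    herd_sizes: Sequence[int],
    breeding_values: Mapping[str, float | np.ndarray],
    fattening_values: Mapping[str, float | np.ndarray],
) -> ScenarioOutput:
    breakdowns = {
        size: breeding_gross_margin(
            sc.breeding, book, HerdSpec(HerdKind.BREEDING, size), sc.name,
            values=breeding_values,
        )
        for size in herd_sizes
    }
    fat = fattening_gross_margin(sc.fattening, book, sc.name, values=fattening_values)
    duration = fattening_values.get("fattening_duration", sc.fattening.fattening_duration.mean)
    turns = annual_turns(duration, sc.fattening.service_period)

    litters = breeding_values.get("litters_per_sow_year", sc.breeding.litters_per_sow_year.mean)
    born = breeding_values.get(
        "piglets_born_alive_per_litter", sc.breeding.piglets_born_alive_per_litter.mean
    )
    reared = required_reared(target_slaughter, sc.fattening.mortality)
    weaned = required_weaned(reared, sc.breeding.rearing_mortality)
    sows = required_sows(weaned, litters, born, sc.breeding.preweaning_mortality)
    demo = DemographicResult(
        target_slaughter=target_slaughter,
        slaughter_pigs=target_slaughter,
        reared_piglets=reared,
        weaned_piglets=weaned,
        breeding_sows=sows,
    )
    return ScenarioOutput(
        breeding_gm={s: bd.gross_margin for s, bd in breakdowns.items()},
        breeding_breakdown=breakdowns,
        fattening_gm=fat.gross_margin,
        fattening_breakdown=fat,
        turns=turns,
        demographics=demo,
    )


def run_simulation(
    scenarios: Mapping[ScenarioName, ScenarioSet],
    book: PriceBook,
    cfg: SimulationSettings,
    target_slaughter: float | None = None,
    herd_sizes: Sequence[int] = BREEDING_HERD_SIZES,
    overrides: Mapping[str, float] | None = None,
) -> SimulationResult:
    """Evaluate all scenarios; PERT-carrying ones get ``cfg.iterations`` draws.

    Reproducible given (seed, iterations).  ``overrides`` pins named
    stochastic parameters ("breeding.rearing_fcr", ...) to fixed values —
    the hook the one-at-a-time sensitivity sweeps use.
    """
    rng = np.random.default_rng(cfg.seed)
    overrides = dict(overrides or {})
    if target_slaughter is None:
        target_slaughter = float(PopulationCounts().slaughter_pigs)
    result = SimulationResult(settings=cfg, target_slaughter=target_slaughter)

    for name in (ScenarioName.AVERAGE, ScenarioName.TOP10, ScenarioName.IDEAL):
        if name not in scenarios:
            continue
        sc = scenarios[name]
        # sweeps pin parameters in the Ideal scenario only
        sc_overrides = overrides if name == ScenarioName.IDEAL else {}
        b_vals: dict[str, float | np.ndarray] = {}
        f_vals: dict[str, float | np.ndarray] = {}
        stochastic = any(
            getattr(sc.breeding, f).kind == "pert" for f in _BREEDING_STOCHASTIC
        ) or any(getattr(sc.fattening, f).kind == "pert" for f in _FATTENING_STOCHASTIC)
        if stochastic:
            n = cfg.iterations
            for fname in _BREEDING_STOCHASTIC:
                key = f"breeding.{fname}"
                if key in sc_overrides:
                    b_vals[fname] = sc_overrides[key]
                else:
                    b_vals[fname] = sample_param(getattr(sc.breeding, fname), rng, n)
            for fname in _FATTENING_STOCHASTIC:
                key = f"fattening.{fname}"
                if key in sc_overrides:
                    f_vals[fname] = sc_overrides[key]
                else:
                    f_vals[fname] = sample_param(getattr(sc.fattening, fname), rng, n)
        # remaining overrides (deterministic fields swept in sensitivity)
        for key, val in sc_overrides.items():
            section, fname = key.split(".", 1)
            target = b_vals if section == "breeding" else f_vals
            if fname not in target:
                target[fname] = val
        result.scenarios[name] = _evaluate_scenario(
            sc, book, target_slaughter, herd_sizes, b_vals, f_vals
        )
    return result


@dataclass(frozen=True)
class AhleSummary:
    """Mean and percentile band of one AHLE aggregate."""

    level: str  # per_kg | per_animal | per_herd | per_population
    segment: str  # breeding | fattening | total
    mean: float
    p5: float
    p95: float
    herd_size: int | None = None
    basis: str | None = None  # population fattening: place_year (default) | per_pig

    def __post_init__(self) -> None:
        if not (self.p5 <= self.mean + 1e-9 and self.mean <= self.p95 + 1e-9):
            raise ValueError(f"requires p5 <= mean <= p95, got {self}")


def _summarize(draws, level, segment, percentiles, herd_size=None, basis=None) -> AhleSummary:
    arr = np.asarray(draws, dtype=float)
    lo, hi = np.percentile(arr, percentiles)
    return AhleSummary(
        level=level,
        segment=segment,
        mean=float(arr.mean()),
        p5=float(min(lo, arr.mean())),
        p95=float(max(hi, arr.mean())),
        herd_size=herd_size,
        basis=basis,
    )


def compute_ahle(
    sim: SimulationResult,
    herds: Iterable[HerdSpec] | None = None,
    pop: PopulationCounts | None = None,
    liveweights: tuple[float, float] = (SOW_LIVEWEIGHT_KG, PIG_LIVEWEIGHT_KG),
) -> list[AhleSummary]:
    """Per-draw Ideal-minus-Average margin differences at every level."""
    pop = pop or PopulationCounts()
    pct = sim.settings.percentiles
    if herds is None:
        herds = [HerdSpec(HerdKind.BREEDING, s) for s in BREEDING_HERD_SIZES] + [
            HerdSpec(HerdKind.FATTENING, s) for s in FATTENING_HERD_SIZES
        ]
    avg = sim[ScenarioName.AVERAGE]
    ideal = sim[ScenarioName.IDEAL]
    sow_lw, pig_lw = liveweights

    if POPULATION_BREEDING_HERD not in ideal.breeding_gm:
        raise ValueError(
            f"simulation lacks the {POPULATION_BREEDING_HERD}-sow herd needed "
            "for per-animal and population AHLE"
        )
    ahle_sow = {
        size: ideal.breeding_gm[size] - avg.breeding_gm[size]
        for size in ideal.breeding_gm
    }
    ahle_pig = ideal.fattening_gm - avg.fattening_gm
    # per finishing place and year; the basis for herd and population levels
    ahle_place_year = ideal.fattening_gm * ideal.turns - avg.fattening_gm * avg.turns

    out: list[AhleSummary] = []
    sow_basis = ahle_sow[POPULATION_BREEDING_HERD]
    out.append(_summarize(sow_basis / sow_lw, "per_kg", "breeding", pct))
    out.append(_summarize(ahle_pig / pig_lw, "per_kg", "fattening", pct))
    out.append(_summarize(sow_basis, "per_animal", "breeding", pct))
    out.append(_summarize(ahle_pig, "per_animal", "fattening", pct))
    for herd in herds:
        if herd.kind == HerdKind.BREEDING:
            draws = ahle_sow[herd.size] * herd.size
            out.append(_summarize(draws, "per_herd", "breeding", pct, herd_size=herd.size))
        else:
            draws = ahle_place_year * herd.size
            out.append(_summarize(draws, "per_herd", "fattening", pct, herd_size=herd.size))
    pop_breeding = sow_basis * pop.breeding_sows
    pop_fattening = ahle_place_year * pop.slaughter_pigs
    out.append(_summarize(pop_breeding, "per_population", "breeding", pct))
    out.append(
        _summarize(pop_fattening, "per_population", "fattening", pct, basis="place_year")
    )
    out.append(
        _summarize(
            ahle_pig * pop.slaughter_pigs, "per_population", "fattening", pct,
            basis="per_pig",
        )
    )
    out.append(
        _summarize(pop_breeding + pop_fattening, "per_population", "total", pct,
                   basis="place_year")
    )
    return out


def find_summary(
    summaries: Iterable[AhleSummary],
    level: str,
    segment: str,
    herd_size: int | None = None,
    basis: str | None = None,
) -> AhleSummary:
    """Pick one summary; population fattening defaults to the place-year basis."""
    for s in summaries:
        if s.level != level or s.segment != segment or s.herd_size != herd_size:
            continue
        if level == "per_population" and segment in ("fattening", "total"):
            if s.basis != (basis or "place_year"):
                continue
        out = s
        return out
    raise KeyError((level, segment, herd_size, basis))
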