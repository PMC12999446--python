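"""One-at-a-time (OAT) sensitivity sweeps with tornado ranking.

Each base input parameter is varied from its Ideal-scenario value (for
PERT-distributed inputs, the distribution bound representing maximum
performance) to its Average-scenario value over evenly spaced increments.
At each increment the swept parameter is pinned to a point value in the
Ideal scenario while all other stochastic inputs keep sampling; the mean
of each output over the increment's Monte Carlo iterations is recorded.
A parameter's tornado range is the spread (max - min) of those increment
means, and parameters are ranked by descending range per output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .economics import BREEDING_HERD_SIZES
from .mc_ahle import compute_ahle, find_summary, run_simulation
from .model_inputs import (
    ParameterValue,
    PopulationCounts,
    PriceBook,
    ScenarioName,
    ScenarioSet,
    SimulationSettings,
)

__all__ = [
    "OUTPUTS",
    "SweepSpec",
    "TornadoEntry",
    "default_parameter_set",
    "run_sweep",
    "run_all_sweeps",
    "tornado_ranking",
]

OUTPUTS = ("ahle_animal_breeding", "ahle_animal_fattening", "ahle_pop_total")

DEFAULT_INCREMENTS = 7
DEFAULT_ITERATIONS = 1_000


@dataclass(frozen=True)
class SweepSpec:
    """One parameter's sweep: Ideal(-bound) value to Average value."""

    parameter_id: str  # e.g. "breeding.piglets_born_alive_per_litter"
    low_value: float  # Ideal / maximum-performance bound
    high_value: float  # Average value
    increments: int = DEFAULT_INCREMENTS
    iterations_per_increment: int = DEFAULT_ITERATIONS
    outputs: tuple[str, ...] = OUTPUTS

    def __post_init__(self) -> None:
        if self.increments < 2:
            raise ValueError("a sweep needs at least 2 increments")

    def increment_values(self) -> np.ndarray:
        """Linearly spaced, inclusive of both endpoints."""
        return np.linspace(self.low_value, self.high_value, self.increments)


@dataclass
class TornadoEntry:
    parameter_id: str
    output_id: str
    increment_values: list[float]
    increment_means: list[float]
    rank: int | None = None

    @property
    def range(self) -> float:
        return float(max(self.increment_means) - min(self.increment_means))

    @property
    def low_end(self) -> float:
        return self.increment_means[0]

    @property
    def high_end(self) -> float:
        return self.increment_means[-1]


def _performance_bound(p: ParameterValue, better: str) -> float:
    """Maximum-performance endpoint of a PERT input; fixed values pass through."""
    if p.kind == "fixed":
        return float(p.value)
    return float(p.spec.maximum if better == "high" else p.spec.minimum)


# (field, direction in which performance improves)
_BREEDING_FIELDS = (
    ("piglets_born_alive_per_litter", "high"),
    ("preweaning_mortality", "low"),
    ("rearing_mortality", "low"),
    ("farrowing_rate", "high"),
    ("return_to_oestrus_rate", "low"),
    ("weaning_to_oestrus", "low"),
    ("litters_per_sow_year", "high"),
    ("sow_replacement_rate", "low"),
    ("rearing_fcr", "low"),
)
_FATTENING_FIELDS = (
    ("fcr", "low"),
    ("fattening_duration", "low"),
    ("mortality", "low"),
    ("adg", "high"),
)


def default_parameter_set(
    scenarios: Mapping[ScenarioName, ScenarioSet],
    increments: int = DEFAULT_INCREMENTS,
    iterations_per_increment: int = DEFAULT_ITERATIONS,
) -> list[SweepSpec]:
    """The 13 base input parameters: 9 breeding/rearing + 4 fattening."""
    avg = scenarios[ScenarioName.AVERAGE]
    ideal = scenarios[ScenarioName.IDEAL]
    specs: list[SweepSpec] = []
    for section, fields in (("breeding", _BREEDING_FIELDS), ("fattening", _FATTENING_FIELDS)):
        for fname, better in fields:
            iv = getattr(getattr(ideal, section), fname)
            av = getattr(getattr(avg, section), fname)
            low = _performance_bound(iv, better) if isinstance(iv, ParameterValue) else float(iv)
            high = float(av.point) if isinstance(av, ParameterValue) else float(av)
            specs.append(
                SweepSpec(
                    parameter_id=f"{section}.{fname}",
                    low_value=low,
                    high_value=high,
                    increments=increments,
                    iterations_per_increment=iterations_per_increment,
                )
            )
    return specs


def _substream_seed(master_seed: int, parameter_id: str, increment_index: int) -> np.random.SeedSequence:
    # stable per (parameter, increment): adding parameters never perturbs others
    return np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(zlib.crc32(parameter_id.encode()), increment_index),
    )


def run_sweep(
    spec: SweepSpec,
    scenarios: Mapping[ScenarioName, ScenarioSet],
    book: PriceBook,
    pop: PopulationCounts | None = None,
    master_seed: int = 0,
) -> dict[str, TornadoEntry]:
    """Sweep one parameter; returns a TornadoEntry per requested output."""
    section, fname = spec.parameter_id.split(".", 1)
    if section not in ("breeding", "fattening"):
        raise ValueError(f"unknown parameter {spec.parameter_id!r}")
    ideal = scenarios[ScenarioName.IDEAL]
    if not hasattr(getattr(ideal, section), fname):
        raise ValueError(f"unknown parameter {spec.parameter_id!r}")
    pop = pop or PopulationCounts()

    values = spec.increment_values()
    means: dict[str, list[float]] = {o: [] for o in spec.outputs}
    for idx, v in enumerate(values):
        seed = int(_substream_seed(master_seed, spec.parameter_id, idx).generate_state(1)[0] % (2**31))
        settings = SimulationSettings(iterations=spec.iterations_per_increment, seed=seed)
        sim = run_simulation(
            scenarios,
            book,
            settings,
            target_slaughter=float(pop.slaughter_pigs),
            herd_sizes=BREEDING_HERD_SIZES,
            overrides={spec.parameter_id: float(v)},
        )
        summaries = compute_ahle(sim, pop=pop)
        lookup = {
            "ahle_animal_breeding": ("per_animal", "breeding", None),
            "ahle_animal_fattening": ("per_animal", "fattening", None),
            "ahle_pop_total": ("per_population", "total", None),
        }
        for out_id in spec.outputs:
            level, segment, herd = lookup[out_id]
            means[out_id].append(find_summary(summaries, level, segment, herd).mean)
    return {
        out_id: TornadoEntry(
            parameter_id=spec.parameter_id,
            output_id=out_id,
            increment_values=[float(v) for v in values],
            increment_means=means[out_id],
        )
        for out_id in spec.outputs
    }


def run_all_sweeps(
    specs: Sequence[SweepSpec],
    scenarios: Mapping[ScenarioName, ScenarioSet],
    book: PriceBook,
    pop: PopulationCounts | None = None,
    master_seed: int = 0,
) -> list[TornadoEntry]:
    entries: list[TornadoEntry] = []
    for spec in specs:
        entries.extend(
            run_sweep(spec, scenarios, book, pop=pop, master_seed=master_seed).values()
        )
    return entries


def tornado_ranking(entries: Iterable[TornadoEntry]) -> dict[str, list[TornadoEntry]]:
    """Per output: entries sorted by descending range (ties lexicographic)."""
    by_output: dict[str, list[TornadoEntry]] = {}
    for e in entries:
        by_output.setdefault(e.output_id, []).append(e)
    for output_id, group in by_output.items():
        group.sort(key=lambda e: (-e.range, e.parameter_id))
        for rank, e in enumerate(group, start=1):
            e.rank = rank
    return by_output
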