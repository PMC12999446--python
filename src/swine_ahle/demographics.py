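"""Demographic back-calculation for a fixed annual slaughter output.

Working backwards from the national slaughter count, each production stage
inflates the required head count by its loss multiplier: fattening
mortality, rearing mortality, then the sow-productivity product
litters/sow/yr x born alive/litter x (1 - preweaning mortality).  Counts
are kept as reals internally; rounding happens only in report writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._sampling import sample_param
from .model_inputs import ScenarioSet

__all__ = [
    "DemographicResult",
    "DemographicDelta",
    "required_reared",
    "required_weaned",
    "required_sows",
    "back_calculate",
    "demographic_delta",
]


def _check_mortality(m, label: str) -> None:
    m = np.asarray(m, dtype=float)
    if np.any(m < 0.0) or np.any(m >= 1.0):
        raise ValueError(f"{label} must be in [0, 1), got {m}")


def required_reared(slaughter, fattening_mortality):
    """Reared piglets entering fattening to yield ``slaughter`` finished pigs."""
    _check_mortality(fattening_mortality, "fattening mortality")
    return slaughter / (1.0 - fattening_mortality)


def required_weaned(reared, rearing_mortality):
    """Weaned piglets entering rearing to yield ``reared`` piglets."""
    _check_mortality(rearing_mortality, "rearing mortality")
    return reared / (1.0 - rearing_mortality)


def required_sows(weaned, litters_per_sow_year, born_alive_per_litter, preweaning_mortality):
    """Breeding sows needed to wean ``weaned`` piglets per year."""
    litters = np.asarray(litters_per_sow_year, dtype=float)
    born = np.asarray(born_alive_per_litter, dtype=float)
    if np.any(litters <= 0.0) or np.any(born <= 0.0):
        raise ValueError("litters and born-alive rates must be positive")
    _check_mortality(preweaning_mortality, "preweaning mortality")
    return weaned / (litters * born * (1.0 - preweaning_mortality))


@dataclass(frozen=True)
class DemographicResult:
    """Required head counts (real-valued; per-draw arrays for Ideal)."""

    target_slaughter: float
    slaughter_pigs: float | np.ndarray
    reared_piglets: float | np.ndarray
    weaned_piglets: float | np.ndarray
    breeding_sows: float | np.ndarray

    def mean(self) -> "DemographicResult":
        """Collapse per-draw arrays to their means."""
        return DemographicResult(
            self.target_slaughter,
            float(np.mean(self.slaughter_pigs)),
            float(np.mean(self.reared_piglets)),
            float(np.mean(self.weaned_piglets)),
            float(np.mean(self.breeding_sows)),
        )


@dataclass(frozen=True)
class StageDelta:
    absolute: float
    percent: float
    p5: Optional[float] = None
    p95: Optional[float] = None


@dataclass(frozen=True)
class DemographicDelta:
    """Average-minus-Ideal stage reductions; sows carry a Monte Carlo band."""

    stages: dict[str, StageDelta] = field(default_factory=dict)


def back_calculate(
    s: ScenarioSet,
    target_slaughter: float,
    rng: np.random.Generator | None = None,
    draws: int | None = None,
) -> DemographicResult:
    """Chain the three stage operations for one scenario.

    For a scenario with PERT-distributed reproduction inputs (the Ideal),
    pass ``rng`` and ``draws`` to obtain per-draw sow requirements; without
    them, distributions collapse to their modes.
    """
    b, f = s.breeding, s.fattening
    if rng is not None and draws is not None:
        litters = sample_param(b.litters_per_sow_year, rng, draws)
        born = sample_param(b.piglets_born_alive_per_litter, rng, draws)
    else:
        litters = b.litters_per_sow_year.point
        born = b.piglets_born_alive_per_litter.point
    reared = required_reared(target_slaughter, f.mortality)
    weaned = required_weaned(reared, b.rearing_mortality)
    sows = required_sows(weaned, litters, born, b.preweaning_mortality)
    return DemographicResult(
        target_slaughter=float(target_slaughter),
        slaughter_pigs=float(target_slaughter),
        reared_piglets=reared,
        weaned_piglets=weaned,
        breeding_sows=sows,
    )


def demographic_delta(
    avg: DemographicResult,
    ideal: DemographicResult,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> DemographicDelta:
    """Per-stage reductions (Average - Ideal), as heads and % of Average.

    The sow stage is summarized across Monte Carlo draws by mean and the
    requested percentiles of the per-draw reduction.
    """
    if avg.target_slaughter != ideal.target_slaughter:
        raise ValueError(
            "scenarios were run against different slaughter targets: "
            f"{avg.target_slaughter} vs {ideal.target_slaughter}"
        )
    stages: dict[str, StageDelta] = {}
    for stage in ("slaughter_pigs", "reared_piglets", "weaned_piglets"):
        a = float(np.mean(getattr(avg, stage)))
        diff = a - float(np.mean(getattr(ideal, stage)))
        stages[stage] = StageDelta(absolute=diff, percent=100.0 * diff / a)
    a_sows = float(np.mean(avg.breeding_sows))
    sow_diff = np.asarray(avg.breeding_sows) - np.asarray(ideal.breeding_sows)
    lo, hi = np.percentile(sow_diff, percentiles) if sow_diff.ndim else (None, None)
    stages["breeding_sows"] = StageDelta(
        absolute=float(np.mean(sow_diff)),
        percent=100.0 * float(np.mean(sow_diff)) / a_sows,
        p5=None if lo is None else float(lo),
        p95=None if hi is None else float(hi),
    )
    return DemographicDelta(stages=stages)
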