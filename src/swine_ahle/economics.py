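"""Deterministic gross-margin engines for breeding/rearing and fattening.

A gross margin is revenue minus variable costs per production unit — per
sow-year for breeding/rearing farms, per slaughter pig produced for
fattening farms.  Labor, overheads and label premiums are excluded.  All
arithmetic is unrounded and broadcasts over numpy arrays, so the same
engine serves the deterministic scenarios and the Monte Carlo draws.

Veterinary cost per sow is herd-size dependent in the empiric scenarios
(a fixed herd-health-visit price per farm plus a per-sow rate), while in
the disease-free Ideal only per-piglet care (castration, iron) remains.

Fattening herd-year figures treat the printed herd sizes as finishing
places cycled through several batches per year: turns = 365/(fattening
duration + service period).  This reconstruction is what reconciles the
per-pig margins with the printed herd-year rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

from .model_inputs import (
    BreedingParameters,
    FatteningParameters,
    PriceBook,
    ScenarioName,
)

__all__ = [
    "HerdKind",
    "HerdSpec",
    "GrossMarginBreakdown",
    "breeding_gross_margin",
    "veterinary_cost_per_sow",
    "fattening_gross_margin",
    "annual_turns",
    "herd_annual_margin",
    "BREEDING_HERD_SIZES",
    "FATTENING_HERD_SIZES",
]

BREEDING_HERD_SIZES = (20, 50, 150)
FATTENING_HERD_SIZES = (150, 350, 1000)

DAYS_PER_YEAR = 365.0


class HerdKind(str, Enum):
    BREEDING = "breeding"
    FATTENING = "fattening"


@dataclass(frozen=True)
class HerdSpec:
    kind: HerdKind
    size: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("herd size must be positive")


@dataclass
class GrossMarginBreakdown:
    """Itemized revenue and cost lines plus the resulting margin.

    Values are CHF per sow-year (breeding) or CHF per slaughter pig
    (fattening); entries may be per-draw numpy arrays.
    """

    unit: str
    revenue: dict[str, float | np.ndarray] = field(default_factory=dict)
    costs: dict[str, float | np.ndarray] = field(default_factory=dict)

    @property
    def total_output(self):
        return sum(self.revenue.values())

    @property
    def total_costs(self):
        return sum(self.costs.values())

    @property
    def gross_margin(self):
        return self.total_output - self.total_costs

    def line(self, name: str):
        if name in self.revenue:
            return self.revenue[name]
        return self.costs[name]


def veterinary_cost_per_sow(
    herd: HerdSpec, book: PriceBook, scenario: ScenarioName
) -> float:
    """CHF per sow-year: fixed visit price diluted over the herd, plus a rate.

    Larger herds therefore pay less per sow; the Ideal pays only the flat
    per-sow rate for castration and iron injections.
    """
    if herd.kind != HerdKind.BREEDING:
        raise ValueError("veterinary_cost_per_sow applies to breeding herds")
    if scenario == ScenarioName.IDEAL:
        return book.vet_per_sow_ideal
    return book.vet_fixed_per_farm / herd.size + book.vet_per_sow[scenario]


def breeding_gross_margin(
    p: BreedingParameters,
    book: PriceBook,
    herd: HerdSpec,
    scenario: ScenarioName,
    values: Mapping[str, float | np.ndarray] | None = None,
) -> GrossMarginBreakdown:
    """Gross margin per sow-year for a breeding/rearing farm.

    ``values`` optionally overrides the stochastic parameters
    (litters_per_sow_year, piglets_born_alive_per_litter,
    sow_replacement_rate, rearing_fcr, and the mortalities/farrowing rate
    during sensitivity sweeps) with sampled scalars or arrays; defaults
    are the parameters' expected values, under which the engine returns
    the (to first order) expected margin.
    """
    if herd.kind != HerdKind.BREEDING:
        raise ValueError("breeding_gross_margin requires a breeding herd")
    v = dict(values or {})
    litters = v.get("litters_per_sow_year", p.litters_per_sow_year.mean)
    born = v.get("piglets_born_alive_per_litter", p.piglets_born_alive_per_litter.mean)
    repl = v.get("sow_replacement_rate", p.sow_replacement_rate.mean)
    rearing_fcr = v.get("rearing_fcr", p.rearing_fcr.mean)
    pwm = v.get("preweaning_mortality", p.preweaning_mortality)
    rmort = v.get("rearing_mortality", p.rearing_mortality)
    farrowing = v.get("farrowing_rate", p.farrowing_rate)

    weaned = litters * born * (1.0 - pwm)  # per sow-year
    sold = weaned * (1.0 - rmort)
    rearing_gain = p.reared_sale_weight - p.piglet_weaning_weight

    gm = GrossMarginBreakdown(unit="CHF/sow/yr")
    gm.revenue["reared_piglets"] = sold * book.reared_piglet_price
    gm.revenue["cull_sow"] = repl * book.cull_sow_price

    gm.costs["replacement"] = repl * book.gilt_price
    # every service is paid, including those that fail to produce a litter
    gm.costs["insemination"] = litters / farrowing * book.insemination_price
    lact_days = p.lactation_length * litters
    gm.costs["gestation_feed"] = (DAYS_PER_YEAR - lact_days) * book.sow_gestation_feed_rate
    gm.costs["lactation_feed"] = lact_days * book.sow_lactation_feed_rate
    gm.costs["starter_feed"] = weaned * book.starter_feed_per_weaned
    gm.costs["rearing_feed"] = sold * rearing_fcr * rearing_gain * book.rearing_feed_price
    gm.costs["gilt_feed"] = repl * book.gilt_feed_per_replacement
    gm.costs["veterinary"] = veterinary_cost_per_sow(herd, book, scenario)
    gm.costs["ear_tags"] = weaned * book.ear_tag_price
    gm.costs["misc_fixed"] = book.breeding_misc_fixed
    return gm


def fattening_gross_margin(
    p: FatteningParameters,
    book: PriceBook,
    scenario: ScenarioName,
    values: Mapping[str, float | np.ndarray] | None = None,
) -> GrossMarginBreakdown:
    """Gross margin per slaughter pig produced.

    Dead pigs incur their full purchase cost — hence the 1/(1 - mortality)
    loading on replacement — but no feed, which is charged per finished
    pig only.
    """
    v = dict(values or {})
    fcr = v.get("fcr", p.fcr.mean)
    mortality = v.get("mortality", p.mortality)
    if np.any(np.asarray(mortality) >= 1.0):
        raise ValueError("fattening mortality must be < 1")

    gm = GrossMarginBreakdown(unit="CHF/pig")
    gm.revenue["slaughter_pig"] = book.slaughter_pig_revenue
    piglet_price = book.piglet_purchase_price(p.start_weight)
    gm.costs["replacement"] = piglet_price / (1.0 - mortality)
    gm.costs["feed"] = fcr * p.weight_gain * book.fattening_feed_price
    gm.costs["veterinary"] = book.fattening_vet_per_pig[scenario]
    gm.costs["misc"] = book.fattening_misc_per_pig
    return gm


def annual_turns(fattening_duration, service_period):
    """Batches per finishing place and year: 365/(duration + service days)."""
    duration = np.asarray(fattening_duration, dtype=float)
    if np.any(duration <= 0):
        raise ValueError("fattening duration must be positive")
    if np.any(np.asarray(service_period) < 0):
        raise ValueError("service period cannot be negative")
    return DAYS_PER_YEAR / (duration + service_period)


def herd_annual_margin(per_animal_margin, herd: HerdSpec, turns=1.0):
    """CHF per herd and year.

    Breeding herds hold ``size`` sows year-round (turns = 1); fattening
    herds cycle ``size`` places through ``turns`` batches per year.
    """
    if herd.kind == HerdKind.BREEDING:
        return per_animal_margin * herd.size
    return per_animal_margin * herd.size * turns
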