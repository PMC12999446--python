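"""Synthetic Average/Ideal scenario pairs for property testing.

The generator emulates the statistical shape the analysis assumes — an
empiric Average scenario with positive mortalities and an Ideal scenario
that weakly dominates it (zero mortalities, maximized farrowing rate,
better reproduction, lower feed conversion) with PERT uncertainty only on
the Ideal inputs — not Swiss market realism.  Prices are drawn uniformly
within +/-30% of the reference book; draws whose Average margins are
negative are rejected and redrawn, since the analysis presumes viable
production in the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economics import HerdKind, HerdSpec, breeding_gross_margin, fattening_gross_margin
from .fixtures import swiss_2023_fixture
from .model_inputs import (
    BreedingParameters,
    FatteningParameters,
    ParameterValue,
    PertSpec,
    PriceBook,
    Principle,
    ScenarioName,
    ScenarioSet,
)

__all__ = ["SyntheticConfig", "SyntheticPair", "generate_synthetic_scenarios"]

_MAX_PRICE_TRIES = 200


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_sets: int = 1
    dominance: bool = True  # Ideal weakly dominates Average
    price_jitter: float = 0.3  # uniform relative half-width around the reference book
    mortality_max: float = 0.25  # Beta-scaled upper bound for Average mortalities
    reproduction_jitter: float = 0.08  # lognormal sigma around reference rates


@dataclass(frozen=True)
class SyntheticPair:
    average: ScenarioSet
    ideal: ScenarioSet
    book: PriceBook

    @property
    def scenarios(self) -> dict[ScenarioName, ScenarioSet]:
        return {ScenarioName.AVERAGE: self.average, ScenarioName.IDEAL: self.ideal}


def _fixed(value: float, principle: Principle = Principle.D_FROM_COMPARISON) -> ParameterValue:
    return ParameterValue(kind="fixed", value=float(value), principle=principle)


def _pert_around(rng: np.random.Generator, mode: float, rel: float = 0.02) -> ParameterValue:
    lo = mode * (1.0 - rel * rng.uniform(0.5, 1.5))
    hi = mode * (1.0 + rel * rng.uniform(0.5, 1.5))
    return ParameterValue(
        kind="pert",
        spec=PertSpec(minimum=lo, mode=mode, maximum=hi),
        principle=Principle.C_PERT,
    )


def _draw_book(rng: np.random.Generator, ref: PriceBook, jitter: float) -> PriceBook:
    def j(x: float) -> float:
        return x * rng.uniform(1.0 - jitter, 1.0 + jitter)

    vet_avg = j(ref.vet_per_sow[ScenarioName.AVERAGE])
    return PriceBook(
        reared_piglet_price=j(ref.reared_piglet_price),
        cull_sow_price=j(ref.cull_sow_price),
        gilt_price=j(ref.gilt_price),
        insemination_price=j(ref.insemination_price),
        sow_gestation_feed_rate=j(ref.sow_gestation_feed_rate),
        sow_lactation_feed_rate=j(ref.sow_lactation_feed_rate),
        starter_feed_per_weaned=j(ref.starter_feed_per_weaned),
        rearing_feed_price=j(ref.rearing_feed_price),
        gilt_feed_per_replacement=j(ref.gilt_feed_per_replacement),
        vet_fixed_per_farm=j(ref.vet_fixed_per_farm),
        vet_per_sow={ScenarioName.AVERAGE: vet_avg, ScenarioName.TOP10: vet_avg},
        # disease-free care (piglet castration, iron) is a strict subset
        vet_per_sow_ideal=vet_avg * rng.uniform(0.1, 0.5),
        ear_tag_price=j(ref.ear_tag_price),
        breeding_misc_fixed=j(ref.breeding_misc_fixed),
        slaughter_pig_revenue=j(ref.slaughter_pig_revenue),
        fattening_piglet_base_price=j(ref.fattening_piglet_base_price),
        fattening_piglet_base_weight=ref.fattening_piglet_base_weight,
        fattening_piglet_price_per_kg_over_base=j(ref.fattening_piglet_price_per_kg_over_base),
        fattening_feed_price=j(ref.fattening_feed_price),
        fattening_vet_per_pig={
            ScenarioName.AVERAGE: j(ref.fattening_vet_per_pig[ScenarioName.AVERAGE]),
            ScenarioName.TOP10: j(ref.fattening_vet_per_pig[ScenarioName.TOP10]),
            ScenarioName.IDEAL: 0.0,
        },
        fattening_misc_per_pig=j(ref.fattening_misc_per_pig),
    )


def _draw_pair(
    rng: np.random.Generator, cfg: SyntheticConfig, ref: ScenarioSet
) -> tuple[ScenarioSet, ScenarioSet]:
    rb, rf = ref.breeding, ref.fattening
    ln = lambda x: float(x * np.exp(rng.normal(0.0, cfg.reproduction_jitter)))

    litters = min(ln(rb.litters_per_sow_year.point), 2.6)
    born = ln(rb.piglets_born_alive_per_litter.point)
    pwm = float(rng.beta(2.0, 8.0) * cfg.mortality_max)
    rmort = float(rng.beta(2.0, 20.0) * cfg.mortality_max)
    farrowing = float(rng.uniform(0.70, 0.95))
    repl = float(rng.uniform(0.25, 0.45))
    rfcr = ln(rb.rearing_fcr.point)
    fmort = float(rng.beta(2.0, 20.0) * cfg.mortality_max)
    ffcr = ln(rf.fcr.point)
    fdur = float(np.clip(rng.normal(rf.fattening_duration.point, 5.0), 70.0, 130.0))

    avg_breeding = BreedingParameters(
        gestation_length=rb.gestation_length,
        lactation_length=rb.lactation_length,
        weaning_to_oestrus=float(rng.uniform(10.0, 25.0)),
        piglet_weaning_weight=rb.piglet_weaning_weight,
        reared_sale_weight=rb.reared_sale_weight,
        rearing_duration=rb.rearing_duration,
        rearing_adg=_fixed(rb.rearing_adg.point),
        rearing_fcr=_fixed(rfcr),
        sow_replacement_rate=_fixed(repl),
        litters_per_sow_year=_fixed(litters),
        return_to_oestrus_rate=float(rng.uniform(0.0, 0.2)),
        piglets_weaned_per_litter=born * (1.0 - pwm),
        piglets_weaned_per_sow_year=litters * born * (1.0 - pwm),
        piglets_born_alive_per_litter=_fixed(born),
        preweaning_mortality=pwm,
        rearing_mortality=rmort,
        farrowing_rate=farrowing,
    )
    avg_fattening = FatteningParameters(
        start_weight=rf.start_weight,
        slaughter_weight=rf.slaughter_weight,
        fattening_duration=_fixed(fdur),
        mortality=fmort,
        fcr=_fixed(ffcr),
        adg=1000.0 * (rf.slaughter_weight - rf.start_weight) / fdur,
        service_period=rf.service_period,
    )

    if cfg.dominance:
        up = lambda lo, hi: float(rng.uniform(lo, hi))
        i_litters = min(litters * up(1.02, 1.10), 2.8)
        i_born = born * up(1.10, 1.40)
        i_repl = repl * up(0.70, 0.95)
        i_rfcr = rfcr * up(0.75, 0.95)
        i_ffcr = ffcr * up(0.75, 0.95)
        i_fdur = fdur * up(0.80, 0.95)
    else:
        sym = lambda: float(rng.uniform(0.85, 1.15))
        i_litters, i_born = litters * sym(), born * sym()
        i_repl, i_rfcr = repl * sym(), rfcr * sym()
        i_ffcr, i_fdur = ffcr * sym(), fdur * sym()

    ideal_breeding = BreedingParameters(
        gestation_length=rb.gestation_length,
        lactation_length=rb.lactation_length,
        weaning_to_oestrus=min(avg_breeding.weaning_to_oestrus, 7.0),
        piglet_weaning_weight=rb.piglet_weaning_weight,
        reared_sale_weight=rb.reared_sale_weight,
        rearing_duration=rb.rearing_duration,
        rearing_adg=_pert_around(rng, rb.rearing_adg.mean),
        rearing_fcr=_pert_around(rng, i_rfcr),
        sow_replacement_rate=_pert_around(rng, i_repl),
        litters_per_sow_year=_pert_around(rng, i_litters, rel=0.01),
        return_to_oestrus_rate=0.0,
        piglets_weaned_per_litter=i_born,
        piglets_weaned_per_sow_year=i_litters * i_born,
        piglets_born_alive_per_litter=_pert_around(rng, i_born),
        preweaning_mortality=0.0,
        rearing_mortality=0.0,
        farrowing_rate=1.0,
    )
    ideal_fattening = FatteningParameters(
        start_weight=rf.start_weight,
        slaughter_weight=rf.slaughter_weight,
        fattening_duration=_pert_around(rng, i_fdur, rel=0.03),
        mortality=0.0,
        fcr=_pert_around(rng, i_ffcr),
        adg=1000.0 * (rf.slaughter_weight - rf.start_weight) / i_fdur,
        service_period=rf.service_period,
    )
    return (
        ScenarioSet(name=ScenarioName.AVERAGE, breeding=avg_breeding, fattening=avg_fattening),
        ScenarioSet(name=ScenarioName.IDEAL, breeding=ideal_breeding, fattening=ideal_fattening),
    )


def generate_synthetic_scenarios(cfg: SyntheticConfig) -> list[SyntheticPair]:
    """Draw ``cfg.n_sets`` (Average, Ideal) pairs with matching price books.

    Deterministic for a fixed config.  With ``dominance`` the Ideal
    scenario weakly dominates, which (with non-negative baseline margins)
    makes every AHLE level non-negative.
    """
    rng = np.random.default_rng(cfg.seed)
    fixture = swiss_2023_fixture()
    ref_avg = fixture.scenarios[ScenarioName.AVERAGE]
    out: list[SyntheticPair] = []
    for _ in range(cfg.n_sets):
        average, ideal = _draw_pair(rng, cfg, ref_avg)
        book = None
        for _try in range(_MAX_PRICE_TRIES):
            candidate = _draw_book(rng, fixture.price_book, cfg.price_jitter)
            gm_b = breeding_gross_margin(
                average.breeding, candidate, HerdSpec(HerdKind.BREEDING, 50),
                ScenarioName.AVERAGE,
            ).gross_margin
            gm_f = fattening_gross_margin(
                average.fattening, candidate, ScenarioName.AVERAGE
            ).gross_margin
            if gm_b >= 0.0 and gm_f >= 0.0:
                book = candidate
                break
        if book is None:  # extreme parameter draw: fall back to reference prices
            book = fixture.price_book
        out.append(SyntheticPair(average=average, ideal=ideal, book=book))
    return out
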