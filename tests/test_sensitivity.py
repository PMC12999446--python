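"""One-at-a-time sweeps: default set, oracles, noise bounds, ranking."""

import numpy as np
import pytest

from swine_ahle.model_inputs import ScenarioName
from swine_ahle.sensitivity import (
    SweepSpec,
    default_parameter_set,
    run_all_sweeps,
    run_sweep,
    tornado_ranking,
)


@pytest.fixture(scope="module")
def specs(fixture_config):
    return default_parameter_set(fixture_config.scenarios, iterations_per_increment=200)


def test_default_set_is_nine_plus_four(specs):
    assert len(specs) == 13
    breeding = [s for s in specs if s.parameter_id.startswith("breeding.")]
    fattening = [s for s in specs if s.parameter_id.startswith("fattening.")]
    assert len(breeding) == 9 and len(fattening) == 4


@pytest.mark.parametrize(
    "parameter_id, low, high",
    [
        ("fattening.mortality", 0.0, 0.0153),
        # PERT inputs sweep from their maximum-performance bound
        ("breeding.piglets_born_alive_per_litter", 18.4, 13.0),
        ("fattening.fcr", 2.00, 2.62),
        ("breeding.farrowing_rate", 1.0, 0.81),
        ("breeding.rearing_fcr", 1.28, 1.70),
    ],
)
def test_default_sweep_endpoints(specs, parameter_id, low, high):
    spec = next(s for s in specs if s.parameter_id == parameter_id)
    assert spec.low_value == pytest.approx(low)
    assert spec.high_value == pytest.approx(high)
    vals = spec.increment_values()
    assert len(vals) == 7
    assert np.allclose(np.diff(vals), (high - low) / 6)


def test_equal_endpoints_give_zero_range(fixture_config):
    spec = SweepSpec(
        parameter_id="fattening.fcr", low_value=2.12, high_value=2.12,
        increments=3, iterations_per_increment=100,
        outputs=("ahle_animal_fattening",),
    )
    entry = run_sweep(spec, fixture_config.scenarios, fixture_config.price_book,
                      master_seed=3)["ahle_animal_fattening"]
    assert entry.range == pytest.approx(0.0, abs=1e-9)


def test_fcr_sweep_matches_linear_feed_cost_oracle(fixture_config):
    """Per-pig AHLE falls linearly as Ideal FCR rises toward Average; with
    the swept FCR pinned the Ideal per-pig margin is deterministic, so the
    tornado range equals the feed-line difference exactly."""
    cfg = fixture_config
    spec = next(
        s for s in default_parameter_set(cfg.scenarios, iterations_per_increment=150)
        if s.parameter_id == "fattening.fcr"
    )
    entry = run_sweep(spec, cfg.scenarios, cfg.price_book, master_seed=7)[
        "ahle_animal_fattening"
    ]
    means = entry.increment_means
    assert all(a > b for a, b in zip(means, means[1:]))  # monotone decreasing
    gain = 115.9 - 27.1
    oracle = (spec.high_value - spec.low_value) * gain * cfg.price_book.fattening_feed_price
    assert entry.range == pytest.approx(oracle, rel=1e-9)


def test_preweaning_mortality_sweep_decreases_breeding_ahle(fixture_config):
    cfg = fixture_config
    spec = next(
        s for s in default_parameter_set(cfg.scenarios, iterations_per_increment=400)
        if s.parameter_id == "breeding.preweaning_mortality"
    )
    entry = run_sweep(spec, cfg.scenarios, cfg.price_book, master_seed=5)[
        "ahle_animal_breeding"
    ]
    assert all(a > b for a, b in zip(entry.increment_means, entry.increment_means[1:]))


def test_inert_parameter_range_within_noise(fixture_config, sim10k):
    """Sweeping an input no output depends on leaves only Monte Carlo noise."""
    cfg = fixture_config
    n = 1000
    spec = SweepSpec(
        parameter_id="breeding.weaning_to_oestrus", low_value=7.0, high_value=22.0,
        iterations_per_increment=n,
    )
    entries = run_sweep(spec, cfg.scenarios, cfg.price_book, pop=cfg.population,
                        master_seed=2)
    ideal = sim10k[ScenarioName.IDEAL]
    avg = sim10k[ScenarioName.AVERAGE]
    sd = {
        "ahle_animal_breeding": np.std(ideal.breeding_gm[50]),
        "ahle_animal_fattening": np.std(ideal.fattening_gm),
        "ahle_pop_total": np.std(
            ideal.breeding_gm[50] * 100_878
            + (ideal.fattening_gm * ideal.turns - avg.fattening_gm * avg.turns) * 2_433_981
        ),
    }
    for out_id, entry in entries.items():
        # range of 7 independent means of n draws; 6 SEs is a generous bound
        assert entry.range < 6.0 * sd[out_id] / np.sqrt(n), out_id


def test_unknown_parameter_rejected(fixture_config):
    spec = SweepSpec(parameter_id="breeding.not_a_field", low_value=0, high_value=1,
                     iterations_per_increment=10)
    with pytest.raises(ValueError, match="unknown parameter"):
        run_sweep(spec, fixture_config.scenarios, fixture_config.price_book)


def test_sweep_reproducible_and_substream_stable(fixture_config, specs):
    """Same master seed reproduces a sweep exactly, whether the parameter is
    run alone or alongside the full set (fresh substream per parameter)."""
    cfg = fixture_config
    born = next(s for s in specs if s.parameter_id == "breeding.piglets_born_alive_per_litter")
    alone = run_sweep(born, cfg.scenarios, cfg.price_book, pop=cfg.population,
                      master_seed=17)["ahle_animal_breeding"]
    again = run_sweep(born, cfg.scenarios, cfg.price_book, pop=cfg.population,
                      master_seed=17)["ahle_animal_breeding"]
    assert alone.increment_means == again.increment_means
    subset = [s for s in specs if s.parameter_id.startswith("breeding.pig")] + [born]
    subset = list({s.parameter_id: s for s in subset}.values())
    among = [
        e for e in run_all_sweeps(subset, cfg.scenarios, cfg.price_book,
                                  pop=cfg.population, master_seed=17)
        if e.parameter_id == born.parameter_id and e.output_id == "ahle_animal_breeding"
    ][0]
    assert among.increment_means == alone.increment_means


def test_tornado_ranking_orders_and_ties(specs, fixture_config):
    cfg = fixture_config
    entries = run_all_sweeps(specs[:4], cfg.scenarios, cfg.price_book,
                             pop=cfg.population, master_seed=9)
    ranked = tornado_ranking(entries)
    for group in ranked.values():
        ranges = [e.range for e in group]
        assert ranges == sorted(ranges, reverse=True)
        assert sorted(e.rank for e in group) == list(range(1, len(group) + 1))
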