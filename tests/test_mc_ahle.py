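"""PERT sampling, Monte Carlo reproducibility, and AHLE aggregation."""

import numpy as np
import pytest

import swine_ahle as sa
from swine_ahle.mc_ahle import (
    POPULATION_BREEDING_HERD,
    AhleSummary,
    compute_ahle,
    find_summary,
    run_simulation,
    sample_pert,
)
from swine_ahle.model_inputs import (
    PertSpec,
    ScenarioName,
    SimulationSettings,
)


@pytest.mark.parametrize(
    "triple, tol",
    [
        ((2.31, 2.34, 2.37), 0.001),  # symmetric: mean = mode
        ((2.00, 2.12, 2.23), 0.002),  # asymmetric: mean = (min+4*mode+max)/6
        ((79, 83, 88), 0.05),
    ],
)
def test_pert_sample_mean_matches_closed_form(triple, tol):
    spec = PertSpec(minimum=triple[0], mode=triple[1], maximum=triple[2])
    draws = sample_pert(spec, np.random.default_rng(42), 100_000)
    assert np.all((draws >= spec.minimum) & (draws <= spec.maximum))
    assert draws.mean() == pytest.approx(spec.mean, abs=tol)


def test_pert_degenerate_is_point_mass():
    spec = PertSpec(minimum=3.3, mode=3.3, maximum=3.3)
    assert sample_pert(spec, np.random.default_rng(0)) == 3.3
    assert np.all(sample_pert(spec, np.random.default_rng(0), 50) == 3.3)


@pytest.mark.parametrize("n", [1_000, 10_000, 100_000])
def test_pert_mean_clt_convergence(n):
    """Sample-mean error shrinks at the CLT rate (4 sigma/sqrt(n) bound)."""
    spec = PertSpec(minimum=16.8, mode=17.6, maximum=18.4)
    draws = sample_pert(spec, np.random.default_rng(n), n)
    bound = 4.0 * np.sqrt(spec.variance / n)
    assert abs(draws.mean() - spec.mean) < bound


def test_simulation_bit_exact_reproducibility(fixture_config):
    cfg = fixture_config
    settings = SimulationSettings(iterations=500, seed=99)
    runs = [
        run_simulation(cfg.scenarios, cfg.price_book, settings,
                       target_slaughter=float(cfg.population.slaughter_pigs))
        for _ in range(2)
    ]
    a, b = (r[ScenarioName.IDEAL] for r in runs)
    assert np.array_equal(a.fattening_gm, b.fattening_gm)
    assert np.array_equal(a.breeding_gm[50], b.breeding_gm[50])
    assert np.array_equal(a.demographics.breeding_sows, b.demographics.breeding_sows)
    s1 = compute_ahle(runs[0], pop=cfg.population)
    s2 = compute_ahle(runs[1], pop=cfg.population)
    assert s1 == s2  # bit-identical summaries


def test_degenerate_perts_reduce_to_deterministic_engine(fixture_config, degenerate_ideal):
    cfg = fixture_config
    scenarios = dict(cfg.scenarios)
    scenarios[ScenarioName.IDEAL] = degenerate_ideal
    sim = run_simulation(
        scenarios, cfg.price_book, SimulationSettings(iterations=1, seed=0),
        target_slaughter=1000.0,
    )
    from swine_ahle.economics import HerdKind, HerdSpec, breeding_gross_margin

    direct = breeding_gross_margin(
        degenerate_ideal.breeding, cfg.price_book,
        HerdSpec(HerdKind.BREEDING, 50), ScenarioName.IDEAL,
    ).gross_margin
    assert np.asarray(sim[ScenarioName.IDEAL].breeding_gm[50]).item() == pytest.approx(
        direct, rel=1e-12
    )


def test_ahle_band_and_level_consistency(fixture_config, sim10k, ahle_summaries):
    pop = fixture_config.population
    for s in ahle_summaries:
        assert s.p5 <= s.mean <= s.p95
    per_sow = find_summary(ahle_summaries, "per_animal", "breeding")
    per_kg = find_summary(ahle_summaries, "per_kg", "breeding")
    herd50 = find_summary(ahle_summaries, "per_herd", "breeding", herd_size=50)
    pop_b = find_summary(ahle_summaries, "per_population", "breeding")
    # exact linear relations, draw by draw, hence also on all summaries
    for a, b, k in [
        (per_kg, per_sow, 1 / 200.0),
        (herd50, per_sow, 50.0),
        (pop_b, per_sow, float(pop.breeding_sows)),
    ]:
        assert a.mean == pytest.approx(b.mean * k, rel=1e-12)
        assert a.p5 == pytest.approx(b.p5 * k, rel=1e-12)
        assert a.p95 == pytest.approx(b.p95 * k, rel=1e-12)
    total = find_summary(ahle_summaries, "per_population", "total")
    pop_f = find_summary(ahle_summaries, "per_population", "fattening")
    assert total.mean == pytest.approx(pop_b.mean + pop_f.mean, rel=1e-9)


def test_population_fattening_bases_differ(ahle_summaries):
    """Place-year basis (default) vs per-pig basis are both reported."""
    place = find_summary(ahle_summaries, "per_population", "fattening", basis="place_year")
    per_pig = find_summary(ahle_summaries, "per_population", "fattening", basis="per_pig")
    # one finishing place produces >1 pig per year, so the bases differ widely
    assert place.mean > 2.5 * per_pig.mean


def test_widening_pert_never_narrows_margin_band(fixture_config):
    cfg = fixture_config
    settings = SimulationSettings(iterations=4000, seed=11)

    def band(widen: float) -> float:
        ideal = cfg.scenarios[ScenarioName.IDEAL].model_copy(deep=True)
        spec = ideal.breeding.piglets_born_alive_per_litter.spec
        ideal.breeding.piglets_born_alive_per_litter = sa.ParameterValue(
            kind="pert",
            spec=PertSpec(
                minimum=spec.minimum - widen, mode=spec.mode, maximum=spec.maximum + widen
            ),
        )
        scenarios = dict(cfg.scenarios)
        scenarios[ScenarioName.IDEAL] = ideal
        sim = run_simulation(scenarios, cfg.price_book, settings, target_slaughter=1000.0)
        draws = sim[ScenarioName.IDEAL].breeding_gm[50]
        lo, hi = np.percentile(draws, (5, 95))
        return hi - lo

    widths = [band(w) for w in (0.0, 0.4, 0.8)]
    assert widths[0] < widths[1] < widths[2]


def test_summary_ordering_enforced():
    with pytest.raises(ValueError):
        AhleSummary(level="per_animal", segment="breeding", mean=1.0, p5=2.0, p95=3.0)


def test_missing_population_herd_size_rejected(fixture_config):
    cfg = fixture_config
    sim = run_simulation(
        cfg.scenarios, cfg.price_book, SimulationSettings(iterations=50, seed=1),
        target_slaughter=1000.0, herd_sizes=(20, 150),  # no 50-sow herd
    )
    with pytest.raises(ValueError, match=str(POPULATION_BREEDING_HERD)):
        compute_ahle(sim, pop=cfg.population)
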