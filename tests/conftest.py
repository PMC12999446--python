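import pytest
from hypothesis import HealthCheck, settings

import swine_ahle as sa
from swine_ahle.model_inputs import ScenarioName

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_config():
    return sa.swiss_2023_fixture()


@pytest.fixture(scope="session")
def sim10k(fixture_config):
    """One full 10,000-draw simulation shared across tests."""
    cfg = fixture_config
    return sa.run_simulation(
        cfg.scenarios,
        cfg.price_book,
        cfg.simulation,
        target_slaughter=float(cfg.population.slaughter_pigs),
    )


@pytest.fixture(scope="session")
def ahle_summaries(fixture_config, sim10k):
    return sa.compute_ahle(sim10k, pop=fixture_config.population)


def ahle_for_pair(pair, iterations=200, seed=0):
    """All AHLE summaries for a synthetic (Average, Ideal) pair."""
    settings_ = sa.SimulationSettings(iterations=iterations, seed=seed)
    sim = sa.run_simulation(
        pair.scenarios, pair.book, settings_, target_slaughter=1000.0
    )
    return sa.compute_ahle(sim)


@pytest.fixture(scope="session")
def dominant_pair_summaries():
    """AHLE summaries for 100 independently seeded Ideal-dominant pairs."""
    out = []
    for seed in range(100):
        pair = sa.generate_synthetic_scenarios(
            sa.SyntheticConfig(seed=seed, n_sets=1, dominance=True)
        )[0]
        out.append((seed, ahle_for_pair(pair, iterations=200, seed=seed)))
    return out


@pytest.fixture()
def degenerate_ideal(fixture_config):
    """Fixture Ideal with every PERT collapsed to its mode (point mass)."""
    ideal = fixture_config.scenarios[ScenarioName.IDEAL].model_copy(deep=True)
    for section in (ideal.breeding, ideal.fattening):
        for fname, fval in section:
            if isinstance(fval, sa.ParameterValue) and fval.kind == "pert":
                setattr(
                    section,
                    fname,
                    sa.ParameterValue(kind="fixed", value=fval.spec.mode),
                )
    return ideal
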