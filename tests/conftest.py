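import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from symbioviz import (CommunityScenario, Motif, build_community_network,
                       default_scenario, make_toy_community, select_point)


@pytest.fixture
def two_species():
    """Deterministic two-species community with one motif of each kind."""
    scenario = default_scenario(2, n_time=10, seed=1, noise_sd=0.0)
    models, field = make_toy_community(scenario)
    network = build_community_network(models)
    fluxes = select_point(field, 0, 0)
    return models, field, network, fluxes


@pytest.fixture
def six_species():
    """Six organisms with a shared nutrient and a lactate-style chain."""
    scenario = CommunityScenario(
        n_species=6,
        motifs=[
            Motif("cross_feed_chain", "lac_L", (0, 1, 2)),
            Motif("competition", "gal", (1, 2, 3)),
            Motif("co_secretion", "for", (4, 5)),
            Motif("single_consumer", "pro_L", (3,)),
        ],
        n_time=8,
        seed=7,
        noise_sd=0.0,
    )
    models, field = make_toy_community(scenario)
    network = build_community_network(models)
    fluxes = select_point(field, 0, 0)
    return models, field, network, fluxes
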