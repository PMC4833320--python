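import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbioviz import (FluxSeries, Role,
                       ValidationError, build_community_network,
                       case_study_pair_scenario, classify_metabolites,
                       exchange_profile, make_toy_community, role_report,
                       role_timeline, select_point)
from symbioviz.interaction import DEFAULT_PALETTE, ExchangeProfile
from symbioviz.metagraph import CommunityNetwork, NodeKind, NodeRecord

from oracle import all_predicates, brute_force_role


def profile_network(n_models, connected):
    """Bare network whose single ENV node 'env::m' touches `connected` models."""
    net = CommunityNetwork()
    net.add_node(NodeRecord(id="env::m", kind=NodeKind.ENV_METABOLITE))
    net.env_registry["env::m"] = {(m, "m_e") for m in connected}
    return net


class TestExchangeProfile:
    def test_cross_feeding_pair_signs(self, two_species):
        _m, _f, net, fluxes = two_species
        prof = exchange_profile(net, fluxes, t=5)
        ac = prof.net_exchange["env::ac"]
        assert ac["sp1"] > 0  # producer secretes
        assert ac["sp2"] < 0  # partner takes it up
        glc = prof.net_exchange["env::glc"]
        assert glc["sp1"] < 0 and glc["sp2"] < 0

    def test_all_zero_flux_gives_zero_profile(self, two_species):
        _m, _f, net, fluxes = two_species
        zeroed = {
            mid: FluxSeries(mid, {r: np.zeros(s.n_time) for r in s.values}, s.n_time)
            for mid, s in fluxes.items()
        }
        prof = exchange_profile(net, zeroed, t=0)
        assert all(v == 0.0 for per in prof.net_exchange.values() for v in per.values())

    def test_two_exchange_reactions_net_sum(self):
        """+1 and -0.4 through two exchange reactions on one ENV node -> +0.6."""
        from symbioviz import MetabolicModel, Metabolite, Reaction

        m = MetabolicModel(
            id="m1",
            metabolites=[Metabolite("x_e", compartment="e", is_extracellular=True)],
            reactions=[
                Reaction("EX_x_a", stoichiometry={"x_e": -1.0}, reversible=True,
                         is_exchange=True),
                Reaction("EX_x_b", stoichiometry={"x_e": -1.0}, reversible=True,
                         is_exchange=True),
            ],
            exchange_ids={"EX_x_a", "EX_x_b"},
        )
        net = build_community_network([m])
        fluxes = {"m1": FluxSeries("m1", {"EX_x_a": np.array([1.0]),
                                          "EX_x_b": np.array([-0.4])}, 1)}
        prof = exchange_profile(net, fluxes, t=0)
        assert prof.net_exchange["env::x"]["m1"] == pytest.approx(0.6)

    def test_time_out_of_range_rejected(self, two_species):
        _m, _f, net, fluxes = two_species
        with pytest.raises(ValidationError):
            exchange_profile(net, fluxes, t=99)


class TestClassification:
    @pytest.mark.parametrize("net_flux,expected", [
        ({"eco": 1.0, "sen": -1.0}, Role.CROSS_FEEDING),
        ({"eco": -1.0, "sen": -2.0}, Role.COMPETITION),
        ({"eco": 0.5, "sen": 0.5}, Role.CO_SECRETION),
        ({"eco": 0.0, "sen": 0.0}, Role.INACTIVE),
        ({"eco": 1.0, "sen": 0.0}, Role.SINGLE),
    ])
    def test_two_model_roles(self, net_flux, expected):
        net = profile_network(2, {"eco", "sen"})
        prof = ExchangeProfile(t=0, net_exchange={"env::m": net_flux})
        out = classify_metabolites(prof, net)
        assert out.roles["env::m"] is expected

    def test_single_model_is_single_regardless_of_flux(self):
        net = profile_network(1, {"eco"})
        prof = ExchangeProfile(t=0, net_exchange={"env::m": {"eco": 0.0}})
        assert classify_metabolites(prof, net).roles["env::m"] is Role.SINGLE

    def test_one_producer_two_consumers_is_cross_feeding(self):
        """Lactate-style chain: secreted by one organism, used by two."""
        net = profile_network(3, {"la", "cd", "eco"})
        prof = ExchangeProfile(
            t=0, net_exchange={"env::m": {"la": 2.0, "cd": -1.0, "eco": -0.5}})
        assert classify_metabolites(prof, net).roles["env::m"] is Role.CROSS_FEEDING

    def test_palette_matches_documented_colors(self):
        assert DEFAULT_PALETTE[Role.CROSS_FEEDING] == "#D3D3D3"  # light gray
        assert DEFAULT_PALETTE[Role.COMPETITION] == "#FF0000"    # red
        assert DEFAULT_PALETTE[Role.CO_SECRETION] == "#0000FF"   # blue
        assert DEFAULT_PALETTE[Role.SINGLE] == "#696969"         # dark gray
        assert DEFAULT_PALETTE[Role.INACTIVE] == "#FFFFFF"       # white

    def test_cross_feeding_symmetric_under_direction_swap(self):
        net = profile_network(2, {"a", "b"})
        p1 = ExchangeProfile(t=0, net_exchange={"env::m": {"a": 1.0, "b": -1.0}})
        p2 = ExchangeProfile(t=0, net_exchange={"env::m": {"a": -1.0, "b": 1.0}})
        assert (classify_metabolites(p1, net).roles["env::m"]
                is classify_metabolites(p2, net).roles["env::m"] is Role.CROSS_FEEDING)


@settings(max_examples=300, deadline=None)
@given(
    n_models=st.integers(min_value=2, max_value=8),
    fluxes=st.lists(st.one_of(st.just(0.0),
                              st.floats(min_value=-10, max_value=10,
                                        allow_nan=False)),
                    min_size=8, max_size=8),
)
def test_classifier_agrees_with_brute_force_oracle(n_models, fluxes):
    models = {f"m{i}" for i in range(n_models)}
    net = profile_network(n_models, models)
    per = {f"m{i}": fluxes[i] for i in range(n_models)}
    prof = ExchangeProfile(t=0, net_exchange={"env::m": per})
    got = classify_metabolites(prof, net, epsilon=1e-9).roles["env::m"]
    assert got.value == brute_force_role(models, per, 1e-9)
    # roles partition: exactly one predicate true
    preds = all_predicates(models, per, 1e-9)
    assert sum(preds.values()) == 1
    assert preds[got.value]


@settings(max_examples=100, deadline=None)
@given(
    n_models=st.integers(min_value=2, max_value=6),
    fluxes=st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False),
                    min_size=6, max_size=6),
    scale=st.floats(min_value=0.01, max_value=100, allow_nan=False),
)
def test_invariance_under_relabeling_and_positive_scaling(n_models, fluxes, scale):
    """For epsilon = 0 the role depends only on flux signs, so relabeling
    models and scaling all fluxes by a positive constant preserve it."""
    models = {f"m{i}" for i in range(n_models)}
    per = {f"m{i}": fluxes[i] for i in range(n_models)}
    net = profile_network(n_models, models)
    base = classify_metabolites(
        ExchangeProfile(t=0, net_exchange={"env::m": per}), net, epsilon=0.0)
    relabeled = {f"x{i}": fluxes[i] for i in range(n_models)}
    net2 = profile_network(n_models, set(relabeled))
    out2 = classify_metabolites(
        ExchangeProfile(t=0, net_exchange={"env::m": relabeled}), net2, epsilon=0.0)
    scaled = {m: v * scale for m, v in per.items()}
    out3 = classify_metabolites(
        ExchangeProfile(t=0, net_exchange={"env::m": scaled}), net, epsilon=0.0)
    assert base.roles["env::m"] is out2.roles["env::m"] is out3.roles["env::m"]


class TestTimeline:
    def test_constant_fluxes_give_constant_roles(self, two_species):
        _m, _f, net, fluxes = two_species
        const = {
            mid: FluxSeries(mid, {r: np.full(4, s.values[r][5]) for r in s.values}, 4)
            for mid, s in fluxes.items()
        }
        tl = role_timeline(net, const)
        assert len(tl) == 4
        assert all(tl[t].roles == tl[0].roles for t in range(4))

    def test_role_changes_exactly_at_sign_crossing(self, two_species):
        _m, _f, net, fluxes = two_species
        n_time = 10
        crossing = np.where(np.arange(n_time) < 5, 1.0, -1.0)
        fluxes = dict(fluxes)
        sp1 = fluxes["sp1"]
        values = {r: sp1.values[r].copy() for r in sp1.values}
        values["EX_ac_e"] = crossing  # producer becomes consumer at t=5
        fluxes["sp1"] = FluxSeries("sp1", values, n_time)
        tl = role_timeline(net, fluxes)
        roles = [tl[t].roles["env::ac"] for t in range(n_time)]
        assert roles[:5] == [Role.CROSS_FEEDING] * 5
        assert roles[5:] == [Role.COMPETITION] * 5

    def test_single_time_point(self, two_species):
        _m, _f, net, fluxes = two_species
        one = {
            mid: FluxSeries(mid, {r: s.values[r][:1].copy() for r in s.values}, 1)
            for mid, s in fluxes.items()
        }
        assert len(role_timeline(net, one)) == 1


class TestReport:
    def test_case_study_pair_roles_from_tidy_output(self):
        """Lactose exclusive to species A; acetate and methionine cross-fed
        in opposite directions — read off the classifier's tidy table."""
        models, field = make_toy_community(case_study_pair_scenario(seed=3))
        net = build_community_network(models)
        fluxes = select_point(field, 0, 0)
        rep = role_report(net, fluxes)
        mid = rep[rep.time == 5].set_index("metabolite")
        assert mid.loc["env::lcts", "role"] == "single"
        assert mid.loc["env::ac", "role"] == "cross_feeding"
        assert mid.loc["env::met_L", "role"] == "cross_feeding"
        prof = exchange_profile(net, fluxes, t=5)
        assert prof.net_exchange["env::ac"]["sp1"] > 0 > prof.net_exchange["env::ac"]["sp2"]
        assert prof.net_exchange["env::met_L"]["sp2"] > 0 > prof.net_exchange["env::met_L"]["sp1"]

    def test_report_columns_and_colors(self, two_species):
        _m, _f, net, fluxes = two_species
        rep = role_report(net, fluxes)
        assert list(rep.columns) == ["metabolite", "time", "n_producers",
                                     "n_consumers", "role", "color"]
        comp = rep[(rep.role == "competition")]
        assert (comp.color == "#FF0000").all()
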