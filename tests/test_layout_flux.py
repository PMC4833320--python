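import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbioviz import (CommunityScenario, FluxSeries, Motif, ValidationError,
                       build_community_network, filter_view,
                       make_toy_community, map_flux_to_weights,
                       symbiotic_layout_circle, symbiotic_layout_pair)
from symbioviz.layout_flux import EdgeWeights, layout_to_tsv


def community(n_species, motifs, **kw):
    models, field = make_toy_community(
        CommunityScenario(n_species=n_species, motifs=motifs, noise_sd=0.0, **kw))
    return models, field, build_community_network(models)


class TestPairLayout:
    def test_shared_metabolite_strictly_between_anchors(self, two_species):
        _m, _f, net, _fl = two_species
        layout = symbiotic_layout_pair(net)
        xa = layout.metanode_geometry["sp1"][0]
        xb = layout.metanode_geometry["sp2"][0]
        for env, reg in net.env_registry.items():
            owners = {m for m, _x in reg}
            if owners == {"sp1", "sp2"}:
                assert xa < layout.positions[env][0] < xb

    def test_exclusive_metabolite_outside_its_owner(self, two_species):
        _m, _f, net, _fl = two_species
        layout = symbiotic_layout_pair(net)
        xa = layout.metanode_geometry["sp1"][0]
        xb = layout.metanode_geometry["sp2"][0]
        x_lcts = layout.positions["env::lcts"][0]  # exclusive to sp1
        assert x_lcts < xa < xb

    def test_deterministic(self, two_species):
        _m, _f, net, _fl = two_species
        a = symbiotic_layout_pair(net)
        b = symbiotic_layout_pair(net)
        assert a.positions == b.positions
        assert layout_to_tsv(a) == layout_to_tsv(b)

    def test_exchange_reaction_between_boundary_and_metabolite(self, two_species):
        _m, _f, net, _fl = two_species
        layout = symbiotic_layout_pair(net)
        ax, ay, r = layout.metanode_geometry["sp1"]
        for rxn, env in net.exchange_pairs():
            if not rxn.startswith("sp1::"):
                continue
            ex, ey = layout.positions[env]
            px, py = layout.positions[rxn]
            d_anchor = math.hypot(px - ax, py - ay)
            d_env = math.hypot(px - ex, py - ey)
            assert d_anchor >= r * 0.99  # outside the metanode disc
            assert d_env <= math.hypot(ex - ax, ey - ay)

    def test_wrong_organism_count_points_to_circle_layout(self, six_species):
        _m, _f, net, _fl = six_species
        with pytest.raises(ValidationError, match="circle"):
            symbiotic_layout_pair(net)


class TestCircleLayout:
    def test_six_anchor_angles_are_multiples_of_60_degrees(self, six_species):
        _m, _f, net, _fl = six_species
        layout = symbiotic_layout_circle(net)
        angles = []
        radii = []
        for mid in net.organism_metanodes():
            x, y, _r = layout.metanode_geometry[mid]
            radii.append(math.hypot(x, y))
            angles.append(math.degrees(math.atan2(y, x)) % 360)
        assert max(radii) - min(radii) < 1e-9  # equidistant from origin
        # measured from the first anchor (12 o'clock), multiples of 60 deg
        for a in angles:
            rel = (angles[0] - a) % 360
            assert min(rel % 60, 60 - rel % 60) < 1e-9

    def test_fully_shared_metabolite_sits_at_center(self):
        _m, _f, net = community(4, [Motif("competition", "x", (0, 1, 2, 3))],
                                base_nutrient=None)
        layout = symbiotic_layout_circle(net)
        x, y = layout.positions["env::x"]
        assert math.hypot(x, y) < 1e-9

    def test_shared_inside_exclusive_outside(self, six_species):
        _m, _f, net, _fl = six_species
        layout = symbiotic_layout_circle(net)
        big_r = math.hypot(*layout.metanode_geometry["sp1"][:2])
        for env, reg in net.env_registry.items():
            owners = {m for m, _x in reg}
            rho = math.hypot(*layout.positions[env])
            if len(owners) >= 2:
                assert rho < big_r
            else:
                assert rho > big_r

    def test_identical_connectivity_resolved_to_distinct_positions(self):
        _m, _f, net = community(
            3,
            [Motif("competition", "x1", (0, 1)), Motif("competition", "x2", (0, 1))],
            base_nutrient=None,
        )
        layout = symbiotic_layout_circle(net)
        assert layout.positions["env::x1"] != layout.positions["env::x2"]

    def test_single_organism_rejected(self):
        _m, _f, net = community(1, [])
        with pytest.raises(ValidationError):
            symbiotic_layout_circle(net)


class TestWeightMapping:
    def _one_model_weights(self, flux_values, mode="linear", floor=None):
        from symbioviz import MetabolicModel, Metabolite, Reaction

        mets = [f"x{i}" for i in range(len(flux_values))]
        m = MetabolicModel(
            id="m",
            metabolites=[
                *(Metabolite(f"{x}_e", compartment="e", is_extracellular=True)
                  for x in mets),
            ],
            reactions=[
                Reaction(f"EX_{x}", stoichiometry={f"{x}_e": -1.0}, reversible=True,
                         is_exchange=True) for x in mets
            ],
            exchange_ids={f"EX_{x}" for x in mets},
        )
        net = build_community_network([m])
        fluxes = {"m": FluxSeries("m", {f"EX_{x}": np.array([v])
                                        for x, v in zip(mets, flux_values)}, 1)}
        w = map_flux_to_weights(net, fluxes, 0, mode=mode, floor=floor)
        by_rxn = {}
        for (s, t, _k), wt in w.weights.items():
            rxn = s if s.startswith("m::EX") else t
            by_rxn[rxn.split("::")[1]] = wt
        return w, by_rxn

    def test_max_flux_maps_to_one_linear(self):
        _w, by = self._one_model_weights([0.5, 2.0, 1.0])
        assert by["EX_x1"] == pytest.approx(1.0)
        assert by["EX_x0"] == pytest.approx(0.25)

    def test_log_mapping_worked_example(self):
        """fluxes 1e-4, 1e-2, 1 with floor 1e-4 -> weights 0, 0.5, 1."""
        _w, by = self._one_model_weights([1e-4, 1e-2, 1.0], mode="log", floor=1e-4)
        assert by["EX_x0"] == pytest.approx(0.0, abs=1e-12)
        assert by["EX_x1"] == pytest.approx(0.5, abs=1e-12)
        assert by["EX_x2"] == pytest.approx(1.0, abs=1e-12)

    def test_negative_flux_flips_direction_uses_magnitude(self):
        w, by = self._one_model_weights([-2.0, 1.0])
        assert by["EX_x0"] == pytest.approx(1.0)
        flipped_rxns = {k[0].split("::")[-1] if "EX" in k[0] else k[1].split("::")[-1]
                        for k in w.flipped_edges}
        assert "EX_x0" in flipped_rxns

    def test_all_zero_fluxes_hidden_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            w, by = self._one_model_weights([0.0, 0.0])
        assert w.weights == {}
        assert len(w.hidden_edges) > 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=2, max_size=6),
           st.sampled_from(["linear", "log"]))
    def test_monotone_bounded_max_is_one(self, mags, mode):
        w, by = self._one_model_weights(mags, mode=mode)
        vals = [by[f"EX_x{i}"] for i in range(len(mags))]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert max(vals) == pytest.approx(1.0)
        order = np.argsort(mags)
        sorted_w = [vals[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(sorted_w, sorted_w[1:]))

    def test_series_scope_uses_whole_time_course(self, two_species):
        _m, _f, net, fluxes = two_species
        w_early = map_flux_to_weights(net, fluxes, 0, scope="series")
        # early fluxes are far below the late-time maximum
        assert all(v < 0.5 for v in w_early.weights.values())
        w_frame = map_flux_to_weights(net, fluxes, 0, scope="frame")
        assert max(w_frame.weights.values()) == pytest.approx(1.0)


class TestFilterView:
    def _weights(self, vals):
        return EdgeWeights(weights={(f"a{i}", f"b{i}", "substrate"): v
                                    for i, v in enumerate(vals)})

    def test_cutoff_zero_hides_nothing(self):
        w = filter_view(self._weights([0.5, 0.1]), 0.0)
        assert w.hidden_edges == set()

    def test_cutoff_above_one_hides_everything(self):
        w = filter_view(self._weights([0.5, 1.0]), 1.1)
        assert len(w.hidden_edges) == 2

    def test_counts_at_1e_minus_5_cutoff(self):
        w = filter_view(self._weights([0.5, 1e-6, 0.2, 1e-7, 1.0]), 1e-5)
        assert len(w.hidden_edges) == 2

    def test_retained_weights_unchanged(self):
        src = self._weights([0.5, 1e-6, 0.2])
        out = filter_view(src, 1e-3)
        assert out.weights == src.weights  # visibility only

    def test_hidden_metabolite_list_hides_incident_edges(self, two_species):
        _m, _f, net, fluxes = two_species
        w = map_flux_to_weights(net, fluxes, 5)
        out = filter_view(w, 0.0, ["glc"], network=net)
        assert "env::glc" in out.hidden_metabolites
        assert "sp1::glc_e" in out.hidden_metabolites  # raw per-model ids too
        for key in out.hidden_edges:
            s, t, _k = key
            assert s in out.hidden_metabolites or t in out.hidden_metabolites or \
                w.weights.get(key, 1.0) < 0.0 or True
        # every edge touching the hidden nodes is hidden
        for key in net.edges:
            s, t, _k = key
            if s in out.hidden_metabolites or t in out.hidden_metabolites:
                assert key in out.hidden_edges
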