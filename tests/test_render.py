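import io

import pytest
from lxml import etree
from PIL import Image

from symbioviz import (ComparisonSpec, RenderOptions, Role, ValidationError,
                       classify_metabolites, exchange_profile, filter_view,
                       layout_for, map_flux_to_weights, render_animation,
                       render_comparison, render_frame, render_frame_png,
                       role_timeline)
from symbioviz.interaction import RoleAssignment
from symbioviz.render import SPARK_W, _spark_points

SVG_NS = "{http://www.w3.org/2000/svg}"


def frame_inputs(net, fluxes, t=5, cutoff=0.0):
    weights = filter_view(map_flux_to_weights(net, fluxes, t), cutoff, network=net)
    roles = classify_metabolites(exchange_profile(net, fluxes, t), net)
    layout = layout_for(net, roles=roles)
    return layout, weights, roles


class TestFrame:
    def test_svg_parses_and_census_matches_visible_nodes(self, two_species):
        _m, _f, net, fluxes = two_species
        layout, weights, roles = frame_inputs(net, fluxes)
        svg = render_frame(net, layout, weights, roles, fluxes=fluxes, t=5)
        root = etree.fromstring(svg.encode())
        assert root.tag == f"{SVG_NS}svg"
        circles = root.findall(f".//{SVG_NS}circle")
        env_circles = [c for c in circles if c.get("class") == "env"]
        met_circles = [c for c in circles if c.get("class") == "metabolite"]
        from symbioviz.metagraph import NodeKind

        visible = [n for n in net.visible_nodes()
                   if n not in weights.hidden_metabolites]
        n_env = sum(1 for n in visible if net.nodes[n].kind is NodeKind.ENV_METABOLITE)
        n_met = sum(1 for n in visible if net.nodes[n].kind is NodeKind.METABOLITE)
        assert len(env_circles) == n_env
        assert len(met_circles) == n_met

    def test_env_nodes_filled_with_role_colors(self, two_species):
        _m, _f, net, fluxes = two_species
        layout, weights, roles = frame_inputs(net, fluxes)
        svg = render_frame(net, layout, weights, roles, fluxes=fluxes, t=5)
        root = etree.fromstring(svg.encode())
        fills = {c.get("fill") for c in root.findall(f".//{SVG_NS}circle")
                 if c.get("class") == "env"}
        # competition (glc) red, cross-feeding (ac) light gray at t=5
        assert "#FF0000" in fills and "#D3D3D3" in fills

    def test_all_edges_below_cutoff_yields_no_edge_lines(self, two_species):
        _m, _f, net, fluxes = two_species
        layout, weights, roles = frame_inputs(net, fluxes, cutoff=1.1)
        svg = render_frame(net, layout, weights, roles, fluxes=fluxes, t=5)
        root = etree.fromstring(svg.encode())
        edges = [l for l in root.findall(f".//{SVG_NS}line")
                 if l.get("class") == "edge"]
        assert edges == []

    def test_byte_deterministic(self, two_species):
        _m, _f, net, fluxes = two_species
        layout, weights, roles = frame_inputs(net, fluxes)
        a = render_frame(net, layout, weights, roles, fluxes=fluxes, t=5)
        b = render_frame(net, layout, weights, roles, fluxes=fluxes, t=5)
        assert a == b

    def test_missing_position_names_the_node(self, two_species):
        _m, _f, net, fluxes = two_species
        layout, weights, roles = frame_inputs(net, fluxes)
        del layout.positions["env::ac"]
        with pytest.raises(ValidationError, match="env::ac"):
            render_frame(net, layout, weights, roles, fluxes=fluxes, t=5)

    def test_png_backend_produces_an_image(self, two_species):
        _m, _f, net, fluxes = two_species
        layout, weights, roles = frame_inputs(net, fluxes)
        png = render_frame_png(net, layout, weights, roles)
        img = Image.open(io.BytesIO(png))
        assert img.format == "PNG"
        assert img.size == RenderOptions().canvas


class TestSparklines:
    def test_cursor_at_t0_sits_at_left_edge(self):
        pts, cursor = _spark_points([1.0, 2.0, 3.0], t=0)
        assert cursor == 0.0
        assert pts[0][0] == 0.0 and pts[-1][0] == SPARK_W

    def test_cursor_at_last_t_sits_at_right_edge(self):
        _pts, cursor = _spark_points([1.0, 2.0, 3.0], t=2)
        assert cursor == SPARK_W

    def test_single_time_point_cursor_left(self):
        pts, cursor = _spark_points([1.0], t=0)
        assert cursor == 0.0 and len(pts) == 1

    def test_sparkline_glyphs_present_for_exchange_reactions(self, two_species):
        _m, _f, net, fluxes = two_species
        layout, weights, roles = frame_inputs(net, fluxes)
        svg = render_frame(net, layout, weights, roles, fluxes=fluxes, t=0)
        root = etree.fromstring(svg.encode())
        glyphs = root.findall(f".//{SVG_NS}g[@class='sparkline']")
        assert len(glyphs) > 0
        cursor = glyphs[0].find(f"{SVG_NS}line[@class='cursor']")
        rect = glyphs[0].find(f"{SVG_NS}rect")
        assert cursor.get("x1") == rect.get("x")  # t=0 -> left edge


class TestAnimation:
    def _series(self, net, fluxes, n=None):
        assignments = role_timeline(net, fluxes)
        if n is not None:
            assignments = assignments[:n]
        weight_series = [map_flux_to_weights(net, fluxes, t)
                         for t in range(len(assignments))]
        return weight_series, assignments

    def test_frame_count_equals_time_points(self, two_species):
        _m, _f, net, fluxes = two_species
        ws, rs = self._series(net, fluxes)
        layout = layout_for(net)
        gif = render_animation(net, layout, ws, rs)
        img = Image.open(io.BytesIO(gif))
        assert img.format == "GIF"
        assert img.n_frames == 10
        assert img.info.get("loop") == 0
        assert img.info.get("duration") == 500

    def test_single_time_point_single_frame(self, two_species):
        _m, _f, net, fluxes = two_species
        ws, rs = self._series(net, fluxes, n=1)
        gif = render_animation(net, layout_for(net), ws, rs)
        assert Image.open(io.BytesIO(gif)).n_frames == 1

    def test_length_mismatch_rejected(self, two_species):
        _m, _f, net, fluxes = two_species
        ws, rs = self._series(net, fluxes)
        with pytest.raises(ValidationError, match="length"):
            render_animation(net, layout_for(net), ws[:-1], rs)

    def test_role_change_alters_node_pixels_between_frames(self, two_species):
        """Force a role flip at t=5 and check the ENV node's color changes
        exactly between frames 4 and 5 at its canvas position."""
        _m, _f, net, fluxes = two_species
        layout = layout_for(net)
        ws, rs = self._series(net, fluxes)
        flip = Role.CO_SECRETION
        for t in range(5, 10):
            rs[t] = RoleAssignment(t=t, roles={**rs[t].roles, "env::ac": flip},
                                   palette=rs[t].palette)
        gif = render_animation(net, layout, ws, rs)
        img = Image.open(io.BytesIO(gif))
        from symbioviz.render import RenderOptions, _Canvas

        cv = _Canvas(layout, RenderOptions())
        x, y = cv.pt(layout.positions["env::ac"])
        px = (int(x), int(y))

        def color_at(frame):
            img.seek(frame)
            return img.convert("RGB").getpixel(px)

        assert color_at(4) != color_at(5)
        assert color_at(5) == (0, 0, 255)  # co-secretion blue

    def test_layout_constant_across_frames(self, two_species):
        # the same layout object feeds every frame; spot-check frame sizes
        _m, _f, net, fluxes = two_species
        ws, rs = self._series(net, fluxes)
        gif = render_animation(net, layout_for(net), ws, rs)
        img = Image.open(io.BytesIO(gif))
        sizes = set()
        for t in range(img.n_frames):
            img.seek(t)
            sizes.add(img.size)
        assert len(sizes) == 1


class TestComparison:
    def test_segments_mode_draws_k_substrokes_per_edge(self, two_species):
        _m, _f, net, fluxes = two_species
        conds = [("a", fluxes), ("b", fluxes), ("c", fluxes)]
        spec = ComparisonSpec(conditions=conds, mode="segments")
        svg = render_comparison(net, layout_for(net), spec, t=5)
        root = etree.fromstring(svg.encode())
        segs = [l for l in root.findall(f".//{SVG_NS}line")
                if l.get("class") == "segment"]
        conds_seen = {}
        for seg in segs:
            key = (seg.get("x1"), seg.get("y1"))
            conds_seen.setdefault(seg.get("data-condition"), 0)
            conds_seen[seg.get("data-condition")] += 1
        assert set(conds_seen) == {"a", "b", "c"}
        assert len(set(conds_seen.values())) == 1  # same count per condition

    def test_identical_conditions_difference_hides_all_edges(self, two_species):
        _m, _f, net, fluxes = two_species
        spec = ComparisonSpec(conditions=[("a", fluxes), ("b", fluxes)],
                              mode="difference")
        svg = render_comparison(net, layout_for(net), spec, t=5)
        root = etree.fromstring(svg.encode())
        diffs = [l for l in root.findall(f".//{SVG_NS}line")
                 if l.get("class") == "difference"]
        assert diffs == []

    def test_difference_antisymmetry(self, two_species):
        """Swapping the two conditions flips every stroke's sign/color but
        leaves widths identical."""
        from symbioviz import FluxSeries

        _m, _f, net, fluxes = two_species
        doubled = {
            mid: FluxSeries(mid, {r: 2.0 * s.values[r] for r in s.values}, s.n_time)
            for mid, s in fluxes.items()
        }
        fwd = ComparisonSpec(conditions=[("a", fluxes), ("b", doubled)],
                             mode="difference")
        rev = ComparisonSpec(conditions=[("b", doubled), ("a", fluxes)],
                             mode="difference")
        layout = layout_for(net)

        def strokes(spec):
            root = etree.fromstring(render_comparison(net, layout, spec, t=5).encode())
            return {
                (l.get("x1"), l.get("y1"), l.get("x2"), l.get("y2")):
                    (l.get("data-sign"), l.get("stroke-width"))
                for l in root.findall(f".//{SVG_NS}line")
                if l.get("class") == "difference"
            }

        sf, sr = strokes(fwd), strokes(rev)
        assert set(sf) == set(sr) and len(sf) > 0
        for key in sf:
            sign_f, width_f = sf[key]
            sign_r, width_r = sr[key]
            assert sign_f != sign_r
            assert width_f == width_r

    def test_difference_mode_requires_exactly_two(self, two_species):
        _m, _f, net, fluxes = two_species
        with pytest.raises(ValidationError, match="exactly 2"):
            ComparisonSpec(conditions=[("a", fluxes), ("b", fluxes), ("c", fluxes)],
                           mode="difference")

    def test_fewer_than_two_conditions_rejected(self, two_species):
        _m, _f, net, fluxes = two_species
        with pytest.raises(ValidationError):
            ComparisonSpec(conditions=[("a", fluxes)], mode="segments")


class TestOptions:
    def test_palette_must_cover_all_roles(self):
        with pytest.raises(ValidationError, match="palette"):
            RenderOptions(role_palette={Role.SINGLE: "#000000"})

    def test_frame_delay_must_be_positive(self):
        with pytest.raises(ValidationError):
            RenderOptions(frame_ms=0)
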