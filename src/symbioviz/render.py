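"""Static, animated and comparative rendering of community networks.

Two backends share the same geometry: a deterministic SVG 1.1 writer
(byte-identical output for fixed inputs) for static frames and
comparisons, and a Pillow raster backend for PNG frames and animated
GIFs.  Exchange reactions can be drawn as sparkline glyphs — a small
flux-vs-time plot with a cursor at the current time point.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .errors import ValidationError
from .flux_io import FluxSeries
from .interaction import DEFAULT_PALETTE, Role, RoleAssignment
from .layout_flux import EdgeWeights, LayoutResult
from .metagraph import SEP, CommunityNetwork, NodeKind

Point = Tuple[float, float]

#: default colors for non-ENV node kinds
KIND_FILL = {
    NodeKind.METABOLITE: "#9ECAE1",
    NodeKind.REACTION: "#FDD49E",
    NodeKind.ENZYME: "#A1D99B",
    NodeKind.METANODE: "none",
    NodeKind.ENV_METABOLITE: "#FFFFFF",
}

CONDITION_COLORS = ("#1B9E77", "#D95F02", "#7570B3", "#E7298A", "#66A61E", "#E6AB02")


@dataclass
class RenderOptions:
    canvas: Tuple[int, int] = (900, 600)
    role_palette: Mapping[Role, str] = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    show_sparklines: bool = True
    frame_ms: int = 500
    node_radius: float = 7.0
    font_size: int = 11
    margin: float = 40.0
    show_labels: bool = True

    def __post_init__(self) -> None:
        if self.frame_ms <= 0:
            raise ValidationError("frame_ms must be > 0")
        missing = [r for r in Role if r not in self.role_palette]
        if missing:
            raise ValidationError(f"palette missing roles: {[r.value for r in missing]}")


@dataclass
class ComparisonSpec:
    """Flux sources for multi-condition comparison of one network."""

    conditions: List[Tuple[str, Mapping[str, FluxSeries]]]
    mode: str = "segments"  # or "difference"
    condition_palette: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValidationError("comparison needs >= 2 conditions")
        if self.mode not in ("segments", "difference"):
            raise ValidationError(f"unknown comparison mode {self.mode!r}")
        if self.mode == "difference" and len(self.conditions) != 2:
            raise ValidationError(
                f"difference mode compares exactly 2 conditions, got {len(self.conditions)}"
            )

    def color(self, label: str) -> str:
        if self.condition_palette and label in self.condition_palette:
            return self.condition_palette[label]
        idx = [lbl for lbl, _f in self.conditions].index(label)
        return CONDITION_COLORS[idx % len(CONDITION_COLORS)]


def stroke_width(weight: float) -> float:
    """Shared width law: stroke width in px for a [0,1] edge weight."""
    return 0.5 + 4.5 * weight


class _Canvas:
    """Affine map from layout coordinates to canvas pixels (y flipped)."""

    def __init__(self, layout: LayoutResult, options: RenderOptions):
        xs = [p[0] for p in layout.positions.values()] or [0.0]
        ys = [p[1] for p in layout.positions.values()] or [0.0]
        for mid, (ax, ay, r) in layout.metanode_geometry.items():
            xs.extend([ax - r, ax + r])
            ys.extend([ay - r, ay + r])
        w, h = options.canvas
        m = options.margin
        span_x = max(max(xs) - min(xs), 1e-9)
        span_y = max(max(ys) - min(ys), 1e-9)
        self.scale = min((w - 2 * m) / span_x, (h - 2 * m) / span_y)
        self.x0, self.y0 = min(xs), min(ys)
        self.off_x = (w - self.scale * span_x) / 2.0
        self.off_y = (h - self.scale * span_y) / 2.0
        self.h = h

    def pt(self, p: Point) -> Point:
        x = self.off_x + (p[0] - self.x0) * self.scale
        y = self.h - (self.off_y + (p[1] - self.y0) * self.scale)
        return (x, y)

    def length(self, r: float) -> float:
        return r * self.scale


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _visible_elements(
    network: CommunityNetwork,
    weights: Optional[EdgeWeights],
) -> Tuple[List[str], List[Tuple[Tuple[str, str, str], float, bool]]]:
    """Visible node ids and (edge key, weight, flipped) triples."""
    hidden_mets = weights.hidden_metabolites if weights is not None else set()
    nodes = [n for n in network.visible_nodes() if n not in hidden_mets]
    vis = set(nodes)
    edges = []
    for key, e in sorted(network.edges.items()):
        if e.source not in vis or e.target not in vis:
            continue
        if weights is None:
            edges.append((key, 0.1, False))
            continue
        if key in weights.hidden_edges:
            continue
        w = weights.weights.get(key)
        if w is None:
            if e.reaction_ref is not None and weights.weights:
                continue  # flux known elsewhere but not for this edge: hide
            w = 0.1
        edges.append((key, w, key in weights.flipped_edges))
    return nodes, edges


def _node_color(network: CommunityNetwork, nid: str,
                roles: Optional[RoleAssignment], options: RenderOptions) -> str:
    node = network.nodes[nid]
    if node.kind is NodeKind.ENV_METABOLITE and roles is not None and nid in roles.roles:
        return options.role_palette[roles.roles[nid]]
    return KIND_FILL[node.kind]


def _sparkline_nodes(network: CommunityNetwork,
                     fluxes: Optional[Mapping[str, FluxSeries]]) -> Dict[str, FluxSeries]:
    """Exchange reaction node id -> its model's flux series."""
    if not fluxes:
        return {}
    out = {}
    for rxn_node, _env in network.exchange_pairs():
        model_id, raw = rxn_node.split(SEP, 1)
        series = fluxes.get(model_id)
        if series is not None and raw in series.values:
            out[rxn_node] = series
    return out


# ---------------------------------------------------------------------------
# SVG backend
# ---------------------------------------------------------------------------

def render_frame(
    network: CommunityNetwork,
    layout: LayoutResult,
    weights: Optional[EdgeWeights],
    roles: Optional[RoleAssignment],
    fluxes: Optional[Mapping[str, FluxSeries]] = None,
    t: int = 0,
    options: Optional[RenderOptions] = None,
) -> str:
    """Render one time point as a standalone SVG 1.1 document (string).

    ENV metabolites are filled with their role color, edge stroke width is
    proportional to the [0,1] weight, hidden elements are absent, and
    exchange reactions become sparkline glyphs (flux vs. time, cursor at
    ``t``) when enabled and flux series are supplied.
    """
    options = options or RenderOptions()
    nodes, edges = _visible_elements(network, weights)
    for nid in nodes:
        if nid not in layout.positions:
            raise ValidationError(f"no layout position for visible node {nid!r}")
    cv = _Canvas(layout, options)
    spark = _sparkline_nodes(network, fluxes) if options.show_sparklines else {}

    w, h = options.canvas
    out: List[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{h}" viewBox="0 0 {w} {h}">'
    )
    out.append(
        '<defs><marker id="arrow" viewBox="0 0 10 10" refX="9" refY="5" '
        'markerWidth="6" markerHeight="6" orient="auto-start-reverse">'
        '<path d="M 0 0 L 10 5 L 0 10 z" fill="#555555"/></marker></defs>'
    )
    out.append(f'<rect width="{w}" height="{h}" fill="#FFFFFF"/>')

    # metanode outlines
    for mid in sorted(layout.metanode_geometry):
        if network.node_hidden(mid) or mid not in network.nodes:
            continue
        ax, ay, r = layout.metanode_geometry[mid]
        cx, cy = cv.pt((ax, ay))
        out.append(
            f'<circle class="metanode" cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
            f'r="{_fmt(cv.length(r))}" fill="none" stroke="#888888" '
            'stroke-dasharray="6,4" stroke-width="1.5"/>'
        )

    # edges
    for key, wgt, flip in edges:
        s, tgt, _k = key
        p1, p2 = cv.pt(layout.positions[s]), cv.pt(layout.positions[tgt])
        if flip:
            p1, p2 = p2, p1
        out.append(
            f'<line class="edge" x1="{_fmt(p1[0])}" y1="{_fmt(p1[1])}" '
            f'x2="{_fmt(p2[0])}" y2="{_fmt(p2[1])}" stroke="#555555" '
            f'stroke-width="{_fmt(stroke_width(wgt))}" marker-end="url(#arrow)"/>'
        )

    # nodes
    for nid in sorted(nodes):
        node = network.nodes[nid]
        if node.kind is NodeKind.METANODE:
            continue  # drawn as outline above
        x, y = cv.pt(layout.positions[nid])
        fill = _node_color(network, nid, roles, options)
        if node.kind is NodeKind.REACTION and nid in spark:
            out.append(_sparkline_svg(nid, spark[nid], x, y, t))
        elif node.kind is NodeKind.REACTION:
            rr = options.node_radius
            out.append(
                f'<rect class="reaction" x="{_fmt(x - rr)}" y="{_fmt(y - rr)}" '
                f'width="{_fmt(2 * rr)}" height="{_fmt(2 * rr)}" '
                f'fill="{fill}" stroke="#333333"/>'
            )
        else:
            cls = "env" if node.kind is NodeKind.ENV_METABOLITE else node.kind.value
            out.append(
                f'<circle class="{cls}" cx="{_fmt(x)}" cy="{_fmt(y)}" '
                f'r="{_fmt(options.node_radius)}" fill="{fill}" stroke="#333333"/>'
            )
        if options.show_labels and node.kind in (NodeKind.ENV_METABOLITE,):
            out.append(
                f'<text class="label" x="{_fmt(x + options.node_radius + 2)}" '
                f'y="{_fmt(y + 3)}" font-size="{options.font_size}" '
                f'font-family="sans-serif">{_xml_escape(node.label)}</text>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _xml_escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
            .replace('"', "&quot;"))


SPARK_W, SPARK_H = 40.0, 20.0


def _spark_points(series_vals, t: int) -> Tuple[List[Point], float]:
    """Normalized sparkline polyline points in glyph-local [0,W]x[0,H] and
    the cursor x offset for time ``t`` (t=0 at the left edge)."""
    vals = list(map(float, series_vals))
    n = len(vals)
    lo, hi = min(vals), max(vals)
    span = (hi - lo) or 1.0
    pts = []
    for i, v in enumerate(vals):
        px = SPARK_W * (i / (n - 1) if n > 1 else 0.0)
        py = SPARK_H * (1.0 - (v - lo) / span)
        pts.append((px, py))
    cursor = SPARK_W * (t / (n - 1) if n > 1 else 0.0)
    return pts, cursor


def _sparkline_svg(nid: str, series: FluxSeries, x: float, y: float, t: int) -> str:
    raw = nid.split(SEP, 1)[1]
    vals = series.values[raw]
    pts, cursor = _spark_points(vals, t)
    x0, y0 = x - SPARK_W / 2, y - SPARK_H / 2
    poly = " ".join(f"{_fmt(x0 + px)},{_fmt(y0 + py)}" for px, py in pts)
    return (
        f'<g class="sparkline" data-node="{_xml_escape(nid)}">'
        f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(SPARK_W)}" '
        f'height="{_fmt(SPARK_H)}" fill="#FFFFFF" stroke="#333333"/>'
        f'<polyline points="{poly}" fill="none" stroke="#2171B5" stroke-width="1"/>'
        f'<line class="cursor" x1="{_fmt(x0 + cursor)}" y1="{_fmt(y0)}" '
        f'x2="{_fmt(x0 + cursor)}" y2="{_fmt(y0 + SPARK_H)}" '
        'stroke="#D62728" stroke-width="1"/></g>'
    )


# ---------------------------------------------------------------------------
# Comparative rendering
# ---------------------------------------------------------------------------

def render_comparison(
    network: CommunityNetwork,
    layout: LayoutResult,
    spec: ComparisonSpec,
    t: int,
    options: Optional[RenderOptions] = None,
) -> str:
    """Render a multi-condition comparison at time ``t`` as SVG.

    ``segments`` mode draws each visible edge as K parallel sub-strokes,
    one per condition, width proportional to that condition's rescaled
    flux at ``t`` (joint normalization across conditions so widths are
    comparable).  ``difference`` mode draws a single stroke of width
    proportional to |v1 - v2|, colored by the sign of the difference;
    edges with zero difference are hidden.
    """
    options = options or RenderOptions()
    cv = _Canvas(layout, options)

    # per-edge per-condition flux at t, joint normalization
    edge_keys = [key for key, e in sorted(network.edges.items()) if e.reaction_ref]
    flux_by_cond: List[Dict[Tuple[str, str, str], float]] = []
    for _label, fmap in spec.conditions:
        per: Dict[Tuple[str, str, str], float] = {}
        for key in edge_keys:
            e = network.edges[key]
            model_id, raw = e.reaction_ref.split(SEP, 1)
            series = fmap.get(model_id)
            if series is not None and raw in series.values:
                per[key] = float(series.values[raw][t])
        flux_by_cond.append(per)
    vmax = max((abs(v) for per in flux_by_cond for v in per.values()), default=0.0)

    w, h = options.canvas
    out = ['<?xml version="1.0" encoding="UTF-8"?>',
           f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
           f'width="{w}" height="{h}" viewBox="0 0 {w} {h}">',
           f'<rect width="{w}" height="{h}" fill="#FFFFFF"/>']
    for mid in sorted(layout.metanode_geometry):
        ax, ay, r = layout.metanode_geometry[mid]
        cx, cy = cv.pt((ax, ay))
        out.append(
            f'<circle class="metanode" cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
            f'r="{_fmt(cv.length(r))}" fill="none" stroke="#888888" '
            'stroke-dasharray="6,4" stroke-width="1.5"/>'
        )

    vis = set(network.visible_nodes())
    k_cond = len(spec.conditions)
    for key in edge_keys:
        s, tgt, _k = key
        if s not in vis or tgt not in vis or s not in layout.positions or tgt not in layout.positions:
            continue
        p1, p2 = cv.pt(layout.positions[s]), cv.pt(layout.positions[tgt])
        dx, dy = p2[0] - p1[0], p2[1] - p1[1]
        norm = math.hypot(dx, dy) or 1.0
        ux, uy = -dy / norm, dx / norm  # unit perpendicular
        if spec.mode == "segments":
            if vmax == 0.0:
                continue
            for ci, (label, _f) in enumerate(spec.conditions):
                v = flux_by_cond[ci].get(key)
                if v is None:
                    continue
                wgt = abs(v) / vmax
                off = (ci - (k_cond - 1) / 2.0) * 3.0
                out.append(
                    f'<line class="segment" data-condition="{_xml_escape(label)}" '
                    f'x1="{_fmt(p1[0] + off * ux)}" y1="{_fmt(p1[1] + off * uy)}" '
                    f'x2="{_fmt(p2[0] + off * ux)}" y2="{_fmt(p2[1] + off * uy)}" '
                    f'stroke="{spec.color(label)}" '
                    f'stroke-width="{_fmt(stroke_width(wgt))}"/>'
                )
        else:  # difference
            v1 = flux_by_cond[0].get(key, 0.0)
            v2 = flux_by_cond[1].get(key, 0.0)
            d = v1 - v2
            dmax = max(
                (abs(flux_by_cond[0].get(kk, 0.0) - flux_by_cond[1].get(kk, 0.0))
                 for kk in edge_keys), default=0.0,
            )
            if d == 0.0 or dmax == 0.0:
                continue  # identical fluxes: edge hidden
            wgt = abs(d) / dmax
            color = spec.color(spec.conditions[0][0]) if d > 0 else spec.color(spec.conditions[1][0])
            out.append(
                f'<line class="difference" data-sign="{"+" if d > 0 else "-"}" '
                f'x1="{_fmt(p1[0])}" y1="{_fmt(p1[1])}" '
                f'x2="{_fmt(p2[0])}" y2="{_fmt(p2[1])}" '
                f'stroke="{color}" stroke-width="{_fmt(stroke_width(wgt))}"/>'
            )

    for nid in sorted(vis):
        node = network.nodes[nid]
        if node.kind is NodeKind.METANODE or nid not in layout.positions:
            continue
        x, y = cv.pt(layout.positions[nid])
        cls = "env" if node.kind is NodeKind.ENV_METABOLITE else node.kind.value
        out.append(
            f'<circle class="{cls}" cx="{_fmt(x)}" cy="{_fmt(y)}" '
            f'r="{_fmt(options.node_radius)}" fill="{KIND_FILL[node.kind]}" '
            'stroke="#333333"/>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Raster backend (PNG frames, animated GIF)
# ---------------------------------------------------------------------------

def render_frame_png(
    network: CommunityNetwork,
    layout: LayoutResult,
    weights: Optional[EdgeWeights],
    roles: Optional[RoleAssignment],
    options: Optional[RenderOptions] = None,
    scale: float = 1.0,
) -> bytes:
    """Render one frame as PNG bytes (Pillow backend, same geometry as SVG)."""
    img = _raster_frame(network, layout, weights, roles, options or RenderOptions(), scale)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def _raster_frame(network, layout, weights, roles, options, scale=1.0,
                  time_cursor=None):
    from PIL import Image, ImageDraw

    nodes, edges = _visible_elements(network, weights)
    for nid in nodes:
        if nid not in layout.positions:
            raise ValidationError(f"no layout position for visible node {nid!r}")
    cv = _Canvas(layout, options)
    w, h = options.canvas
    img = Image.new("RGB", (int(w * scale), int(h * scale)), "#FFFFFF")
    draw = ImageDraw.Draw(img)

    def s(p: Point) -> Point:
        return (p[0] * scale, p[1] * scale)

    for mid in sorted(layout.metanode_geometry):
        if mid not in network.nodes or network.node_hidden(mid):
            continue
        ax, ay, r = layout.metanode_geometry[mid]
        cx, cy = s(cv.pt((ax, ay)))
        rr = cv.length(r) * scale
        draw.ellipse([cx - rr, cy - rr, cx + rr, cy + rr], outline="#888888", width=1)

    for key, wgt, flip in edges:
        src, tgt, _k = key
        p1, p2 = s(cv.pt(layout.positions[src])), s(cv.pt(layout.positions[tgt]))
        if flip:
            p1, p2 = p2, p1
        draw.line([p1, p2], fill="#555555", width=max(1, round(stroke_width(wgt) * scale)))

    rr = options.node_radius * scale
    for nid in sorted(nodes):
        node = network.nodes[nid]
        if node.kind is NodeKind.METANODE:
            continue
        x, y = s(cv.pt(layout.positions[nid]))
        fill = _node_color(network, nid, roles, options)
        if node.kind is NodeKind.REACTION:
            draw.rectangle([x - rr, y - rr, x + rr, y + rr], fill=fill, outline="#333333")
        else:
            draw.ellipse([x - rr, y - rr, x + rr, y + rr], fill=fill, outline="#333333")

    if time_cursor is not None:
        # time-slider strip: a bar along the bottom with a cursor at t
        t, n = time_cursor
        wpx, hpx = img.size
        x0, x1, yb = 10 * scale, wpx - 10 * scale, hpx - 8 * scale
        draw.line([(x0, yb), (x1, yb)], fill="#BBBBBB", width=max(1, int(2 * scale)))
        frac = t / (n - 1) if n > 1 else 0.0
        cx = x0 + frac * (x1 - x0)
        draw.line([(cx, yb - 5 * scale), (cx, yb + 5 * scale)], fill="#D62728",
                  width=max(1, int(2 * scale)))
    return img


def render_animation(
    network: CommunityNetwork,
    layout: LayoutResult,
    weight_series: Sequence[EdgeWeights],
    role_series: Sequence[RoleAssignment],
    options: Optional[RenderOptions] = None,
) -> bytes:
    """Render an animated GIF: one frame per time point, constant layout,
    frame delay ``options.frame_ms``, looping forever."""
    options = options or RenderOptions()
    if len(weight_series) != len(role_series):
        raise ValidationError(
            f"weight series ({len(weight_series)}) and role series "
            f"({len(role_series)}) lengths differ"
        )
    if not weight_series:
        raise ValidationError("need at least one time point to animate")
    n = len(weight_series)
    frames = [
        _raster_frame(network, layout, wts, rls, options, time_cursor=(t, n))
        for t, (wts, rls) in enumerate(zip(weight_series, role_series))
    ]
    buf = io.BytesIO()
    frames[0].save(
        buf, format="GIF", save_all=True, append_images=frames[1:],
        duration=options.frame_ms, loop=0, optimize=False, disposal=2,
    )
    return buf.getvalue()
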