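"""Symbiotic layouts and flux-to-edge-weight mapping.

Layouts emphasize inter-organism interaction: organism metanodes sit
side-by-side (two organisms) or on a circle (more), shared environmental
metabolites gather between/inside, exclusive ones sit outside their owner.
All geometry derives deterministically from node counts; ordering is
id-lexicographic throughout.

Geometry constants
------------------
* metanode radius       ``r(n) = 40 + 6 * sqrt(n)`` for ``n`` member nodes
* pairwise separation   anchors at ``(-D, 0)`` and ``(+D, 0)`` with
                        ``D = max(r_A, r_B) + 80``
* circle radius         ``R = max(150, N * (r_max + 40) / pi)`` for N organisms
* shared ENV pull       barycenter of connected anchors scaled by 0.5
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import ValidationError
from .flux_io import FluxSeries
from .interaction import RoleAssignment
from .metagraph import SEP, CommunityNetwork, EdgeKey, NodeKind

Point = Tuple[float, float]


@dataclass
class LayoutResult:
    """Node coordinates plus metanode anchor/radius geometry."""

    positions: Dict[str, Point]
    metanode_geometry: Dict[str, Tuple[float, float, float]]

    def validate_finite(self) -> None:
        for nid, (x, y) in self.positions.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValidationError(f"non-finite position for node {nid!r}")


@dataclass
class EdgeWeights:
    """[0,1] edge widths plus visibility state feeding the renderer."""

    weights: Dict[EdgeKey, float]
    mode: str = "linear"  # or "log"
    cutoff: float = 0.0
    hidden_edges: Set[EdgeKey] = field(default_factory=set)
    hidden_metabolites: Set[str] = field(default_factory=set)
    #: edges whose drawn direction is reversed (negative flux on a reversible reaction)
    flipped_edges: Set[EdgeKey] = field(default_factory=set)

    def visible_weight(self, key: EdgeKey) -> Optional[float]:
        if key in self.hidden_edges:
            return None
        return self.weights.get(key)


def _metanode_radius(n_members: int) -> float:
    return 40.0 + 6.0 * math.sqrt(max(n_members, 1))


def _env_partition(network: CommunityNetwork) -> Tuple[Dict[str, Set[str]], List[str]]:
    """ENV node -> set of connected organism ids, plus sorted ENV ids."""
    conn = {
        env: {m for m, _x in reg} for env, reg in network.env_registry.items()
    }
    return conn, sorted(conn)


def _place_internals(
    network: CommunityNetwork,
    positions: Dict[str, Point],
    metanode_id: str,
    anchor: Point,
    radius: float,
) -> None:
    """Deterministic ring placement of a metanode's visible members."""
    members = sorted(
        n for n in network.members(metanode_id)
        if not network.node_hidden(n) and n not in positions
    )
    if not members:
        return
    k = len(members)
    inner = radius * 0.6
    for i, nid in enumerate(members):
        theta = math.pi / 2 - 2 * math.pi * i / k
        positions[nid] = (anchor[0] + inner * math.cos(theta),
                          anchor[1] - inner * math.sin(theta))


def _place_exchange_reactions(
    network: CommunityNetwork,
    positions: Dict[str, Point],
    geometry: Dict[str, Tuple[float, float, float]],
) -> None:
    """Exchange reaction nodes sit midway between their metanode boundary
    (toward the ENV metabolite) and the metabolite itself."""
    for rxn_node, env_id in network.exchange_pairs():
        if network.node_hidden(rxn_node) or env_id not in positions:
            continue
        owner = network.nodes[rxn_node].owner
        if owner is None or owner not in geometry:
            continue
        ax, ay, r = geometry[owner]
        ex, ey = positions[env_id]
        dx, dy = ex - ax, ey - ay
        dist = math.hypot(dx, dy) or 1.0
        bx, by = ax + r * dx / dist, ay + r * dy / dist  # boundary point
        positions[rxn_node] = ((bx + ex) / 2.0, (by + ey) / 2.0)


def symbiotic_layout_pair(
    network: CommunityNetwork,
    roles: Optional[RoleAssignment] = None,
) -> LayoutResult:
    """Two-organism symbiotic layout.

    Metanodes at ``(-D, 0)`` and ``(+D, 0)`` (id order); ENV metabolites
    shared by both on the central ``x = 0`` column (ordered by role, then
    id, when ``roles`` is given), exclusive ones on the outer side of their
    owner; exchange reactions midway between metanode boundary and
    metabolite.  Deterministic.
    """
    organisms = network.organism_metanodes()
    if len(organisms) != 2:
        raise ValidationError(
            f"pairwise layout needs exactly 2 organism metanodes, got {len(organisms)}; "
            "use symbiotic_layout_circle for larger communities"
        )
    a, b = sorted(organisms)
    r_a = _metanode_radius(len(network.members(a)))
    r_b = _metanode_radius(len(network.members(b)))
    d = max(r_a, r_b) + 80.0
    geometry = {a: (-d, 0.0, r_a), b: (+d, 0.0, r_b)}
    positions: Dict[str, Point] = {a: (-d, 0.0), b: (+d, 0.0)}

    conn, env_ids = _env_partition(network)

    def role_key(env: str) -> Tuple:
        if roles is not None and env in roles.roles:
            return (roles.roles[env].value, env)
        return ("", env)

    shared = sorted((e for e in env_ids if conn[e] >= {a, b}), key=role_key)
    excl_a = [e for e in env_ids if conn[e] == {a}]
    excl_b = [e for e in env_ids if conn[e] == {b}]

    dy = 28.0
    for i, env in enumerate(shared):
        positions[env] = (0.0, (i - (len(shared) - 1) / 2.0) * dy)
    for i, env in enumerate(excl_a):
        positions[env] = (-(d + r_a + 60.0), (i - (len(excl_a) - 1) / 2.0) * dy)
    for i, env in enumerate(excl_b):
        positions[env] = (+(d + r_b + 60.0), (i - (len(excl_b) - 1) / 2.0) * dy)

    _place_exchange_reactions(network, positions, geometry)
    for mid in (a, b):
        _place_internals(network, positions, mid, positions[mid], geometry[mid][2])
    _place_loose_nodes(network, positions)
    res = LayoutResult(positions=positions, metanode_geometry=geometry)
    res.validate_finite()
    return res


def symbiotic_layout_circle(network: CommunityNetwork) -> LayoutResult:
    """Multi-organism symbiotic layout.

    N organism metanodes on a circle of radius R (equiangular, first at
    12 o'clock, proceeding clockwise in input order); ENV metabolites
    connected to >=2 organisms at the barycenter of their connected
    anchors scaled toward the center by 0.5 (coincident positions are
    separated by an id-sorted spiral); exclusive ENV metabolites radially
    outside their owner.
    """
    organisms = network.organism_metanodes()
    n = len(organisms)
    if n < 2:
        raise ValidationError(f"circular layout needs >=2 organism metanodes, got {n}")
    radii = {m: _metanode_radius(len(network.members(m))) for m in organisms}
    r_max = max(radii.values())
    big_r = max(150.0, n * (r_max + 40.0) / math.pi)

    geometry: Dict[str, Tuple[float, float, float]] = {}
    positions: Dict[str, Point] = {}
    angle: Dict[str, float] = {}
    for k, mid in enumerate(organisms):
        theta = math.pi / 2 - 2 * math.pi * k / n  # 12 o'clock, clockwise
        x, y = big_r * math.cos(theta), big_r * math.sin(theta)
        geometry[mid] = (x, y, radii[mid])
        positions[mid] = (x, y)
        angle[mid] = theta

    conn, env_ids = _env_partition(network)
    shared = [e for e in env_ids if len(conn[e]) >= 2]
    # barycenter pulled toward the center; spiral separation of collisions
    raw: Dict[str, Point] = {}
    for env in shared:
        anchors = [positions[m] for m in sorted(conn[env])]
        bx = sum(p[0] for p in anchors) / len(anchors)
        by = sum(p[1] for p in anchors) / len(anchors)
        raw[env] = (0.5 * bx, 0.5 * by)
    groups: Dict[Tuple[float, float], List[str]] = {}
    for env in shared:
        key = (round(raw[env][0], 6), round(raw[env][1], 6))
        groups.setdefault(key, []).append(env)
    golden = math.pi * (3 - math.sqrt(5))
    for key, members in sorted(groups.items()):
        for j, env in enumerate(sorted(members)):
            if j == 0:
                positions[env] = raw[env]
            else:
                rho = min(8.0 * j, big_r * 0.35)
                positions[env] = (raw[env][0] + rho * math.cos(golden * j),
                                  raw[env][1] + rho * math.sin(golden * j))

    for env in env_ids:
        if len(conn[env]) != 1:
            continue
        (owner,) = conn[env]
        theta = angle[owner]
        siblings = sorted(e for e in env_ids if conn[e] == {owner})
        i = siblings.index(env)
        fan = (i - (len(siblings) - 1) / 2.0) * (math.pi / max(18, 3 * len(siblings)))
        rho = big_r + radii[owner] + 50.0
        positions[env] = (rho * math.cos(theta + fan), rho * math.sin(theta + fan))

    _place_exchange_reactions(network, positions, geometry)
    for mid in organisms:
        _place_internals(network, positions, mid, positions[mid], radii[mid])
    _place_loose_nodes(network, positions)
    res = LayoutResult(positions=positions, metanode_geometry=geometry)
    res.validate_finite()
    return res


def _place_loose_nodes(network: CommunityNetwork, positions: Dict[str, Point]) -> None:
    """Any remaining visible node (e.g. from a bare edge list) on an outer ring."""
    loose = sorted(n for n in network.visible_nodes() if n not in positions)
    if not loose:
        return
    if positions:
        rho = 80.0 + max(math.hypot(x, y) for x, y in positions.values())
    else:
        rho = 120.0
    k = len(loose)
    for i, nid in enumerate(loose):
        theta = math.pi / 2 - 2 * math.pi * i / k
        positions[nid] = (rho * math.cos(theta), rho * math.sin(theta))


def layout_for(network: CommunityNetwork,
               roles: Optional[RoleAssignment] = None) -> LayoutResult:
    """Pairwise layout for 2 organisms, circular otherwise."""
    if len(network.organism_metanodes()) == 2:
        return symbiotic_layout_pair(network, roles=roles)
    return symbiotic_layout_circle(network)


# ---------------------------------------------------------------------------
# Flux -> edge weights
# ---------------------------------------------------------------------------

def map_flux_to_weights(
    network: CommunityNetwork,
    fluxes: Mapping[str, FluxSeries],
    t: int,
    mode: str = "linear",
    floor: Optional[float] = None,
    scope: str = "series",
    edges: Optional[Iterable[EdgeKey]] = None,
) -> EdgeWeights:
    """Rescale reaction fluxes at time ``t`` into [0, 1] edge weights.

    ``linear``: ``w = |v| / vmax``.  ``log``: ``w = (log10|v| - log10 floor)
    / (log10 vmax - log10 floor)`` clipped to [0, 1]; ``floor`` defaults to
    the smallest nonzero |v| in scope.  ``vmax`` is taken over the
    normalization *scope*: ``"series"`` (all time points — the default, so
    animation frames stay mutually comparable) or ``"frame"`` (time ``t``
    only).  ``edges`` restricts the mapping to a selection (default: every
    edge with a reaction reference).  Zero-flux edges are hidden rather
    than drawn at zero width; negative flux on a reversible reaction flips
    the drawn direction and uses |v|.
    """
    if mode not in ("linear", "log"):
        raise ValidationError(f"unknown mode {mode!r}")
    if scope not in ("series", "frame"):
        raise ValidationError(f"unknown scope {scope!r}")
    selection = set(edges) if edges is not None else None

    def flux_of(model_id: str, raw_rxn: str, ti: int) -> Optional[float]:
        series = fluxes.get(model_id)
        if series is None or raw_rxn not in series.values:
            return None
        if not (0 <= ti < series.n_time):
            raise ValidationError(f"time index {ti} out of range 0..{series.n_time - 1}")
        return float(series.values[raw_rxn][ti])

    # collect the mapped edge set and flux magnitudes
    edge_flux: Dict[EdgeKey, float] = {}
    mags_scope: List[float] = []
    for key, e in sorted(network.edges.items()):
        if e.reaction_ref is None:
            continue
        if selection is not None and key not in selection:
            continue
        model_id, raw_rxn = e.reaction_ref.split(SEP, 1)
        v = flux_of(model_id, raw_rxn, t)
        if v is None:
            continue
        edge_flux[key] = v
        series = fluxes[model_id]
        if scope == "series":
            mags_scope.extend(abs(float(x)) for x in series.values[raw_rxn])
        else:
            mags_scope.append(abs(v))

    vmax = max(mags_scope, default=0.0)
    weights: Dict[EdgeKey, float] = {}
    hidden: Set[EdgeKey] = set()
    flipped: Set[EdgeKey] = set()
    if vmax == 0.0:
        if edge_flux:
            warnings.warn("all fluxes are zero in scope; all mapped edges hidden",
                          stacklevel=2)
        return EdgeWeights(weights={}, mode=mode, hidden_edges=set(edge_flux),
                           flipped_edges=set())

    if mode == "log":
        nonzero = [m for m in mags_scope if m > 0]
        lo = floor if floor is not None else min(nonzero)
        if lo <= 0:
            raise ValidationError("log floor must be positive")
        log_lo, log_hi = math.log10(lo), math.log10(vmax)

    for key, v in edge_flux.items():
        a = abs(v)
        if a == 0.0:
            hidden.add(key)
            continue
        if mode == "linear":
            w = a / vmax
        else:
            if log_hi == log_lo:
                w = 1.0
            else:
                w = (math.log10(a) - log_lo) / (log_hi - log_lo)
            w = min(1.0, max(0.0, w))
        weights[key] = w
        if v < 0:
            flipped.add(key)
    return EdgeWeights(weights=weights, mode=mode, hidden_edges=hidden,
                       flipped_edges=flipped)


def filter_view(
    weights: EdgeWeights,
    cutoff: float,
    hidden_metabolite_list: Sequence[str] = (),
    network: Optional[CommunityNetwork] = None,
    hide_inactive: Optional[RoleAssignment] = None,
) -> EdgeWeights:
    """Hide low-weight edges and listed metabolites (with incident edges).

    Retained weights are never altered — only visibility changes.  Listed
    metabolites match ENV node ids, node labels, or raw per-model
    metabolite ids (so ``H2O_e0``-style cofactor lists work).  With
    ``hide_inactive``, ENV nodes classified INACTIVE are hidden too.
    The caller is expected to recompute the symbiotic layout afterwards.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    hidden_edges = set(weights.hidden_edges)
    hidden_mets = set(weights.hidden_metabolites)
    hidden_edges.update(k for k, w in weights.weights.items() if w < cutoff)

    targets = set(hidden_metabolite_list)
    if hide_inactive is not None:
        from .interaction import Role

        targets.update(e for e, r in hide_inactive.roles.items() if r is Role.INACTIVE)
    if targets and network is not None:
        for nid in sorted(network.nodes):
            node = network.nodes[nid]
            if node.kind not in (NodeKind.METABOLITE, NodeKind.ENV_METABOLITE):
                continue
            raw = nid.split(SEP, 1)[1] if SEP in nid else nid
            names = {nid, raw, node.label}
            if node.kind is NodeKind.ENV_METABOLITE:
                names.update(x for _m, x in network.env_registry.get(nid, set()))
            if names & targets:
                hidden_mets.add(nid)
        for key in network.edges:
            s, t, _k = key
            if s in hidden_mets or t in hidden_mets:
                hidden_edges.add(key)
    elif targets:
        hidden_mets.update(targets)

    return EdgeWeights(
        weights=dict(weights.weights),
        mode=weights.mode,
        cutoff=cutoff,
        hidden_edges=hidden_edges,
        hidden_metabolites=hidden_mets,
        flipped_edges=set(weights.flipped_edges),
    )


def layout_to_tsv(layout: LayoutResult) -> str:
    """Serialize a layout as ``node<TAB>x<TAB>y`` rows."""
    lines = ["#node\tx\ty"]
    for nid in sorted(layout.positions):
        x, y = layout.positions[nid]
        lines.append(f"{nid}\t{x:.4f}\t{y:.4f}")
    return "\n".join(lines) + "\n"
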