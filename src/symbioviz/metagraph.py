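"""Community metagraph construction and transformation.

A community network is a bipartite metabolite/reaction graph per organism,
each organism wrapped in a collapsible *metanode*, plus one duplicated
*environmental* (ENV) node per distinct exchanged extracellular metabolite.
ENV nodes are owned by no organism and mediate all inter-organism edges.

Edge conventions
----------------
* one SUBSTRATE edge (metabolite -> reaction) per distinct pair with a
  negative net coefficient, one PRODUCT edge (reaction -> metabolite) per
  pair with a positive net coefficient — coefficient magnitude is ignored;
* each (exchange reaction, ENV node) pair carries **two** directed EXCHANGE
  edges, ``env -> reaction`` (uptake side) and ``reaction -> env``
  (secretion side).  With this convention the iJO1366 E. coli model yields
  4,713 nodes and 10,831 edges when loaded as a one-organism community.

All iteration is id-sorted; the module is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import ValidationError
from .model_io import MetabolicModel, detect_exchange_reactions, split_compartment

ENV_NS = "env"
SEP = "::"


class NodeKind(str, Enum):
    REACTION = "reaction"
    METABOLITE = "metabolite"
    ENV_METABOLITE = "env_metabolite"
    ENZYME = "enzyme"
    METANODE = "metanode"


class EdgeKind(str, Enum):
    SUBSTRATE = "substrate"
    PRODUCT = "product"
    EXCHANGE = "exchange"
    REGULATORY = "regulatory"
    #: edge created by collapsing a metanode; carries a multiplicity
    AGGREGATE = "aggregate"


@dataclass
class NodeRecord:
    id: str
    kind: NodeKind
    owner: Optional[str] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = self.id


@dataclass
class EdgeRecord:
    source: str
    target: str
    kind: EdgeKind
    reaction_ref: Optional[str] = None
    multiplicity: int = 1

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.source, self.target, self.kind.value)


EdgeKey = Tuple[str, str, str]


@dataclass
class CommunityNetwork:
    """Typed nodes + directed edges + metanode membership + ENV registry."""

    nodes: Dict[str, NodeRecord] = field(default_factory=dict)
    edges: Dict[EdgeKey, EdgeRecord] = field(default_factory=dict)
    #: node id -> set of metanode ids it belongs to (may be several)
    membership: Dict[str, Set[str]] = field(default_factory=dict)
    collapsed: Set[str] = field(default_factory=set)
    #: ENV node id -> {(model_id, raw extracellular metabolite id)}
    env_registry: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    #: (model_id, raw exchange reaction id) -> +-1 sign s.t. sign*flux = secretion
    exchange_orientation: Dict[Tuple[str, str], int] = field(default_factory=dict)
    #: reaction nodes promoted to metanodes by enzyme attachment
    reaction_metanodes: Set[str] = field(default_factory=set)
    #: collapse undo-log: metanode id -> edges removed when it collapsed
    _collapse_store: Dict[str, List[EdgeRecord]] = field(default_factory=dict)

    # -- basic mutation ----------------------------------------------------
    def add_node(self, node: NodeRecord, metanodes: Iterable[str] = ()) -> None:
        self.nodes[node.id] = node
        ms = set(metanodes)
        if ms:
            self.membership.setdefault(node.id, set()).update(ms)

    def add_edge(self, edge: EdgeRecord) -> None:
        self.edges[edge.key] = edge

    # -- queries -----------------------------------------------------------
    def metanode_ids(self) -> Set[str]:
        return {n.id for n in self.nodes.values() if n.kind is NodeKind.METANODE} | set(
            self.reaction_metanodes
        )

    def organism_metanodes(self) -> List[str]:
        """Top-level organism metanodes, in insertion order."""
        return [n.id for n in self.nodes.values() if n.kind is NodeKind.METANODE]

    def members(self, metanode_id: str) -> Set[str]:
        return {nid for nid, ms in self.membership.items() if metanode_id in ms}

    def neighbors(self, node_id: str) -> Set[str]:
        """Direct neighbors over both edge directions."""
        if node_id not in self.nodes:
            raise ValidationError(f"unknown node {node_id!r}")
        out = set()
        for (s, t, _k) in self.edges:
            if s == node_id:
                out.add(t)
            elif t == node_id:
                out.add(s)
        return out

    def node_hidden(self, node_id: str) -> bool:
        """A node is hidden iff it has metanodes and all of them are collapsed."""
        ms = self.membership.get(node_id)
        if not ms:
            return False
        return ms <= self.collapsed

    def visible_nodes(self) -> List[str]:
        return sorted(nid for nid in self.nodes if not self.node_hidden(nid))

    def visible_edges(self) -> List[EdgeRecord]:
        vis = set(self.visible_nodes())
        return [e for k, e in sorted(self.edges.items()) if e.source in vis and e.target in vis]

    def env_nodes(self) -> List[str]:
        return sorted(n.id for n in self.nodes.values() if n.kind is NodeKind.ENV_METABOLITE)

    def exchange_pairs(self) -> List[Tuple[str, str]]:
        """Sorted (exchange reaction node id, ENV node id) pairs."""
        out = []
        for (s, t, k), _e in sorted(self.edges.items()):
            if k == EdgeKind.EXCHANGE.value and t.startswith(ENV_NS + SEP):
                out.append((s, t))
        return out

    def validate(self) -> None:
        for nid, ms in self.membership.items():
            if nid not in self.nodes:
                raise ValidationError(f"membership lists unknown node {nid!r}")
            bad = ms - self.metanode_ids()
            if bad:
                raise ValidationError(f"node {nid!r} member of non-metanode(s) {sorted(bad)}")
        for (s, t, _k), _e in self.edges.items():
            if s not in self.nodes or t not in self.nodes:
                raise ValidationError(f"edge ({s!r}, {t!r}) references unknown node")
        env_ids = {n.id for n in self.nodes.values() if n.kind is NodeKind.ENV_METABOLITE}
        if set(self.env_registry) != env_ids:
            raise ValidationError("env_registry keys differ from ENV_METABOLITE node set")
        for nid in env_ids:
            if self.nodes[nid].owner is not None:
                raise ValidationError(f"ENV node {nid!r} must have no owner")


# ---------------------------------------------------------------------------
# ENV id normalization
# ---------------------------------------------------------------------------

def normalize_env_id(met_id: str, synonyms: Optional[Mapping[str, str]] = None) -> str:
    """Normalize an extracellular metabolite id for cross-model matching.

    Strips a BiGG-style ``M_`` prefix and a compartment suffix
    (``[e]`` / ``_e`` / ``_e0`` ...), then applies the optional synonym
    table (useful to reconcile BiGG vs. SEED namespaces).
    """
    base = met_id
    if base.startswith("M_") and len(base) > 2:
        base = base[2:]
    base, _comp = split_compartment(base)
    if synonyms:
        base = synonyms.get(base, base)
    return base


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_community_network(
    models: Sequence[MetabolicModel],
    synonyms: Optional[Mapping[str, str]] = None,
) -> CommunityNetwork:
    """Assemble the community metagraph from one or more organism models.

    Node ids are namespaced ``<model_id>::<raw_id>``; ENV duplicates live
    in ``env::<normalized_id>``.  The resulting node count always equals
    ``sum(|metabolites| + |reactions|) + |ENV| + n_models``.
    """
    if not models:
        raise ValidationError("at least one model is required")
    ids = [m.id for m in models]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"duplicate model ids: {sorted({i for i in ids if ids.count(i) > 1})}")

    net = CommunityNetwork()
    for model in models:
        model.validate()
        mid = model.id
        net.add_node(NodeRecord(id=mid, kind=NodeKind.METANODE, owner=None, label=model.name))
        for met in model.metabolites:
            net.add_node(
                NodeRecord(id=f"{mid}{SEP}{met.id}", kind=NodeKind.METABOLITE,
                           owner=mid, label=met.name),
                metanodes=[mid],
            )
        exchange = detect_exchange_reactions(model)
        for rxn in model.reactions:
            rnode = f"{mid}{SEP}{rxn.id}"
            net.add_node(
                NodeRecord(id=rnode, kind=NodeKind.REACTION, owner=mid, label=rxn.name),
                metanodes=[mid],
            )
            for met_id in sorted(rxn.stoichiometry):
                coeff = rxn.stoichiometry[met_id]
                mnode = f"{mid}{SEP}{met_id}"
                if coeff < 0:
                    net.add_edge(EdgeRecord(mnode, rnode, EdgeKind.SUBSTRATE, reaction_ref=rnode))
                else:
                    net.add_edge(EdgeRecord(rnode, mnode, EdgeKind.PRODUCT, reaction_ref=rnode))
            if rxn.id in exchange:
                (met_id,) = rxn.stoichiometry
                env_id = f"{ENV_NS}{SEP}{normalize_env_id(met_id, synonyms)}"
                if env_id not in net.nodes:
                    net.add_node(NodeRecord(id=env_id, kind=NodeKind.ENV_METABOLITE,
                                            owner=None, label=env_id.split(SEP, 1)[1]))
                    net.env_registry[env_id] = set()
                net.env_registry[env_id].add((mid, met_id))
                # uptake side and secretion side, per the documented convention
                net.add_edge(EdgeRecord(env_id, rnode, EdgeKind.EXCHANGE, reaction_ref=rnode))
                net.add_edge(EdgeRecord(rnode, env_id, EdgeKind.EXCHANGE, reaction_ref=rnode))
                # positive flux = secretion when the metabolite is the substrate
                coeff = rxn.stoichiometry[met_id]
                net.exchange_orientation[(mid, rxn.id)] = 1 if coeff < 0 else -1
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Collapse / expand
# ---------------------------------------------------------------------------

def collapse_metanode(network: CommunityNetwork, metanode_id: str) -> CommunityNetwork:
    """Collapse a metanode in place: hide members, aggregate boundary edges.

    Every edge between an internal and an external node is replaced by one
    AGGREGATE edge per (direction-insensitive metanode/external pair) whose
    ``multiplicity`` counts the underlying edges.  The originals are stored
    so :func:`expand_metanode` restores the network bit-identically.
    """
    if metanode_id not in network.metanode_ids():
        raise ValidationError(f"unknown metanode {metanode_id!r}")
    if metanode_id in network.collapsed:
        raise ValidationError(f"metanode {metanode_id!r} is already collapsed")
    internal = network.members(metanode_id)
    removed: List[EdgeRecord] = []
    agg: Dict[Tuple[str, str], int] = {}
    for key in sorted(network.edges):
        e = network.edges[key]
        s_in, t_in = e.source in internal, e.target in internal
        if not (s_in or t_in):
            continue
        removed.append(e)
        del network.edges[key]
        if s_in and t_in:
            continue  # fully internal: hidden, nothing to aggregate
        if s_in:
            agg_key = (metanode_id, e.target)
        else:
            agg_key = (e.source, metanode_id)
        agg[agg_key] = agg.get(agg_key, 0) + 1
    for (s, t), mult in sorted(agg.items()):
        network.add_edge(EdgeRecord(s, t, EdgeKind.AGGREGATE, multiplicity=mult))
    network.collapsed.add(metanode_id)
    network._collapse_store[metanode_id] = removed
    return network


def expand_metanode(network: CommunityNetwork, metanode_id: str) -> CommunityNetwork:
    """Exact inverse of :func:`collapse_metanode` (in place)."""
    if metanode_id not in network.collapsed:
        raise ValidationError(f"metanode {metanode_id!r} is not collapsed")
    for key in [k for k, e in network.edges.items()
                if e.kind is EdgeKind.AGGREGATE and metanode_id in (e.source, e.target)]:
        del network.edges[key]
    for e in network._collapse_store.pop(metanode_id):
        network.add_edge(e)
    network.collapsed.discard(metanode_id)
    return network


def expand_neighborhood(
    network: CommunityNetwork, node_id: str, visible: Set[str]
) -> Set[str]:
    """Exploratory expansion: reveal the direct neighbors of ``node_id``.

    Mirrors double-click navigation in a GUI; idempotent for a fixed node.
    """
    if node_id not in network.nodes:
        raise ValidationError(f"unknown node {node_id!r}")
    return set(visible) | network.neighbors(node_id)


# ---------------------------------------------------------------------------
# Enzyme embedding
# ---------------------------------------------------------------------------

def attach_enzymes(
    network: CommunityNetwork,
    reaction_id: str,
    enzyme_ids: Sequence[str],
    regulatory_edges: Sequence[Tuple[str, str]] = (),
) -> CommunityNetwork:
    """Promote a reaction node to a reaction-metanode with embedded enzymes.

    Regulatory edges may connect enzymes to any node (signaling/regulatory
    overlay); the bipartite view is preserved whenever the reaction-metanode
    is collapsed.  Attaching zero enzymes is a no-op.
    """
    node = network.nodes.get(reaction_id)
    if node is None or node.kind is not NodeKind.REACTION:
        raise ValidationError(f"unknown reaction node {reaction_id!r}")
    if not enzyme_ids and not regulatory_edges:
        return network
    network.reaction_metanodes.add(reaction_id)
    for ez in enzyme_ids:
        if ez not in network.nodes:
            network.add_node(NodeRecord(id=ez, kind=NodeKind.ENZYME, owner=node.owner))
        network.membership.setdefault(ez, set()).add(reaction_id)
    for s, t in regulatory_edges:
        for nid in (s, t):
            if nid not in network.nodes:
                raise ValidationError(f"regulatory edge references unknown node {nid!r}")
        network.add_edge(EdgeRecord(s, t, EdgeKind.REGULATORY))
    return network


# ---------------------------------------------------------------------------
# Edge-list row conversion (used by model_io.read/write_edge_list)
# ---------------------------------------------------------------------------

_NODE_TOKENS = {k.value: k for k in NodeKind}
_EDGE_TOKENS = {k.value: k for k in EdgeKind}
_EDGE_TOKENS["member"] = None  # membership pseudo-edge


def network_from_edge_rows(
    rows: Sequence[Tuple[int, Sequence[str]]], source: str = "<edge list>"
) -> CommunityNetwork:
    net = CommunityNetwork()
    memberships: List[Tuple[int, str, str]] = []
    for lineno, (src, tgt, s_type, t_type, e_type) in rows:
        for nid, tok in ((src, s_type), (tgt, t_type)):
            if tok not in _NODE_TOKENS:
                raise ValidationError(f"{source}:{lineno}: unknown node type {tok!r}")
            kind = _NODE_TOKENS[tok]
            if nid not in net.nodes:
                net.add_node(NodeRecord(id=nid, kind=kind))
                if kind is NodeKind.ENV_METABOLITE:
                    net.env_registry.setdefault(nid, set())
            elif net.nodes[nid].kind is not kind:
                raise ValidationError(
                    f"{source}:{lineno}: node {nid!r} redeclared as {tok!r} "
                    f"(was {net.nodes[nid].kind.value!r})"
                )
        if e_type not in _EDGE_TOKENS:
            raise ValidationError(f"{source}:{lineno}: unknown edge type {e_type!r}")
        if e_type == "member":
            memberships.append((lineno, src, tgt))
        else:
            net.add_edge(EdgeRecord(src, tgt, _EDGE_TOKENS[e_type]))
    for lineno, src, tgt in memberships:
        tnode = net.nodes.get(tgt)
        if tnode is None or tnode.kind not in (NodeKind.METANODE, NodeKind.REACTION):
            raise ValidationError(
                f"{source}:{lineno}: membership target {tgt!r} is not a metanode"
            )
        if tnode.kind is NodeKind.REACTION:
            net.reaction_metanodes.add(tgt)
        net.membership.setdefault(src, set()).add(tgt)
        if net.nodes[src].kind is NodeKind.METABOLITE or net.nodes[src].kind is NodeKind.REACTION:
            if tnode.kind is NodeKind.METANODE:
                net.nodes[src].owner = tgt
    return net


def network_to_edge_rows(network: CommunityNetwork) -> List[Tuple[str, str, str, str, str]]:
    rows: List[Tuple[str, str, str, str, str]] = []
    for _key, e in network.edges.items():
        rows.append((
            e.source, e.target,
            network.nodes[e.source].kind.value, network.nodes[e.target].kind.value,
            e.kind.value,
        ))
    for nid in network.membership:
        for mid in network.membership[nid]:
            rows.append((nid, mid, network.nodes[nid].kind.value,
                         network.nodes[mid].kind.value, "member"))
    rows.sort()
    return rows


# ---------------------------------------------------------------------------
# GraphML / JSON export
# ---------------------------------------------------------------------------

def to_networkx(network: CommunityNetwork):
    """Export as a :class:`networkx.MultiDiGraph` with typed attributes."""
    import networkx as nx

    g = nx.MultiDiGraph()
    for nid in sorted(network.nodes):
        n = network.nodes[nid]
        g.add_node(
            nid,
            kind=n.kind.value,
            owner=n.owner or "",
            label=n.label,
            membership=",".join(sorted(network.membership.get(nid, ()))),
            collapsed=nid in network.collapsed,
        )
    for key in sorted(network.edges):
        e = network.edges[key]
        g.add_edge(e.source, e.target, kind=e.kind.value,
                   reaction_ref=e.reaction_ref or "", multiplicity=e.multiplicity)
    return g


def write_graphml(network: CommunityNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(network), str(path))


def to_json(network: CommunityNetwork) -> str:
    """Lossless JSON serialization of the full network state."""
    payload = {
        "nodes": [
            {"id": n.id, "kind": n.kind.value, "owner": n.owner, "label": n.label}
            for _nid, n in sorted(network.nodes.items())
        ],
        "edges": [
            {"source": e.source, "target": e.target, "kind": e.kind.value,
             "reaction_ref": e.reaction_ref, "multiplicity": e.multiplicity}
            for _k, e in sorted(network.edges.items())
        ],
        "membership": {nid: sorted(ms) for nid, ms in sorted(network.membership.items())},
        "collapsed": sorted(network.collapsed),
        "env_registry": {k: sorted(map(list, v)) for k, v in sorted(network.env_registry.items())},
        "exchange_orientation": [
            [m, r, s] for (m, r), s in sorted(network.exchange_orientation.items())
        ],
        "reaction_metanodes": sorted(network.reaction_metanodes),
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def from_json(text: str) -> CommunityNetwork:
    payload = json.loads(text)
    net = CommunityNetwork()
    for n in payload["nodes"]:
        net.nodes[n["id"]] = NodeRecord(id=n["id"], kind=NodeKind(n["kind"]),
                                        owner=n["owner"], label=n["label"])
    for e in payload["edges"]:
        net.add_edge(EdgeRecord(e["source"], e["target"], EdgeKind(e["kind"]),
                                reaction_ref=e["reaction_ref"],
                                multiplicity=e["multiplicity"]))
    net.membership = {nid: set(ms) for nid, ms in payload["membership"].items()}
    net.collapsed = set(payload["collapsed"])
    net.env_registry = {k: {tuple(p) for p in v} for k, v in payload["env_registry"].items()}
    net.exchange_orientation = {(m, r): s for m, r, s in payload["exchange_orientation"]}
    net.reaction_metanodes = set(payload["reaction_metanodes"])
    return net


def write_json(network: CommunityNetwork, path: str | Path) -> None:
    Path(path).write_text(to_json(network), encoding="utf-8")
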