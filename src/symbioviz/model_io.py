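"""Metabolic model I/O.

Reads stoichiometric models from SBML (Level 2/3 core subset, via
python-libsbml) and from COMETS-style flat model files, identifies
exchange reactions and extracellular metabolites, and reads/writes typed
tab-delimited edge lists of community networks.

Conventions
-----------
* A metabolite is *extracellular* when its compartment tag is in the
  configured extracellular tag set (default ``{"e", "e0", "Extracellular"}``,
  covering both BiGG ``ac_e`` and SEED ``H2O_e0`` styles).
* An *exchange reaction* is a boundary pseudo-reaction touching exactly one
  metabolite, and that metabolite is extracellular.  Its flux sign encodes
  secretion (+) vs. uptake (-) under the standard FBA convention where the
  metabolite appears as the substrate.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .errors import ParseError, ValidationError

#: Compartment tags treated as extracellular by default.
DEFAULT_EXTRACELLULAR_TAGS = frozenset({"e", "e0", "Extracellular"})

_COMPARTMENT_SUFFIX = re.compile(r"^(?P<base>.+?)(?:\[(?P<br>[A-Za-z]\w{0,2})\]|_(?P<us>[a-z]\d?))$")


@dataclass
class Metabolite:
    """A chemical species in one organism's model."""

    id: str
    name: str = ""
    compartment: str = ""
    is_extracellular: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """A (pseudo-)reaction: signed stoichiometry over metabolite ids.

    Negative coefficients are substrates, positive are products.  Zero
    coefficients are never stored.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    bounds: Optional[Tuple[float, float]] = None
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id


@dataclass
class MetabolicModel:
    """One organism's metabolites, reactions and exchange-reaction set."""

    id: str
    name: str = ""
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    exchange_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id

    # -- lookups -----------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def metabolite_ids(self) -> Set[str]:
        return {m.id for m in self.metabolites}

    @property
    def reaction_ids(self) -> Set[str]:
        return {r.id for r in self.reactions}

    def validate(self) -> None:
        """Check model invariants; raise :class:`ValidationError` on breach."""
        mids = [m.id for m in self.metabolites]
        if len(mids) != len(set(mids)):
            dup = sorted({i for i in mids if mids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids in model {self.id!r}: {dup}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids in model {self.id!r}: {dup}")
        known = set(mids)
        ext = {m.id for m in self.metabolites if m.is_extracellular}
        for r in self.reactions:
            missing = sorted(set(r.stoichiometry) - known)
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: {missing}"
                )
            if any(c == 0 for c in r.stoichiometry.values()):
                raise ValidationError(f"reaction {r.id!r} stores a zero coefficient")
            if r.is_exchange:
                if len(r.stoichiometry) != 1:
                    raise ValidationError(
                        f"exchange reaction {r.id!r} must touch exactly one metabolite"
                    )
                (mid,) = r.stoichiometry
                if mid not in ext:
                    raise ValidationError(
                        f"exchange reaction {r.id!r} metabolite {mid!r} is not extracellular"
                    )
        if not self.exchange_ids <= set(rids):
            raise ValidationError(
                f"exchange_ids not a subset of reaction ids in model {self.id!r}"
            )


def split_compartment(met_id: str) -> Tuple[str, Optional[str]]:
    """Split a metabolite id into (base, compartment tag) by suffix.

    Recognises bracket style (``ac[e]``) and underscore style (``ac_e``,
    ``H2O_e0``).  Returns ``(met_id, None)`` when no suffix is found.
    """
    m = _COMPARTMENT_SUFFIX.match(met_id)
    if not m:
        return met_id, None
    tag = m.group("br") or m.group("us")
    return m.group("base"), tag


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _strip_prefix(sid: str, prefix: str, taken: Set[str]) -> str:
    """Strip a BiGG-style ``M_``/``R_`` id prefix when unambiguous."""
    if sid.startswith(prefix) and len(sid) > len(prefix):
        cand = sid[len(prefix):]
        if cand not in taken:
            return cand
    return sid


def read_sbml(
    path: str | Path,
    extracellular_tags: Iterable[str] = DEFAULT_EXTRACELLULAR_TAGS,
) -> MetabolicModel:
    """Read a metabolic model from an SBML file (``.xml`` or ``.xml.gz``).

    Supports the Level 2 v4 / Level 3 v1 core subset: compartments,
    species, reactions with stoichiometry and the ``reversible`` flag.
    BiGG-style ``M_``/``R_`` id prefixes are stripped when doing so keeps
    ids unique.  Exchange reactions are detected with
    :func:`detect_exchange_reactions` after parsing.
    """
    import libsbml

    path = Path(path)
    if not path.exists():
        raise ParseError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    errs = []
    for i in range(doc.getNumErrors()):
        e = doc.getError(i)
        if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errs.append(f"line {e.getLine()}: {e.getMessage().strip()}")
    if errs:
        raise ParseError(f"malformed SBML in {path.name}: " + "; ".join(errs[:5]))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError(f"{path.name}: no <model> element")

    ext_tags = set(extracellular_tags)
    # compartment names also count as tags (SBML L3 often tags by name)
    comp_names = {
        sbml_model.getCompartment(i).getId(): (sbml_model.getCompartment(i).getName() or "")
        for i in range(sbml_model.getNumCompartments())
    }

    mets: List[Metabolite] = []
    raw_ids: Set[str] = {sbml_model.getSpecies(i).getId() for i in range(sbml_model.getNumSpecies())}
    id_map: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sid = _strip_prefix(sp.getId(), "M_", raw_ids)
        id_map[sp.getId()] = sid
        comp = sp.getCompartment() or ""
        is_ext = comp in ext_tags or comp_names.get(comp, "") in ext_tags
        mets.append(Metabolite(id=sid, name=sp.getName() or sid, compartment=comp,
                               is_extracellular=is_ext))
    known = {m.id for m in mets}

    rxns: List[Reaction] = []
    raw_rids: Set[str] = {sbml_model.getReaction(i).getId() for i in range(sbml_model.getNumReactions())}
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        undeclared: List[str] = []

        def _acc(ref, sign: float) -> None:
            sid = ref.getSpecies()
            mid = id_map.get(sid)
            if mid is None or mid not in known:
                undeclared.append(sid)
                return
            coeff = ref.getStoichiometry()
            if coeff is None or (isinstance(coeff, float) and math.isnan(coeff)):
                coeff = 1.0
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

        for j in range(rx.getNumReactants()):
            _acc(rx.getReactant(j), -1.0)
        for j in range(rx.getNumProducts()):
            _acc(rx.getProduct(j), +1.0)
        if undeclared:
            raise ValidationError(
                f"reaction {rx.getId()!r} references undeclared species: {sorted(set(undeclared))}"
            )
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        # L2 default for `reversible` is true; libsbml reports it either way.
        rev = bool(rx.getReversible()) if rx.isSetReversible() or doc.getLevel() < 3 else False
        rxns.append(Reaction(id=_strip_prefix(rx.getId(), "R_", raw_rids),
                             name=rx.getName() or "", stoichiometry=stoich, reversible=rev))

    model = MetabolicModel(
        id=sbml_model.getId() or path.stem,
        name=sbml_model.getName() or "",
        metabolites=mets,
        reactions=rxns,
    )
    model.exchange_ids = detect_exchange_reactions(model)
    for r in model.reactions:
        r.is_exchange = r.id in model.exchange_ids
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as SBML Level 3 Version 1 (core subset)."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    sm = doc.createModel()
    sm.setId(model.id)
    sm.setName(model.name)
    comps = sorted({m.compartment or "c" for m in model.metabolites})
    for c in comps:
        co = sm.createCompartment()
        co.setId(c)
        co.setConstant(True)
    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment or "c")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for mid in sorted(r.stoichiometry):
            coeff = r.stoichiometry[mid]
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise SymbiovizIOError(f"could not write SBML to {path}")


class SymbiovizIOError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# COMETS model flat files
# ---------------------------------------------------------------------------

_COMETS_BLOCKS = (
    "SMATRIX", "BOUNDS", "OBJECTIVE", "METABOLITE_NAMES", "REACTION_NAMES",
    "EXCHANGE_REACTIONS",
)


def read_comets_model(
    path: str | Path,
    model_id: Optional[str] = None,
    extracellular_tags: Iterable[str] = DEFAULT_EXTRACELLULAR_TAGS,
) -> MetabolicModel:
    """Read a COMETS-style flat model file.

    The supported dialect is block-structured with 1-based indices::

        SMATRIX  <n_mets>  <n_rxns>
            <i> <j> <coeff>
        //
        BOUNDS  <default_lb>  <default_ub>
            <j> <lb> <ub>
        //
        OBJECTIVE
            <j>
        //
        METABOLITE_NAMES
            <name>
        //
        REACTION_NAMES
            <name>
        //
        EXCHANGE_REACTIONS
            <j> <j> ...
        //

    Compartments are recovered from metabolite-name suffixes
    (``ac[e]`` / ``ac_e`` / ``H2O_e0``); reversibility from ``lb < 0``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"COMETS model file not found: {path}")
    blocks: Dict[str, List[str]] = {}
    headers: Dict[str, List[str]] = {}
    current: Optional[str] = None
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("%") or line.startswith("#"):
            continue
        if line.startswith("//"):
            current = None
            continue
        tok = line.split()
        if current is None:
            key = tok[0].upper()
            if key not in _COMETS_BLOCKS:
                raise ParseError(f"{path.name}:{lineno}: unknown block {tok[0]!r}")
            current = key
            headers[key] = tok[1:]
            blocks.setdefault(key, [])
        else:
            blocks[current].append(line)

    if "SMATRIX" not in blocks:
        raise ParseError(f"{path.name}: missing SMATRIX block")
    for required in ("METABOLITE_NAMES", "REACTION_NAMES"):
        if required not in blocks:
            raise ValidationError(f"{path.name}: missing {required} block")

    try:
        n_mets, n_rxns = (int(v) for v in headers["SMATRIX"][:2])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path.name}: SMATRIX header must give n_mets n_rxns") from exc

    met_names = [ln.strip() for ln in blocks["METABOLITE_NAMES"]]
    rxn_names = [ln.strip() for ln in blocks["REACTION_NAMES"]]
    if len(met_names) != n_mets:
        raise ValidationError(
            f"{path.name}: METABOLITE_NAMES lists {len(met_names)} names, SMATRIX declares {n_mets}"
        )
    if len(rxn_names) != n_rxns:
        raise ValidationError(
            f"{path.name}: REACTION_NAMES lists {len(rxn_names)} names, SMATRIX declares {n_rxns}"
        )

    ext_tags = set(extracellular_tags)
    mets = []
    for name in met_names:
        base, comp = split_compartment(name)
        mets.append(Metabolite(id=name, name=base, compartment=comp or "",
                               is_extracellular=(comp in ext_tags)))

    stoich: List[Dict[str, float]] = [dict() for _ in range(n_rxns)]
    for entry in blocks["SMATRIX"]:
        parts = entry.split()
        if len(parts) != 3:
            raise ParseError(f"{path.name}: bad SMATRIX entry {entry!r}")
        i, j = int(parts[0]), int(parts[1])
        coeff = float(parts[2])
        if not (1 <= i <= n_mets) or not (1 <= j <= n_rxns):
            raise ValidationError(
                f"{path.name}: SMATRIX index ({i},{j}) out of range {n_mets}x{n_rxns}"
            )
        if coeff != 0.0:
            stoich[j - 1][met_names[i - 1]] = stoich[j - 1].get(met_names[i - 1], 0.0) + coeff

    bounds: List[Optional[Tuple[float, float]]] = [None] * n_rxns
    if "BOUNDS" in blocks:
        default_lb, default_ub = -1000.0, 1000.0
        if len(headers.get("BOUNDS", [])) >= 2:
            default_lb, default_ub = float(headers["BOUNDS"][0]), float(headers["BOUNDS"][1])
        bounds = [(default_lb, default_ub)] * n_rxns
        for entry in blocks["BOUNDS"]:
            parts = entry.split()
            j = int(parts[0])
            if not (1 <= j <= n_rxns):
                raise ValidationError(f"{path.name}: BOUNDS index {j} out of range")
            bounds[j - 1] = (float(parts[1]), float(parts[2]))

    exchange_idx: Set[int] = set()
    for entry in blocks.get("EXCHANGE_REACTIONS", []):
        for tok in entry.split():
            j = int(tok)
            if not (1 <= j <= n_rxns):
                raise ValidationError(
                    f"{path.name}: EXCHANGE_REACTIONS index {j} out of range (1..{n_rxns})"
                )
            exchange_idx.add(j - 1)

    rxns = []
    for j, name in enumerate(rxn_names):
        b = bounds[j]
        rxns.append(Reaction(
            id=name,
            stoichiometry=stoich[j],
            reversible=(b is not None and b[0] < 0),
            bounds=b,
            is_exchange=(j in exchange_idx),
        ))
    # an exchanged metabolite is extracellular by definition
    ext_met_ids = {mid for j in exchange_idx for mid in stoich[j]}
    for m in mets:
        if m.id in ext_met_ids:
            m.is_extracellular = True

    model = MetabolicModel(
        id=model_id or path.stem,
        metabolites=mets,
        reactions=rxns,
        exchange_ids={rxn_names[j] for j in exchange_idx},
    )
    model.validate()
    return model


def write_comets_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the COMETS flat dialect documented in :func:`read_comets_model`."""
    met_index = {m.id: i + 1 for i, m in enumerate(model.metabolites)}
    lines: List[str] = []
    lines.append(f"SMATRIX  {len(model.metabolites)}  {len(model.reactions)}")
    for j, r in enumerate(model.reactions, 1):
        for mid in sorted(r.stoichiometry):
            lines.append(f"    {met_index[mid]} {j} {r.stoichiometry[mid]:.10g}")
    lines.append("//")
    lines.append("BOUNDS  -1000  1000")
    for j, r in enumerate(model.reactions, 1):
        if r.bounds is not None:
            lines.append(f"    {j} {r.bounds[0]:.10g} {r.bounds[1]:.10g}")
        elif r.reversible:
            lines.append(f"    {j} -1000 1000")
        else:
            lines.append(f"    {j} 0 1000")
    lines.append("//")
    lines.append("METABOLITE_NAMES")
    lines.extend(f"    {m.id}" for m in model.metabolites)
    lines.append("//")
    lines.append("REACTION_NAMES")
    lines.extend(f"    {r.id}" for r in model.reactions)
    lines.append("//")
    lines.append("EXCHANGE_REACTIONS")
    ex = sorted(j for j, r in enumerate(model.reactions, 1) if r.id in model.exchange_ids)
    lines.append("    " + " ".join(str(j) for j in ex))
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Exchange detection
# ---------------------------------------------------------------------------

def detect_exchange_reactions(model: MetabolicModel) -> Set[str]:
    """Return the set of exchange reaction ids for ``model``.

    Explicit ``is_exchange`` flags (e.g. from a COMETS exchange block) win;
    otherwise a heuristic applies: reactions with exactly one nonzero
    stoichiometric entry on an extracellular metabolite.  Single-metabolite
    boundary reactions on intracellular metabolites (sink/demand reactions)
    are deliberately excluded.
    """
    flagged = {r.id for r in model.reactions if r.is_exchange}
    if flagged:
        return flagged
    ext = {m.id for m in model.metabolites if m.is_extracellular}
    out = set()
    for r in model.reactions:
        if len(r.stoichiometry) == 1:
            (mid,) = r.stoichiometry
            if mid in ext:
                out.add(r.id)
    return out


# ---------------------------------------------------------------------------
# Edge lists  (thin wrappers; the network type lives in metagraph)
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path):
    """Read a typed tab-delimited edge list into a community network.

    Columns: ``source  target  source_type  target_type  edge_type``;
    UTF-8; ``#`` comment lines.  See
    :func:`symbioviz.metagraph.network_from_edge_rows` for the row
    semantics (``member`` rows encode metanode membership).
    """
    from .metagraph import network_from_edge_rows

    path = Path(path)
    if not path.exists():
        raise ParseError(f"edge list not found: {path}")
    rows: List[Tuple[int, Sequence[str]]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ParseError(
                f"{path.name}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
            )
        rows.append((lineno, parts[:5]))
    return network_from_edge_rows(rows, source=path.name)


def write_edge_list(network, path: str | Path) -> None:
    """Write a community network as a typed edge list (deterministic order)."""
    from .metagraph import network_to_edge_rows

    rows = network_to_edge_rows(network)
    lines = ["#source\ttarget\tsource_type\ttarget_type\tedge_type"]
    lines.extend("\t".join(r) for r in rows)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
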