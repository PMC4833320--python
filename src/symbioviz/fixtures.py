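"""Synthetic multi-species communities with known interaction structure.

Each species gets a minimal stoichiometric model (uptake, a couple of
internal conversions, secretion) and a mass-action-flavored flux time
series: biomass follows a logistic growth curve and every exchange flux
is a per-biomass rate times biomass, so the series look like dynamic-FBA
output without running FBA.  Requested interaction *motifs* (cross-feeding
chain, competition, co-secretion, single consumer) are built so that the
role classifier recovers the intended role at every time point; additive
Gaussian noise is applied after sign enforcement and re-clipped so the
motif signs survive.

Everything is deterministic given the scenario seed, and every generated
artifact can be written in all supported on-disk formats (SBML, COMETS
model + flux log, Manifest, hidden list) via :func:`write_fixture_bundle`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .flux_io import (FluxField, FluxSeries, ManifestSpec, read_manifest)
from .model_io import (MetabolicModel, Metabolite, Reaction,
                       write_comets_model, write_sbml)

MOTIF_KINDS = ("cross_feed_chain", "competition", "co_secretion", "single_consumer")

#: per-biomass exchange rate for motif metabolites (mmol gDW^-1 h^-1)
MOTIF_RATE = 2.0
#: per-biomass uptake rate of the shared base nutrient
BASE_RATE = 10.0


@dataclass
class Motif:
    """One interaction motif: a metabolite and the species it involves.

    ``species`` lists 0-based species indices.  cross_feed_chain: first
    index produces, the rest consume.  competition: all consume (>=2).
    co_secretion: all produce (>=2).  single_consumer: exactly one
    consumer, no other species connected.
    """

    kind: str
    metabolite: str
    species: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_KINDS:
            raise ValidationError(f"unknown motif kind {self.kind!r}")
        if self.kind == "cross_feed_chain" and len(self.species) < 2:
            raise ValidationError("cross_feed_chain needs a producer and >=1 consumer")
        if self.kind in ("competition", "co_secretion") and len(self.species) < 2:
            raise ValidationError(f"{self.kind} needs >=2 species")
        if self.kind == "single_consumer" and len(self.species) != 1:
            raise ValidationError("single_consumer names exactly one species")

    def producers(self) -> Tuple[int, ...]:
        if self.kind == "cross_feed_chain":
            return (self.species[0],)
        if self.kind == "co_secretion":
            return self.species
        return ()

    def consumers(self) -> Tuple[int, ...]:
        if self.kind == "cross_feed_chain":
            return self.species[1:]
        if self.kind in ("competition", "single_consumer"):
            return self.species
        return ()


@dataclass
class CommunityScenario:
    """Full description of a synthetic community experiment."""

    n_species: int
    motifs: List[Motif] = field(default_factory=list)
    n_time: int = 10
    seed: int = 0
    noise_sd: float = 0.05
    time_step: float = 0.5  # hours per step
    #: nutrient consumed by every species; None drops the shared uptake
    base_nutrient: Optional[str] = "glc"

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if self.n_time < 1:
            raise ValidationError("n_time must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for m in self.motifs:
            bad = [i for i in m.species if not (0 <= i < self.n_species)]
            if bad:
                raise ValidationError(
                    f"motif on {m.metabolite!r} references species {bad}, "
                    f"but n_species={self.n_species}"
                )
        mets = [m.metabolite for m in self.motifs]
        if len(mets) != len(set(mets)):
            raise ValidationError("each motif must use a distinct metabolite")
        if self.base_nutrient in mets:
            raise ValidationError("motif metabolite collides with base nutrient")


def species_id(i: int) -> str:
    return f"sp{i + 1}"


def _logistic_biomass(n_time: int, dt: float, rate: float, b0: float = 0.01,
                      capacity: float = 1.0) -> np.ndarray:
    t = np.arange(n_time) * dt
    a = (capacity - b0) / b0
    return capacity / (1.0 + a * np.exp(-rate * t))


def _species_model(scenario: CommunityScenario, i: int) -> MetabolicModel:
    sid = species_id(i)
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []

    def add_met(mid: str, comp: str) -> None:
        if not any(m.id == mid for m in mets):
            mets.append(Metabolite(id=mid, name=mid.rsplit("_", 1)[0], compartment=comp,
                                   is_extracellular=(comp == "e")))

    add_met("bio_c", "c")

    def add_uptake(met: str) -> None:
        add_met(f"{met}_e", "e")
        add_met(f"{met}_c", "c")
        rxns.append(Reaction(id=f"EX_{met}_e", stoichiometry={f"{met}_e": -1.0},
                             reversible=True, is_exchange=True))
        rxns.append(Reaction(id=f"T_{met}", stoichiometry={f"{met}_e": -1.0, f"{met}_c": 1.0}))
        rxns.append(Reaction(id=f"USE_{met}", stoichiometry={f"{met}_c": -1.0, "bio_c": 1.0}))

    def add_secretion(met: str) -> None:
        add_met(f"{met}_e", "e")
        add_met(f"{met}_c", "c")
        rxns.append(Reaction(id=f"MAKE_{met}", stoichiometry={"bio_c": -0.1, f"{met}_c": 1.0}))
        rxns.append(Reaction(id=f"Tout_{met}", stoichiometry={f"{met}_c": -1.0, f"{met}_e": 1.0}))
        rxns.append(Reaction(id=f"EX_{met}_e", stoichiometry={f"{met}_e": -1.0},
                             reversible=True, is_exchange=True))

    if scenario.base_nutrient:
        add_uptake(scenario.base_nutrient)
    for motif in scenario.motifs:
        if i in motif.producers():
            add_secretion(motif.metabolite)
        if i in motif.consumers():
            add_uptake(motif.metabolite)

    model = MetabolicModel(id=sid, name=f"species {i + 1}", metabolites=mets,
                           reactions=rxns,
                           exchange_ids={r.id for r in rxns if r.is_exchange})
    model.validate()
    return model


def make_toy_community(scenario: CommunityScenario) -> Tuple[List[MetabolicModel], FluxField]:
    """Generate the community models and a 1x1-grid flux field.

    Exchange fluxes are ``±MOTIF_RATE * biomass(t)`` (sign by motif role;
    shared base nutrient at ``-BASE_RATE * biomass``), with additive
    Gaussian noise of sd ``noise_sd * rate * biomass`` clipped away from
    zero so each motif's intended role holds at every time point.
    Internal reaction fluxes mirror the exchange magnitudes.
    """
    rng = np.random.default_rng(scenario.seed)
    models = [_species_model(scenario, i) for i in range(scenario.n_species)]
    n_time, dt = scenario.n_time, scenario.time_step

    cell: Dict[str, FluxSeries] = {}
    biomass: Dict[Tuple[int, int, str], np.ndarray] = {}
    for i, model in enumerate(models):
        growth_rate = 0.8 + 0.1 * (i % 3)  # mildly species-specific kinetics
        b = _logistic_biomass(n_time, dt, growth_rate)
        biomass[(0, 0, model.id)] = b
        values: Dict[str, np.ndarray] = {r.id: np.zeros(n_time) for r in model.reactions}

        def signed_flux(rate: float, sign: float) -> np.ndarray:
            base = sign * rate * b
            if scenario.noise_sd > 0:
                noise = rng.normal(0.0, scenario.noise_sd * rate, size=n_time) * b
                out = base + noise
                # re-clip so the motif sign survives the noise
                floor = 0.05 * rate * b
                if sign > 0:
                    out = np.maximum(out, floor)
                else:
                    out = np.minimum(out, -floor)
                return out
            return base

        if scenario.base_nutrient:
            bn = scenario.base_nutrient
            v = signed_flux(BASE_RATE, -1.0)
            values[f"EX_{bn}_e"] = v
            values[f"T_{bn}"] = -v
            values[f"USE_{bn}"] = -v
        for motif in scenario.motifs:
            met = motif.metabolite
            if i in motif.producers():
                v = signed_flux(MOTIF_RATE, +1.0)
                values[f"EX_{met}_e"] = v
                values[f"Tout_{met}"] = v
                values[f"MAKE_{met}"] = v
            elif i in motif.consumers():
                v = signed_flux(MOTIF_RATE, -1.0)
                values[f"EX_{met}_e"] = v
                values[f"T_{met}"] = -v
                values[f"USE_{met}"] = -v
        cell[model.id] = FluxSeries(model_id=model.id, values=values, n_time=n_time,
                                    time_step=dt)

    field = FluxField(width=1, height=1, cells={(0, 0): cell}, biomass=biomass)
    return models, field


def default_scenario(n_species: int = 2, n_time: int = 10, seed: int = 0,
                     noise_sd: float = 0.05) -> CommunityScenario:
    """A ready-made scenario with one motif of each applicable kind."""
    motifs = []
    if n_species >= 2:
        motifs.append(Motif("cross_feed_chain", "ac", (0, 1)))
        motifs.append(Motif("co_secretion", "for", tuple(range(min(2, n_species)))))
    motifs.append(Motif("single_consumer", "lcts", (0,)))
    return CommunityScenario(n_species=n_species, motifs=motifs, n_time=n_time,
                             seed=seed, noise_sd=noise_sd)


def case_study_pair_scenario(n_time: int = 10, seed: int = 0,
                             noise_sd: float = 0.0) -> CommunityScenario:
    """A two-species consortium emulating an obligate cross-feeding pair.

    Species 1 consumes lactose (exclusively) and secretes acetate;
    species 2 consumes the acetate and secretes methionine, which
    species 1 consumes — two cross-feeding metabolites in opposite
    directions plus one single-organism nutrient.
    """
    return CommunityScenario(
        n_species=2,
        motifs=[
            Motif("single_consumer", "lcts", (0,)),
            Motif("cross_feed_chain", "ac", (0, 1)),
            Motif("cross_feed_chain", "met_L", (1, 0)),
        ],
        n_time=n_time,
        seed=seed,
        noise_sd=noise_sd,
        base_nutrient=None,
    )


def write_fixture_bundle(
    models: Sequence[MetabolicModel],
    field: FluxField,
    directory: str | Path,
    hidden: Sequence[str] = (),
) -> ManifestSpec:
    """Write a complete input bundle and return the parsed-back Manifest.

    Writes each model as SBML *and* as a COMETS flat file, the flux log in
    the COMETS assignment dialect, a hidden-metabolite list, and a
    Manifest referencing the COMETS variants.
    """
    from .flux_io import write_comets_flux_log

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_lines = ["# symbioviz fixture bundle"]
    for model in models:
        write_sbml(model, directory / f"{model.id}.xml")
        write_comets_model(model, directory / f"{model.id}.cmt")
        manifest_lines.append(f"model\tcomets\t{model.id}.cmt")
    write_comets_flux_log(field, models, directory / "flux.log")
    manifest_lines.append("flux\tflux.log")
    hidden_path = directory / "hidden.txt"
    hidden_path.write_text(
        "# metabolites to hide from rendered views\n" + "".join(f"{h}\n" for h in hidden)
    )
    manifest_lines.append("hidden\thidden.txt")
    manifest_path = directory / "manifest.txt"
    manifest_path.write_text("\n".join(manifest_lines) + "\n")
    return read_manifest(manifest_path)
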