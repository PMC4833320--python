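"""End-to-end convenience layer: Manifest in, community + fluxes out.

This is the programmatic equivalent of "open a Manifest file": it loads
every referenced model in its declared format, builds the community
metagraph, loads flux data when present (COMETS log or plain table) and
reads the hidden-metabolite list.  The CLI is a thin wrapper over this.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional

from .errors import ParseError, ValidationError
from .flux_io import (FluxField, FluxSeries, ManifestSpec, average_over_grid,
                      read_comets_flux_log, read_flux_table, read_hidden_list,
                      read_manifest, select_point)
from .metagraph import CommunityNetwork, build_community_network
from .model_io import (MetabolicModel, read_comets_model, read_edge_list,
                       read_sbml)


@dataclass
class LoadedCommunity:
    """Everything a Manifest points at, loaded and assembled."""

    models: List[MetabolicModel]
    network: CommunityNetwork
    field: Optional[FluxField] = None
    hidden: List[str] = dc_field(default_factory=list)
    options: Dict[str, str] = dc_field(default_factory=dict)

    def fluxes_at(self, point: Optional[tuple] = None) -> Optional[Dict[str, FluxSeries]]:
        """Flux series at a grid point, or averaged over the grid (default)."""
        if self.field is None:
            return None
        if point is not None:
            return select_point(self.field, point[0], point[1])
        if (self.field.width, self.field.height) == (1, 1):
            return select_point(self.field, 0, 0)
        return average_over_grid(self.field)


def load_community(manifest_path: str | Path) -> LoadedCommunity:
    """Load models, network, fluxes and hidden list from a Manifest file."""
    spec = read_manifest(manifest_path)
    return load_from_spec(spec)


def load_from_spec(spec: ManifestSpec) -> LoadedCommunity:
    models: List[MetabolicModel] = []
    for path, fmt in spec.model_entries:
        if "://" in path:
            raise ValidationError(
                f"URL model entries are not supported offline: {path}"
            )
        if fmt == "sbml":
            models.append(read_sbml(path))
        elif fmt == "comets":
            models.append(read_comets_model(path))
        elif fmt == "edgelist":
            raise ValidationError(
                "edgelist entries describe a prebuilt network; load them with "
                "read_edge_list instead of mixing into a model community"
            )
        else:  # pragma: no cover - read_manifest already validates
            raise ValidationError(f"unknown model format {fmt!r}")

    network = build_community_network(models)

    flux_field: Optional[FluxField] = None
    if spec.flux_entry:
        path = Path(spec.flux_entry)
        if not path.exists():
            raise ParseError(f"flux entry not found: {path}")
        try:
            flux_field = read_comets_flux_log(path, models)
        except ParseError:
            if len(models) != 1:
                raise
            series = read_flux_table(path, models[0].id,
                                     reactions=[r.id for r in models[0].reactions])
            flux_field = FluxField(width=1, height=1,
                                   cells={(0, 0): {models[0].id: series}})

    hidden = read_hidden_list(spec.hidden_metabolites_entry) if spec.hidden_metabolites_entry else []
    return LoadedCommunity(models=models, network=network, field=flux_field,
                           hidden=hidden, options=dict(spec.options))
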