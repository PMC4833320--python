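"""Interaction-role classification of environmental metabolites.

For each ENV metabolite node and time point, the net exchange of every
topologically connected organism is computed (positive = secretion into
the shared environment, negative = uptake), and the metabolite is assigned
one of five roles:

=============== =============================================== ==========
role            condition                                        color
=============== =============================================== ==========
SINGLE          only one organism is connected, or exactly one   dark gray
                organism is active while several are connected
CROSS_FEEDING   at least one producer and one consumer           light gray
COMPETITION     >=2 consumers, no producer                       red
CO_SECRETION    >=2 producers, no consumer                       blue
INACTIVE        no organism transports it at this time point     white
=============== =============================================== ==========

"Active" means |net exchange| exceeds the activity threshold ``epsilon``
(default 1e-9 mmol gDW^-1 h^-1).  With multiple producers *and* consumers
the syntrophy-first priority (CROSS_FEEDING before COMPETITION before
CO_SECRETION) applies; the two-organism special cases reduce to the
classical reading (blue = secreted by both, red = consumed by both,
light gray = produced by one and consumed by the other, dark gray =
associated with a single organism).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional

import pandas as pd

from .errors import ValidationError
from .flux_io import FluxSeries
from .metagraph import SEP, CommunityNetwork

DEFAULT_EPSILON = 1e-9


class Role(str, Enum):
    CROSS_FEEDING = "cross_feeding"
    COMPETITION = "competition"
    CO_SECRETION = "co_secretion"
    SINGLE = "single"
    INACTIVE = "inactive"


#: Default role palette (light gray, red, blue, dark gray, white).
DEFAULT_PALETTE: Dict[Role, str] = {
    Role.CROSS_FEEDING: "#D3D3D3",
    Role.COMPETITION: "#FF0000",
    Role.CO_SECRETION: "#0000FF",
    Role.SINGLE: "#696969",
    Role.INACTIVE: "#FFFFFF",
}

#: Colorblind-safe alternative (Okabe–Ito oranges/blues instead of red/blue).
COLORBLIND_PALETTE: Dict[Role, str] = {
    Role.CROSS_FEEDING: "#D3D3D3",
    Role.COMPETITION: "#E69F00",
    Role.CO_SECRETION: "#0072B2",
    Role.SINGLE: "#696969",
    Role.INACTIVE: "#FFFFFF",
}


@dataclass
class ExchangeProfile:
    """Net exchange flux per ENV node per connected organism at one time."""

    t: int
    net_exchange: Dict[str, Dict[str, float]]


@dataclass
class RoleAssignment:
    """One interaction role per ENV node at one time point."""

    t: int
    roles: Dict[str, Role]
    palette: Mapping[Role, str] = field(default_factory=lambda: dict(DEFAULT_PALETTE))

    def color(self, env_id: str) -> str:
        return self.palette[self.roles[env_id]]


def exchange_profile(
    network: CommunityNetwork,
    fluxes: Mapping[str, FluxSeries],
    t: int,
) -> ExchangeProfile:
    """Compute net exchange per ENV node at time ``t``.

    Sums the sign-normalized fluxes of each organism's exchange reactions
    attached to the ENV node (an organism may import and export the same
    metabolite through distinct reactions; the sum nets them).  Organisms
    connected to the node but missing from ``fluxes`` contribute zero.
    """
    for series in fluxes.values():
        if not (0 <= t < series.n_time):
            raise ValidationError(
                f"time index {t} out of range 0..{series.n_time - 1}"
            )
    net: Dict[str, Dict[str, float]] = {}
    for env_id, registry in sorted(network.env_registry.items()):
        per_model: Dict[str, float] = {}
        for model_id, _met in sorted(registry):
            per_model.setdefault(model_id, 0.0)
        for rxn_node, env in network.exchange_pairs():
            if env != env_id:
                continue
            model_id, raw_rxn = rxn_node.split(SEP, 1)
            sign = network.exchange_orientation.get((model_id, raw_rxn), 1)
            series = fluxes.get(model_id)
            v = series.at(raw_rxn, t) if series is not None else 0.0
            per_model[model_id] = per_model.get(model_id, 0.0) + sign * v
        net[env_id] = per_model
    return ExchangeProfile(t=t, net_exchange=net)


def classify_metabolites(
    profile: ExchangeProfile,
    network: CommunityNetwork,
    epsilon: float = DEFAULT_EPSILON,
    palette: Optional[Mapping[Role, str]] = None,
) -> RoleAssignment:
    """Assign one interaction role per ENV node from its exchange profile.

    With P = producers (net > epsilon), C = consumers (net < -epsilon) and
    A = topologically connected organisms::

        SINGLE         if |A| == 1
        CROSS_FEEDING  elif |P| >= 1 and |C| >= 1
        COMPETITION    elif |C| >= 2
        CO_SECRETION   elif |P| >= 2
        SINGLE         elif |P| + |C| == 1
        INACTIVE       otherwise
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    roles: Dict[str, Role] = {}
    for env_id, per_model in profile.net_exchange.items():
        connected = {m for m, _x in network.env_registry.get(env_id, set())}
        n_p = sum(1 for m in connected if per_model.get(m, 0.0) > epsilon)
        n_c = sum(1 for m in connected if per_model.get(m, 0.0) < -epsilon)
        if len(connected) == 1:
            role = Role.SINGLE
        elif n_p >= 1 and n_c >= 1:
            role = Role.CROSS_FEEDING
        elif n_c >= 2:
            role = Role.COMPETITION
        elif n_p >= 2:
            role = Role.CO_SECRETION
        elif n_p + n_c == 1:
            role = Role.SINGLE
        else:
            role = Role.INACTIVE
        roles[env_id] = role
    return RoleAssignment(
        t=profile.t, roles=roles,
        palette=dict(palette) if palette is not None else dict(DEFAULT_PALETTE),
    )


def role_timeline(
    network: CommunityNetwork,
    fluxes: Mapping[str, FluxSeries],
    epsilon: float = DEFAULT_EPSILON,
    palette: Optional[Mapping[Role, str]] = None,
) -> List[RoleAssignment]:
    """Classify every ENV node at every time point (for animation/reports)."""
    if not fluxes:
        raise ValidationError("no flux series supplied")
    n_time = min(s.n_time for s in fluxes.values())
    return [
        classify_metabolites(exchange_profile(network, fluxes, t), network,
                             epsilon=epsilon, palette=palette)
        for t in range(n_time)
    ]


def role_report(
    network: CommunityNetwork,
    fluxes: Mapping[str, FluxSeries],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Tidy role table: metabolite, time, n_producers, n_consumers, role, color."""
    rows = []
    n_time = min(s.n_time for s in fluxes.values()) if fluxes else 0
    for t in range(n_time):
        profile = exchange_profile(network, fluxes, t)
        assignment = classify_metabolites(profile, network, epsilon=epsilon)
        for env_id in sorted(profile.net_exchange):
            per_model = profile.net_exchange[env_id]
            connected = {m for m, _x in network.env_registry.get(env_id, set())}
            rows.append({
                "metabolite": env_id,
                "time": t,
                "n_producers": sum(1 for m in connected if per_model.get(m, 0.0) > epsilon),
                "n_consumers": sum(1 for m in connected if per_model.get(m, 0.0) < -epsilon),
                "role": assignment.roles[env_id].value,
                "color": assignment.color(env_id),
            })
    return pd.DataFrame(rows, columns=["metabolite", "time", "n_producers",
                                       "n_consumers", "role", "color"])
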