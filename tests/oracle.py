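"""Independent brute-force oracle for interaction-role classification.

Evaluates the five role predicates directly on (connected, net-flux)
descriptions, without touching the package's classifier internals.  Used
by property tests to check agreement and that the roles form a partition.
"""

from typing import Dict, Set


def brute_force_role(connected: Set[str], net: Dict[str, float], epsilon: float) -> str:
    producers = {m for m in connected if net.get(m, 0.0) > epsilon}
    consumers = {m for m in connected if net.get(m, 0.0) < -epsilon}
    if len(connected) == 1:
        return "single"
    if producers and consumers:
        return "cross_feeding"
    if len(consumers) >= 2:
        return "competition"
    if len(producers) >= 2:
        return "co_secretion"
    if len(producers) + len(consumers) == 1:
        return "single"
    return "inactive"


def all_predicates(connected: Set[str], net: Dict[str, float], epsilon: float) -> Dict[str, bool]:
    """Each role's defining predicate, evaluated independently (with the
    documented syntrophy-first priority made explicit), for exhaustiveness
    and mutual-exclusion checks."""
    p = {m for m in connected if net.get(m, 0.0) > epsilon}
    c = {m for m in connected if net.get(m, 0.0) < -epsilon}
    one = len(connected) == 1
    return {
        "single": one or (not one and not (p and c) and len(c) < 2 and len(p) < 2
                          and len(p) + len(c) == 1),
        "cross_feeding": not one and bool(p) and bool(c),
        "competition": not one and not (p and c) and len(c) >= 2,
        "co_secretion": not one and not (p and c) and len(c) < 2 and len(p) >= 2,
        "inactive": not one and not p and not c,
    }
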