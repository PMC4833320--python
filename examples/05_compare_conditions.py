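"""Comparative rendering of two flux states on one network.

Compares the community's fluxes against a perturbed state (half flux in
species 2 — e.g. a different spatial location or medium).  In 'segments'
mode every edge splits into parallel per-condition strokes; in
'difference' mode a single stroke scales with |v1 - v2| and its color
gives the sign of the change.
"""

from pathlib import Path

import symbioviz as sv

models, field = sv.make_toy_community(sv.default_scenario(2, n_time=10, seed=1))
network = sv.build_community_network(models)
baseline = sv.select_point(field, 0, 0)

perturbed = {
    mid: sv.FluxSeries(mid, {r: (0.5 if mid == "sp2" else 1.0) * s.values[r]
                             for r in s.values}, s.n_time)
    for mid, s in baseline.items()
}

layout = sv.layout_for(network)
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
for mode in ("segments", "difference"):
    spec = sv.ComparisonSpec(conditions=[("baseline", baseline),
                                         ("perturbed", perturbed)], mode=mode)
    svg = sv.render_comparison(network, layout, spec, t=5)
    path = out / f"comparison_{mode}.svg"
    path.write_text(svg)
    print(f"wrote {path}")
# In difference mode only species-2 edges appear (species 1 is unchanged),
# and swapping the two conditions flips every stroke's color but not width.
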