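"""Export the full flux time course as an animated GIF.

Each frame shows one time point: edge widths follow flux magnitude
(normalized over the whole series so frames are comparable), metabolite
colors follow their interaction role at that time point, and a cursor
along the bottom marks the current step.
"""

from pathlib import Path

import symbioviz as sv

models, field = sv.make_toy_community(sv.default_scenario(2, n_time=10, seed=1))
network = sv.build_community_network(models)
fluxes = sv.select_point(field, 0, 0)

assignments = sv.role_timeline(network, fluxes)
weight_series = [sv.map_flux_to_weights(network, fluxes, t)
                 for t in range(field.n_time)]
layout = sv.layout_for(network)
gif = sv.render_animation(network, layout, weight_series, assignments,
                          options=sv.RenderOptions(frame_ms=400))

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
(out / "community.gif").write_bytes(gif)
print(f"wrote {out / 'community.gif'}: {field.n_time} frames, 400 ms each, "
      f"{len(gif)} bytes")
# Frame count always equals the number of simulated time points; the layout
# is computed once and held constant so only colors and widths animate.
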