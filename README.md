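# symbioviz

Headless analysis and visualization of **ecosystem-level metabolic
networks** in microbial communities.

Most microbial life happens in multi-species communities whose dynamics
are driven by metabolites exchanged through a shared environment:
cross-feeding (one organism secretes a compound another consumes),
competition for common nutrients, and co-secretion of by-products.
Dynamic flux balance analysis frameworks such as COMETS predict reaction
fluxes for every organism at every time point (and grid location), but
interpreting those predictions requires a community-level view of the
network.  `symbioviz` provides that view as a library plus a small CLI,
for microbiome and systems-biology researchers who work with
genome-scale stoichiometric models and dFBA output.

## What it computes

**Community metagraph.**  Each organism's model becomes a bipartite
metabolite/reaction graph (substrate edges metabolite→reaction, product
edges reaction→metabolite) wrapped in a collapsible *metanode*.  Every
extracellular metabolite touched by an exchange reaction is duplicated
once as an organism-independent *environmental* (ENV) node that carries
a pair of directed exchange edges (uptake side, secretion side) to each
attached exchange reaction.  Node ids are namespaced
(`sp1::ac_e`, `env::ac`) so models never collide.  Loading the published
iJO1366 *E. coli* reconstruction as a one-organism community yields
1,805 metabolite, 2,583 reaction and 324 environmental-metabolite nodes
(4,713 nodes total) connected by 10,831 edges.

**Interaction roles.**  For ENV metabolite *m* at time *t*, each
connected organism's *net exchange* is the sign-normalized sum of its
exchange-reaction fluxes (positive = secretion, in mmol gDW⁻¹ h⁻¹).
With producers P = {net > ε}, consumers C = {net < −ε} and A the
topologically connected organisms:

| role | condition | color |
|---|---|---|
| `single` | \|A\| = 1, or exactly one active organism | dark gray |
| `cross_feeding` | \|P\| ≥ 1 and \|C\| ≥ 1 | light gray |
| `competition` | \|C\| ≥ 2, no producer | red |
| `co_secretion` | \|P\| ≥ 2, no consumer | blue |
| `inactive` | no organism transports it at *t* | white |

**Symbiotic layout.**  Two organisms sit side by side with shared ENV
metabolites on the central column and exclusive ones outside; three or
more organisms sit equiangular on a circle with shared metabolites
pulled toward the center.  All geometry is deterministic.

**Flux rendering.**  Fluxes are rescaled to [0, 1] edge widths, linearly
(w = |v|/vmax) or logarithmically
(w = (log₁₀|v| − log₁₀ floor)/(log₁₀ vmax − log₁₀ floor)), with a lower
weight cutoff and cofactor hiding; output as deterministic SVG frames,
PNG, animated GIF over the time course, and multi-condition comparison
views (parallel segments, or signed two-state difference).

## Worked example

```python
import symbioviz as sv

models, field = sv.make_toy_community(sv.case_study_pair_scenario(seed=1))
network = sv.build_community_network(models)
fluxes  = sv.select_point(field, 0, 0)
report  = sv.role_report(network, fluxes)
print(report[report.time == 5].to_string(index=False))
```

prints

```
metabolite  time  n_producers  n_consumers          role   color
   env::ac     5            1            1 cross_feeding #D3D3D3
 env::lcts     5            0            1        single #696969
env::met_L     5            1            1 cross_feeding #D3D3D3
```

This is the signature of an obligate mutualism: lactose is used by
species A alone (`single`), while acetate (A → B) and methionine (B → A)
are each produced by one partner and consumed by the other
(`cross_feeding`), in opposite directions.  The `examples/` directory
has one short script per capability (network building, classification,
layout + SVG, GIF animation, condition comparison).

The same pipeline is available from the shell:

```bash
symbioviz simulate --species 2 --seed 1 -o bundle/
symbioviz classify -m bundle/manifest.txt --time 6 -o roles.tsv
symbioviz render   -m bundle/manifest.txt --time 6 --mode log --cutoff 1e-5 -o frame.svg
symbioviz animate  -m bundle/manifest.txt -o community.gif
```

Inputs are tied together by a Manifest file (`model`/`flux`/`layout`/
`hidden` entries); models load from SBML or COMETS flat files, fluxes
from COMETS logs or plain TSV tables keyed by reaction id.

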