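# Methods

This note documents the models, conventions and numerical choices behind
`symbioviz`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The community metagraph

Each organism's stoichiometric model is represented as a bipartite
directed graph: one SUBSTRATE edge per distinct (metabolite, reaction)
pair with negative net coefficient (metabolite → reaction) and one
PRODUCT edge per pair with positive net coefficient (reaction →
metabolite).  Coefficient *magnitudes* are deliberately ignored for
edge construction — the graph encodes connectivity; quantitative
information enters later through fluxes.  Coefficients for a metabolite
appearing on both sides of a reaction are netted, and zero entries are
never stored.

The whole per-organism graph is wrapped in a *metanode*.  Metanodes can
be collapsed: internal nodes are hidden and every boundary edge is
replaced by a single aggregated edge per (metanode, external node,
direction) whose multiplicity counts the underlying edges; the removed
originals are kept in an undo log so expansion is a bit-identical
inverse.  Reaction nodes can themselves become metanodes by attaching
enzyme nodes, which supports overlaying regulatory/signaling edges while
preserving the plain bipartite view when collapsed.

### Environmental duplication and exchange edges

An *exchange reaction* is a boundary pseudo-reaction touching exactly
one metabolite, and that metabolite must be extracellular; explicit
exchange flags from the source format always win over this heuristic,
and single-metabolite sink/demand reactions on intracellular metabolites
are excluded.  Extracellular compartments are recognized by a
configurable tag set defaulting to `{"e", "e0", "Extracellular"}`, which
covers both BiGG (`ac_e`, `ac[e]`) and SEED (`H2O_e0`) conventions.

Every exchanged extracellular metabolite is duplicated once as an ENV
node, matched across organisms by a normalized id (strip `M_` prefix and
compartment suffix, then apply an optional synonym table).  Each
(exchange reaction, ENV node) pair carries **two** directed EXCHANGE
edges — `env → reaction` (uptake side) and `reaction → env` (secretion
side) — reflecting the two transport directions of a reversible
exchange.  Under this convention the node count decomposes exactly as

    nodes = Σ_organisms (|metabolites| + |reactions|) + |ENV| + n_organisms

and loading the iJO1366 *E. coli* reconstruction as a one-organism
community gives 1,805 + 2,583 + 324 + 1 = 4,713 nodes and
10,183 (metabolite–reaction pairs) + 2·324 (exchange-edge pairs) =
10,831 edges; the paired-exchange-edge convention is the one that makes
the published edge total come out exactly, and is validated in the
acceptance suite.  Only the `e` compartment counts as extracellular for
this tally: periplasmic metabolites are internal, and iJO1366's six
cytosolic sink/demand boundary reactions are not exchanges.

## Flux data and sign conventions

Fluxes are in mmol gDW⁻¹ h⁻¹, keyed by reaction id per organism per time
point, on an optional spatial grid (one flux vector per cell per model
per step, as dynamic-FBA simulators emit).  Grid data can be inspected
at a single point or averaged; averaging is an unweighted arithmetic
mean over cells by default (biomass weighting is opt-in) and reduces to
the identity on a 1×1 grid.

Net exchange of organism *o* for ENV metabolite *m* at time *t* is

    net(o, m, t) = Σ_r  s_r · v_r(o, t)     over o's exchange reactions r of m

with s_r = +1 when the metabolite is the exchange reaction's substrate
(the standard convention: positive flux = secretion, negative = uptake)
and −1 when it is written as product.  An organism importing and
exporting the same metabolite through distinct reactions is netted.

Missing-data policy (all tolerant cases emit warnings): sparse flux logs
are zero-filled for absent time steps; unknown reaction columns in plain
tables are dropped; a >50% id mismatch in both table orientations is an
error, since it almost always means the wrong model.

## Role classification

Parameters: activity threshold ε ≥ 0 on |net exchange|, default 1e-9
mmol gDW⁻¹ h⁻¹ — small enough to pass any genuine flux, large enough to
absorb solver-level numerical noise; exposed on the API and CLI.

With P = producers, C = consumers, A = topologically connected
organisms, roles are assigned by the first matching rule: SINGLE if
|A| = 1; CROSS_FEEDING if P and C are both non-empty; COMPETITION if
|C| ≥ 2; CO_SECRETION if |P| ≥ 2; SINGLE if exactly one organism is
active; INACTIVE otherwise.  Two points in this rule set were genuinely
open design choices:

* **Syntrophy-first priority.**  A profile with ≥2 producers *and* ≥1
  consumer satisfies several two-organism descriptions at once; we rank
  CROSS_FEEDING above COMPETITION above CO_SECRETION because a
  producer/consumer pair is the ecologically distinctive signal.
* **CO_SECRETION requires zero consumers.**  The stricter reading
  ("produced by more than one organism, consumed by none") is adopted;
  under the priority rule the looser reading ("secreted by both") would
  be unreachable whenever any consumer exists.

SINGLE has two triggers — topological (only one organism connected) and
flux-based (exactly one active organism among several connected) — the
topological one checked first.  The default palette is light gray /
red / blue / dark gray / white for cross-feeding / competition /
co-secretion / single / inactive; a colorblind-safe alternative
(Okabe–Ito orange and blue) is provided.

For ε = 0 the role depends only on the sign pattern, so classification
is invariant under organism relabeling and positive flux rescaling;
the property suite checks this, plus agreement with a brute-force
predicate evaluator and that the five roles partition profile space.

## Symbiotic layouts

All geometry derives from node counts, so tests can assert positions
exactly; ordering is id-lexicographic and there is no randomness.

* metanode radius r(n) = 40 + 6√n canvas units for n member nodes;
* **pairwise**: anchors at (−D, 0) and (+D, 0) with D = max(r_A, r_B) + 80;
  shared ENV metabolites on the x = 0 column (ordered by role, then id),
  exclusive ones at ±(D + r + 60); exchange reactions midway between the
  metanode boundary (toward the metabolite) and the metabolite;
* **circular**: N anchors on radius R = max(150, N(r_max + 40)/π),
  first at 12 o'clock, clockwise in input order; shared ENV nodes at the
  barycenter of their connected anchors scaled by 0.5 toward the center
  (always strictly inside R), with coincident positions separated along
  an id-sorted golden-angle spiral capped at 0.35 R; exclusive ENV nodes
  at R + r_owner + 50 (strictly outside), fanned around the owner's angle.

## Flux-to-width mapping and filtering

Weights live in [0, 1].  Linear: w = |v|/vmax.  Logarithmic:
w = (log₁₀|v| − log₁₀ floor)/(log₁₀ vmax − log₁₀ floor), clipped, with
floor defaulting to the smallest nonzero |v| in scope.  The
normalization scope defaults to the *whole series* (vmax over all time
points) so animation frames remain mutually comparable; per-frame
normalization is available.  Zero-flux edges are hidden, never drawn at
zero width; negative flux on a reversible reaction flips the drawn arrow
and uses |v|.  The mapping can be restricted to an explicit edge
selection (e.g. only interaction-mediating edges).

The view filter hides edges below a weight cutoff (applied to the active
mapping's output, linear or log) and hides listed metabolites — matched
by ENV id, label or raw per-model id, so `H2O_e0`-style cofactor lists
work — together with their incident edges.  Retained weights are never
altered, and the caller recomputes the layout afterwards.  Suggested
cutoffs are 1e-5 for two-organism views and 1e-4 for larger communities
(the CLI defaults).

## Rendering

Two backends share one geometry (`_Canvas` affine transform, common
stroke-width law 0.5 + 4.5w px):

* **SVG 1.1** writer producing byte-identical output for fixed inputs —
  metanode outlines, weighted directed edges, role-colored metabolite
  circles, reaction squares, and sparkline glyphs on exchange reactions
  (40×20 px flux-vs-time polyline, y-axis auto-scaled per glyph, red
  cursor at the current time point; t = 0 at the left edge).
* **Pillow raster** backend for PNG frames and animated GIF export (one
  frame per time point, constant layout, configurable frame delay,
  infinite loop).  Each animation frame includes a time-slider strip
  with a cursor at the current step — the headless counterpart of an
  interactive slider, which also guarantees the encoded frame count
  equals the number of time points.  PNG output is produced directly by
  this backend at a configurable scale rather than by rasterizing the
  SVG.

Comparative views: *segments* mode draws K parallel per-condition
strokes per edge with joint normalization across conditions; *difference*
mode (exactly two conditions) draws one stroke of width ∝ |v₁ − v₂|
colored by the sign, so identical states produce an empty overlay and
swapping the states flips colors but not widths.

## Synthetic communities

The generator emulates the *structure* of dFBA output without running
FBA.  Each species gets a minimal model — exchange, transport and one
internal conversion per nutrient/product, plus a biomass precursor — and
biomass follows a logistic curve B(t) = K/(1 + (K − B₀)/B₀ · e^(−rt))
with B₀ = 0.01 gDW, K = 1 gDW, species-specific r ∈ {0.8, 0.9, 1.0} h⁻¹
and a 0.5 h step.  Exchange fluxes are ± rate · B(t) with rate 2 mmol
gDW⁻¹ h⁻¹ for motif metabolites and 10 for the shared base nutrient —
magnitudes in the range typical of carbon-source exchange in bacterial
dFBA simulations.  Gaussian noise of sd `noise_sd`·rate·B (default 5%)
is added after sign enforcement and clipped away from zero at 5% of the
base magnitude, so every requested motif (cross-feeding chain,
competition, co-secretion, single consumer) yields its intended role at
*every* time point and any seed.  A single seeded RNG stream makes the
whole community reproducible.

What this does *not* emulate: stoichiometric feasibility (fluxes are not
solutions of any LP), mass balance across species, lag phases, death
phases, diffusion, or realistic network sizes.  Passing tests therefore
demonstrate the correctness of graph construction, classification,
layout and rendering logic — not predictive fidelity on real organisms.

## File formats

* **SBML** Level 2 v4 / Level 3 v1 core subset via python-libsbml
  (species, compartments, reactions, stoichiometry, reversible flag;
  `M_`/`R_` prefixes stripped when unambiguous).  No fbc objectives,
  rules or events.
* **COMETS model files**: block format SMATRIX / BOUNDS / OBJECTIVE /
  METABOLITE_NAMES / REACTION_NAMES / EXCHANGE_REACTIONS with `//`
  terminators and 1-based indices.  Compartments recovered from name
  suffixes; reversibility from a negative lower bound.
* **COMETS flux logs**: MATLAB-style `fluxes{t}{x}{y}{m} = [ ... ];`
  assignments, 1-based, vectors bound positionally to each model's
  reaction order.  Parsing is isolated behind one function so other
  dialects can be added.
* **Manifest**: tab-separated `model <format> <path>`, `flux`, `layout`,
  `hidden` and `option.*` lines; relative paths resolve against the
  manifest directory, URLs are kept verbatim.
* **Edge lists**: `source target source_type target_type edge_type`
  TSV with `member` pseudo-edges for metanode membership; exports also
  to GraphML (via networkx) and lossless JSON.

## Problem sizes used in tests and the acceptance script

Property suites run at desk scale: 1,000 random exchange profiles over
2–8 organisms, 50 seeded three-species communities with four motifs and
6 time points each, 20 random communities for the node-count
decomposition, and two- and six-species communities (10 and 8 time
points) for layouts, rendering and round trips.  The published-model
accounting runs on the full iJO1366 reconstruction (2,583 reactions),
read from the copy distributed with the installed cobra package.

## Known limitations

* Time indexing is 0-based throughout (CLI `--time` included).
* URL entries in Manifests are parsed but not fetched.
* Six-organism published-model accounting (KBase gut models) is not
  reproduced here because those models are not redistributable with the
  package; the circular-layout and multi-species logic is exercised on
  synthetic six-species communities instead.
* The weight cutoff applies to the active mapping's output (after log
  rescaling when log mode is on), not to raw fluxes.
* Very large communities render, but no level-of-detail reduction is
  attempted beyond collapse/hide/cutoff filtering.
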