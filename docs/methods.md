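# Methods

This note documents the models and algorithms behind `sigmapnet`, the
choices made where the underlying procedures were originally manual or
under-specified, and what the synthetic benchmarks do and do not establish.

## The map model

A process-description signaling map contains *species* — a molecule in a
specific state, compartment and complexation context — and *reactions*,
both first-class.  `MapSpecies` carries a CellDesigner class (PROTEIN,
GENE, RNA, COMPLEX, SIMPLE_MOLECULE, ION, DRUG, PHENOTYPE, DEGRADED,
UNKNOWN), a `protein_reference` symbol shared by all states of one
molecule, state tags, complex member symbols, and PMID annotations parsed
from the SBML notes (any 6–9 digit token following "PMID",
case-insensitive).  `MapReaction` carries a CellDesigner reaction class and
signed modifier arcs; catalysis/inhibition is always a reaction modifier,
never a separate reaction, which keeps the reaction-category accounting
aligned with how curated maps are drawn.

Identity rules: a species' `protein_reference` is its normalised display
name with recognised state suffixes stripped; complexes contribute their
listed members to the unique-protein set; degraded products are excluded
from it by default (configurable).  These rules are what let "314 protein
species" collapse to "199 unique proteins" in a curated map.

SBML I/O is implemented over the stdlib XML tools for the Level-2 +
CellDesigner-extension subset that carries network semantics (classes,
protein references, states, included species of complexes, reaction types,
modification types, notes).  Writers emit everything in sorted identifier
order, so output is byte-stable; layout, kinetics and rendering are out of
scope.

## Bipartite graph and topology

`build_reaction_graph` makes one node per species and per reaction, with
reactant/modifier arcs entering and product arcs leaving reactions.  A
species holding several roles toward one reaction keeps a single edge
(degree counts direct neighbors, not arcs).

**TF-downstream pruning.**  The transcription-target layer is removed
before topology analysis.  "Downstream of the transcription factor layer"
is operationalised as: the *strict* descendants of the configured TF
species (descendants that are not also ancestors — feedback loops through a
TF belong to the signaling core, not the target layer), minus anything
still reachable from the rest of the map without traversing a TF; a
reachability witness must itself have a neighbor outside the layer, so a
target gene whose only link is its own transcription reaction is removed
with the layer.  The operation keeps the TF nodes, is idempotent, and is
driven by an explicit TF list because curated maps do not mark the layer
machine-readably.

**Statistics.**  Degree and closeness are computed on the undirected view.
Closeness uses the component-size-normalised Wasserman–Faust form
`((r−1)/(n−1)) · ((r−1)/Σd)` so values are comparable on disconnected
graphs and lie in [0, 1]; isolated nodes score 0.  Hubs are nodes with
degree strictly greater than the threshold (default 5).

## Modular decomposition

1. **Core extraction** — the largest strongly connected component is the
   map's central cyclic motif; remaining nodes are classified upstream,
   downstream or detached.
2. **Material components** — for each molecule, all its states (including
   complexes that contain it) plus incident core reactions.  Species
   without any molecule symbol are attached to the components of their
   incident reactions (logged).
3. **Overlap merging** — components sharing ≥ 50 % of the smaller one
   (overlap coefficient |A∩B|/min(|A|,|B|); Jaccard available via config)
   are merged to a fixed point.  The scan order is fixed (descending size,
   then name) and order-independence is asserted by test, replacing the
   manual clustering judgment of the original workflow.
4. **Unique-cycle splitting** — a merged sub-network holding more than one
   nontrivial SCC is split into one part per SCC; acyclic nodes go to the
   SCC they touch in the fewest hops (ties to the larger SCC, then name).
5. **Roles** — after dropping unconnected nodes, nodes unique to one
   sub-network are its *defining* set; external nodes with arcs into
   (out of) the defining set are *incoming* (*outgoing*).  Modules are
   named after their highest-degree defining species (overridable);
   outcome annotations (proliferation, migration, apoptosis, …) are input
   metadata, never computed.
6. **Projection and completeness** — module A activates (inhibits) module
   B when a defining node of A is an activating (inhibitory) modifier of,
   or produces, a defining or incoming node of B; opposite-sign evidence
   yields both edges.  Merging all modules back must reproduce every node
   and edge of the pruned map; the completeness report lists anything
   missed.

## PPI-based expansion

PSI-MITAB 2.5+ records are resolved to canonical symbols (alias table
optional), filtered by a whitelist of PSI-MI detection-method accessions
(default: the two-hybrid family and protein-complementation assays; an
ontology child→parent map extends whitelisting to descendants),
deduplicated across databases, and self-interactions dropped.

The expansion base network is the undirected protein-level projection of
the map (two molecules adjacent when they co-occur in a reaction or a
complex) unioned with interactome edges among map proteins.  Every protein
with ≥ 1 map partner is evaluated *independently against the unmodified
base network*, so verdicts cannot interact.

**The four compactness indicators.**  A tightly linked interactor should
make the map denser, more central, more clustered and shorter-pathed.  The
literal reading — "all four all-node network means must improve" — is
unsatisfiable: on a connected graph the mean betweenness is identically
`(L−1)/(N−2)` (L the characteristic path length), so it cannot rise while
L falls; and the mean local clustering coefficient mechanically falls
around any well-connected addition because its partners gain neighbors
faster than triangles.  The implemented test, one delta per indicator:

| indicator   | implemented as                                             | accepted when |
|-------------|------------------------------------------------------------|---------------|
| degree      | change in mean degree 2E/N                                 | > 0 |
| betweenness | candidate's betweenness − extended-network mean            | > 0 |
| clustering  | change in the network's triangle count                     | > 0 |
| path length | change in mean shortest-path distance over connected pairs | < 0 |

Acceptance is the conjunction (configurable to any *k*-of-4).  Betweenness
is the normalised shortest-path form with endpoints excluded; path length
averages over connected ordered pairs only, so a candidate that joins
components legitimately shortens it.  A candidate already in the base
network can only add its missing interactome edges; with the base network
defined as above it adds nothing and is rejected — in-map acceptances in
the original analysis depended on an interactome snapshot that no longer
exists and are not reproduced.  The indicator set lives entirely inside
`evaluate_candidate` for easy substitution.

## Synthetic worlds

`generate_map` plants `n_modules` modules, each a kinase-hub motif: one
hub molecule drives a 2-reaction activation/deactivation loop with every
member molecule and catalyses the members' state cycles.  Consequences,
by construction:

* every member's material component shares its state-cycle and
  hub-coupling reactions with the hub's component, giving overlap ≥ 1/2 —
  exactly what the merge step needs to reassemble the module;
* modules are chained in a ring of signed cross-talk arcs (plus random
  extras at `bridge_density`, degree-weighted sources, ≤ 1 per species,
  always targeting member→hub return reactions), making the whole core one
  SCC while keeping cross-module component overlap < 1/2;
* hubs acquire degrees an order of magnitude above the median, emulating
  the right-skewed degree distribution of real maps;
* modules with ≥ 3 molecules get one hub-catalysed heterodimer
  association/dissociation loop, adding COMPLEX species and member–member
  protein-projection edges;
* `tf_layer_size` transcription tails (TF → transcription → RNA →
  translation → protein, gene as transcription reactant) hang off module
  hubs and are exactly what pruning must remove (5 nodes per tail).

`generate_interactome` wires planted candidates to
`ceil(planted_wiring_fraction × |map proteins|)` uniformly chosen map
proteins — redrawing (bounded, then minimally repairing) a draw that
contains no map-adjacent protein pair, since a tight interactor closes
triangles by definition — and decoys to 1–2 partners; 10 % of decoy
records carry non-whitelisted detection methods to exercise the filter.
Both generators are byte-deterministic given a seed.

Defaults (the frozen benchmark): 8 modules of 6–14 molecules with 1–4
states, bridge density 0.05, 4 TF tails, 10 planted candidates at wiring
fraction 0.3, 200 decoys.  On seeds 0–9 the pipeline recovers all 8
modules with defining-set Jaccard 1.0, the completeness report is empty,
all 10 planted candidates are accepted and no decoy is.

**What a green benchmark does not establish.**  The generator's modules
are cleanly separable by construction; real curated maps contain molecules
shared between pathways, multi-protein reactions and curation noise, where
the ≥ 50 % overlap rule involved manual judgment and exact module
boundaries are not expected to be reproduced.  Likewise the synthetic
interactome has no false-positive edges among map proteins and no study
bias; the decoy-rejection rate measured on it is an upper bound on
specificity, not an estimate for real interactomes.

## Numerical and degenerate-input conventions

* All randomness flows from a single integer seed (`random.Random`);
  identical spec + seed give byte-identical SBML/MITAB files and report
  bundles (the manifest records the configured paths; no timestamps are
  written).
* Acyclic graphs yield an empty core and everything detached; single-node
  networks report path length 0 by convention; empty models yield all-zero
  category tables.
* Merge and split tie-breaks are fixed (size descending, then name), so
  decomposition is deterministic despite originating from a partly manual
  procedure.
* Unknown CellDesigner classes parse to UNKNOWN with a logged warning;
  malformed XML and dangling species references are hard errors naming
  the line or reaction.

## Known limitations

* The exact published module boundaries of curated maps (18 for the CCKR
  map) involved curator judgment and are not a target; counts and the
  published graph/category totals are (they require the deposited SBML
  file, see `data/README.md`).
* Published expansion counts (4119 interactors, 102 accepted, 70 novel)
  depend on a 2012 interactome snapshot and cannot be recomputed; the
  synthetic benchmark replaces them with planted-truth recovery.
* The PSI-MI whitelist ships as an editable default, not a reproduction of
  any specific published filter list.
* No SBGN rendering, kinetics, layout, GO enrichment, or live PSICQUIC
  queries.
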