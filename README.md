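# sigmapnet

Network analysis of literature-curated signaling maps in CellDesigner-style
SBML (SBGN process description): topology statistics, modular decomposition,
and protein–protein-interaction-based map expansion.

## Who this is for

Curated signaling maps — such as the cholecystokinin/gastrin receptor (CCKR)
map, where both molecular species and the reactions transforming them are
first-class nodes — are too large to reason about directly.  `sigmapnet`
turns such a map into quantitative, testable structure:

1. **Map accounting** (`sigmapnet.model`, `sigmapnet.sbml_io`): parse the
   CellDesigner dialect of SBML into a typed model and produce the standard
   overview table — species per category, reactions per category, and the
   number of *unique proteins* after collapsing all states of one molecule
   onto its shared reference symbol.
2. **Bipartite topology** (`sigmapnet.graph`): the directed species–reaction
   graph (reactant and modifier arcs enter reactions, product arcs leave
   them), pruning of the layer downstream of the transcription factors,
   node degree *k*, Wasserman–Faust closeness centrality on the undirected
   view, and hubs (nodes with *k* > 5).
3. **Modular decomposition** (`sigmapnet.decompose`): extract the strongly
   connected core (the map's central cyclic motif), split it into *material
   components* (all states of one molecule plus their incident reactions),
   merge components sharing ≥ 50 % of the smaller one
   (overlap = |A∩B| / min(|A|,|B|)), re-split anything holding more than one
   cyclic motif, and assign roles: *defining* (module-specific), *incoming*
   (upstream regulators), *outgoing* (downstream effectors).  The map is
   then projected onto a signed activation/inhibition module network, and a
   completeness check certifies that merging the modules back reproduces
   the map.
4. **PPI expansion** (`sigmapnet.ppi`): read PSI-MITAB interaction records,
   keep binary physical interactions via a PSI-MI detection-method
   whitelist, and test every interactor of the map with a four-indicator
   network-compactness criterion.  Candidate *v* is accepted iff adding it
   (with its interactions to map proteins) to the map's protein network

   * raises the mean degree (Δ(2E/N) > 0),
   * gives *v* above-average betweenness in the extended network,
   * closes new triangles (Δ#triangles > 0), and
   * lowers the characteristic path length (ΔL < 0).

   Accepted interactors are split into in-map and novel, and classified
   per module as single- or multi-module.
5. **Synthetic worlds** (`sigmapnet.synthetic`): seeded generators for maps
   with planted modules, a planted cyclic core, transcription tails and
   hub-dominated degree distributions, plus MITAB interactomes with planted
   tight candidates among loose decoys — so every stage is testable against
   known ground truth without downloads.
6. **Pipeline** (`sigmapnet.pipeline`): `run_pipeline(PipelineConfig(...))`
   orchestrates everything into a deterministic plain-file report bundle;
   `compare_to_reference` checks a bundle against published-style counts.

## Worked example

```bash
python examples/03_decompose_modules.py
```

prints (seed 1 of the default synthetic world):

```
strongly connected core: 488 of 488 nodes
8 modules recovered (planted: 8)
  M1HUB    defining  98  incoming   1  outgoing   2
  M4HUB    defining  80  incoming   1  outgoing   1
  ...
signed module-level edges:
  M0HUB --| M1HUB
  M2HUB --> M3HUB
  ...
complete cover of the map: True
```

The entire pruned map is one strongly connected component; the
decomposition recovers exactly the 8 planted modules (named after their
highest-degree defining species, the module hubs), every planted signed
cross-talk arc appears in the module-level projection (`-->` activation,
`--|` inhibition), and the completeness check confirms nothing was lost.
Likewise `examples/04_expand_with_ppi.py` filters 551 interaction records
down to 514 binary physical interactions and accepts exactly the 10
planted tight interactors out of ~200 candidates:

```
accepted interactors: 10 (10 of 10 planted)
  EXP0: 25 map partners, d_degree +0.581, d_betweenness +0.314, new triangles +10, d_path_length -0.359
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world from the seed, runs the complete pipeline
(parse → prune → topology → decomposition → PPI expansion), prints the
headline counts of the run, and writes the acceptance-target report to the
given path.

See `docs/methods.md` for the models, the numerical choices and the known
limitations.
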