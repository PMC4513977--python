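# Optional reference data

Two acceptance tests reproduce the published accounting of the curated
cholecystokinin/gastrin receptor (CCKR) signaling map.  The map's SBML file
is journal supplementary material and is not redistributed here.

To run those tests, place:

- `cckr_map.xml` — the CellDesigner SBML export of the CCKR map
  (supplementary "Additional file 1" of the map's publication, unzipped);
- `cckr_tf_list.txt` — one species id per line naming the map's
  transcription-factor species (used by the TF-downstream pruning step).

Everything else in the test suite and the acceptance script runs from
synthetic data generated at test time.
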