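# ecforest

Enzyme function prediction from protein sequences: a 73-feature
physicochemical featurization feeding a three-tier random-forest cascade
(enzyme vs non-enzyme → EC main class 1–6 → EC sub-class "X.Y"), plus a
direct single-step sub-class model, carry-over-adjusted evaluation metrics
that propagate main-class errors into sub-class reporting, and
permutation-based feature ranking.

## What's inside

| Module | Role |
| --- | --- |
| `ecforest.sequence_io` | FASTA + labels-TSV I/O, residue validation, exact (100% identity) deduplication |
| `ecforest.features` | 73-feature schema: mole%, dayhoffstat, property-class compositions, MW, theoretical pI, GRAVY, aliphatic/instability indices, atom counts, extinction coefficient — tables shipped as versioned JSON |
| `ecforest.cascade` | Model 1 (three-tier cascade) and Model 2 (direct), OOB-error grid tuning, stratified cross-validation, directory-based persistence |
| `ecforest.evaluation` | Per-class precision/recall, one-vs-rest ROC areas, largest-remainder carry-over allocation, adjusted ("new") precision/recall |
| `ecforest.importance` | Mean-decrease-in-accuracy permutation importance; per-class five-number feature summaries |
| `ecforest.synth` | Seeded synthetic datasets with controllable class-conditional residue compositions (strong/weak separability presets) |
| `ecforest.cli` | `ecforest` command-line front end |

## CLI quick start

```sh
ecforest simulate --preset strong --per-sub-class 50 --seed 1 --out run/data
ecforest features --fasta run/data/sequences.fasta --out run/feats
ecforest train-cascade --features run/feats/features.tsv \
    --labels run/data/labels.tsv --seed 1 --out run/model
ecforest predict  --model run/model --features run/feats/features.tsv --out run/preds
ecforest evaluate --model run/model --features run/feats/features.tsv \
    --labels run/data/labels.tsv --out run/eval
ecforest importance --features run/feats/features.tsv \
    --labels run/data/labels.tsv --out run/imp
ecforest tune --features run/feats/features.tsv --labels run/data/labels.tsv \
    --ntree-grid 50,100,200 --mtry-grid 5,7,15,25 --out run/tune
```

Every command writes a `manifest.run.json` (config echo, version, seed,
timing) sufficient to re-run it identically.

## Notes

- Default forest parameters follow the tuned values: level 1 `ntree=200,
  mtry=25`; levels 2–3 `ntree=200, mtry=7`; direct model `ntree=200, mtry=5`.
  Feature values are used unnormalized.
- The default ambiguity policy drops sequences containing non-standard
  residues (B, Z, X, U, O, J, `*`), since mole% and dayhoffstat are defined
  only over the 20 standard residues; `strip-residue` is available.
- The carry-over allocation uses the deterministic largest-remainder
  method; adjusted metrics anchor on the closed-form formulas
  `TP/(TP+FP+carryFP)` and `TP/(TP+FN+carryFN)`.
- The pKa set defaults to the EMBOSS values; the Bjellqvist set (with
  residue-specific terminal adjustments) is available via
  `load_tables(pka_set="bjellqvist")` or `ecforest features --pka-set`.
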