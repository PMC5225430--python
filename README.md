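# resq

Per-residue ("local") quality prediction for protein structure models.
A model's Cα trace is represented as a spatial residue graph — main-chain
edges, contact edges below a neighbor cutoff, and a one-pass shared-neighbor
closure — and a conditional random field over the maximal cliques of that
graph predicts, for every residue, whether its modelled position lies within
a chosen error cutoff of the correct position after global superposition.

Key ingredients:

- **structure**: Cα-only PDB parsing, Kabsch (SVD) superposition with
  per-residue displacement, coarse H/B/C secondary-structure assignment from
  Cα geometry (with a file-override hook for DSSP-style input).
- **graph**: three-layer residue graph construction and classification of
  edges into five secondary-structure classes (HH, BB, HB, CHB, CC).
- **cliques**: deterministic min-fill triangulation, Bron–Kerbosch maximal
  clique enumeration, and a junction tree verified for running intersection.
- **crf**: the probability model (label-conditioned node weights λ, four
  ordered pair-pattern weights ω, per-edge-class weights w), exact
  sum-product marginals and max-product MAP on the clique tree, SGD training
  of the conditional log-likelihood, plus a 1.0 Å "linear" degeneration and
  a logistic-regression baseline.
- **features**: the 25-feature per-residue schema (6 local), with contact
  order, MSA column statistics (BLOSUM45 mutation score, gap ratio,
  conservation) and log/ratio transforms computed in-package; external
  program scores ingested from TSV; Z-scoring against the training set.
- **evaluate**: label generation from model-vs-native superposition,
  accuracy/MCC (with explicit undefined handling), paired t-tests,
  model-level k-fold cross-validation, neighbor-cutoff comparisons, and the
  6^5 edge-weight grid search.
- **synthetic**: seeded toy structures with ideal helix/strand geometry,
  perturbed models with planted error regions, and CRF-sampled datasets for
  parameter-recovery experiments.

## CLI

```bash
# generate a small synthetic benchmark (natives, perturbed models, features)
resq synth --n-models 10 --n-residues 12 --ss-layout CCHHHHHCCBBB --seed 1 --out data/

# train CRF parameters (writes params.json + per-epoch log-likelihood log)
resq train --models data/models --natives data/natives --features data/features \
           --seed 1 --out params.json

# predict per-residue quality for one model
resq predict --params params.json --model data/models/synth000.pdb \
             --features data/features/synth000.tsv --out pred.tsv

# score predictions against the native structure
resq evaluate --predictions pred.tsv --model data/models/synth000.pdb \
              --native data/natives/synth000.pdb

# grid-search the five secondary-structure edge weights (subset shown)
resq gridsearch --models data/models --natives data/natives \
                --features data/features --max-points 10 --out grid.json
```

Defaults live in `resq.config.RunConfig` (YAML-loadable): neighbor cutoff
4.5 Å, Cα error cutoff 5.0 Å, 25 features, uniform edge weights, SGD with
learning rate 0.05, 50 epochs, L2 penalty 1e-3.

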