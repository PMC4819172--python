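# qprob

Single-model protein quality assessment: estimate a structural model's
GDT-TS without the native structure by combining per-feature Gaussian
error densities and taking the quality value that maximizes the combined
density.

## Who this is for

Structure-prediction groups and assessors who need to rank a pool of
candidate 3-D models for one target — the CASP "QA" setting — using only
each model on its own (no consensus over the pool, so it also works when
the pool is small or dominated by low-quality models).

## The method

Eleven features are computed per model, each normalized to [0, 1] and
oriented so that larger means better: a distance-dependent statistical
potential (RF_CB_SRS_OD), secondary-structure similarity and penalty
scores against an external sequence-based prediction, a Euclidean
compactness score, three solvent-exposure scores (nonpolar surface
fraction, exposed mass fraction, exposed surface fraction), a solvent-
accessibility similarity score, and three more energy/ML scores (RWplus,
ModelEvaluator, Dope).  Raw statistical-potential values grow with chain
length *L*, so they are mapped linearly onto [0, 1] over length-dependent
ranges (e.g. DFIRE2 over [−1.971·L, 0], RWplus over [−232.6·L, 0],
RF_CB_SRS_OD over [0.4823·L − 300, 700]).

On a training pool with known true qualities, the error of feature *i* on
model *j* is

    FE_ij = F_ij − R_j

where *F_ij* is the feature score and *R_j* the real GDT-TS; its mean
*M_i* and standard deviation *SD_i* are fitted per feature.  At
prediction time each feature's adjusted score `Adjust_pre_i = pre_i − M_i`
centres a Gaussian density that is divided by its own peak,

    f_i(X) = exp(−(X − Adjust_pre_i)² / (2·SD_i²)),

and the combined score over candidate qualities X ∈ [0, 1] is the
weighted sum

    P_combine(X) = Σ_i W_i · f_i(X).

The grid value of X maximizing P_combine is the predicted GDT-TS.  The
weights W_i are trained by grid coordinate descent (step 0.01 on
[−0.8, 0.8]) minimizing the per-target average GDT-TS loss — the true
quality of the best model minus that of the model ranked first.  The
package ships the published weight vector
[0.03, 0.09, 0.04, 0.08, 0.08, 0.01, 0.03, 0.10, 0.00, 0.09, −0.02].

Everything needed to train and evaluate is included: a PDB/FASTA/DSSP
reader layer, an internal Shrake–Rupley surface-area sampler and
dihedral-window secondary-structure assigner (a DSSP file overrides
both), a GDT-TS implementation (exact by subset enumeration on small
chains, fragment-seeded heuristic beyond), CASP-style metrics (per-target
Pearson/Spearman/Kendall, top-1 loss, Wilcoxon signed-rank, summed
Z-scores), and synthetic generators so the whole loop runs without any
external data.  The third-party energy programs themselves are out of
scope; their raw outputs are consumed from a TSV table.

## Worked example

`python examples/score_models.py` builds a 16-residue helix, perturbs it
into three decoys (0.5 / 3 / 8 Å coordinate noise), computes their
features plus one external ML score, and ranks them:

```
decoy_rms0.5   true GDT-TS 1.000  external score 1.000
decoy_rms3     true GDT-TS 0.672  external score 0.668
decoy_rms8     true GDT-TS 0.281  external score 0.300

    model_id  score
decoy_rms0.5  1.000
  decoy_rms3  0.684
  decoy_rms8  0.255
```

The score column is the predicted GDT-TS; the ranking follows the true
perturbation order, and the predicted values track the true qualities.
`examples/train_pipeline.py` runs the full training loop on synthetic
data (fitted error SDs, trained weights, held-out loss 0.0065) and
`examples/gdt_and_metrics.py` shows the ground-truth GDT-TS machinery.

The same workflow is available from the shell:

```
qprob synth --seed 0 --out data/
qprob train-errors --features data/features.tsv --truths data/truths.tsv --out stats.yaml
qprob train-weights --features data/features.tsv --truths data/truths.tsv \
    --stats stats.yaml --seed 42 --out weights.yaml
qprob score --target target.fasta --models models/ --raw-scores raw.tsv \
    --stats stats.yaml --weights weights.yaml --out scores.tsv
qprob evaluate --predictions preds.tsv --truths truths.tsv
```

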