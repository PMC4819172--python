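# Methods

## Model

The predictor treats every feature score as a direct, noisy estimate of
the model's true GDT-TS.  For feature *i* with score `pre_i`, the error
`FE_ij = F_ij − R_j` observed on a training pool is modelled as a
Gaussian with mean `M_i` and standard deviation `SD_i`; subtracting the
bias gives the adjusted score `Adjust_pre_i = pre_i − M_i`, an unbiased
point estimate of GDT-TS under the model.  Each feature then contributes
a density in the candidate quality X centred at its adjusted score with
width `SD_i`, divided by its own peak so its maximum is exactly 1, and
the prediction is

    X* = argmax_X Σ_i W_i · exp(−(X − Adjust_pre_i)² / (2·SD_i²))

over the grid {0, 0.001, …, 1}.  The combination is a weighted **sum**
of peak-normalized densities, not a product: the individual densities
are deliberately renormalized into [0, 1], and one shipped weight is
negative, which a product could not express.  A sharp (small-SD) feature
therefore acts as a strong local vote around its own estimate while
diffuse features supply a broad prior-like background.

Assumptions worth keeping in mind: feature errors are treated as
mutually independent Gaussians even though `FE ∈ [−1, 1]` (the
truncation bias is accepted) and even though real feature errors are
correlated; and the error statistics are assumed transferable from the
training pool to new targets.

## Features

Seven features come from the model itself (plus external per-residue
predictions); four are externally computed energies/ML scores consumed
from a TSV table and normalized here.  Canonical order, used everywhere
to index `M_i`, `SD_i`, `W_i`:

| # | feature | definition |
|---|---------|------------|
| 1 | rf_cb_srs_od | raw score normalized over [0.4823·L − 300, 700], lower raw = 1 |
| 2 | ss_similarity | fraction of residues whose predicted 3-state secondary structure matches the model's |
| 3 | ss_penalty | (F_H + F_S)/N: confirmed helix + sheet predictions over sequence length |
| 4 | euclidean_compact | mean pairwise CA–CA distance over D_ref(L) = 5.54·L^(1/3)·2.0, clipped |
| 5 | surface_nonpolar | Σ SE_i / Σ S_i: nonpolar share of exposed area |
| 6 | exposed_mass | mass fraction of residues with relative accessibility > 0.25 |
| 7 | exposed_surface | Σ S_i / Σ ST_i: exposed over reference area |
| 8 | sa_similarity | fraction of residues whose predicted 2-state exposure matches the model's |
| 9 | rwplus | raw energy normalized over [−232.6·L, 0] |
| 10 | modeleval | external SVM score, already in [0, 1], used as-is |
| 11 | dope | raw energy normalized over a configurable range (defaults below) |

A DFIRE2 normalizer (range [−1.971·L, 0]) is provided as well; a
`dfire2` column in a raw table is parsed but is not part of the
11-feature combination vector, which follows the canonical listing.

Orientation: every normalizer maps the *best* (lowest) energy to 1, so
all features point the same way as GDT-TS; without this the fitted error
means could not be small.  Normalization uses the target sequence length
N rather than the model's resolved residue count, so partially built
models are not rewarded.

Surface quantities use an internal Shrake–Rupley sampler: each atom's
probe-expanded sphere (probe 1.4 Å) is sampled on a deterministic
Fibonacci lattice of 960 points; a point is accessible if outside every
neighbour's expanded sphere.  The lattice makes results reproducible and
rotation-invariant to within ~0.5 %.  Reference ("total") areas ST_i are
a fixed Gly-X-Gly table; residues are called exposed above relative
accessibility 0.25 (a common convention).  The nonpolar set is
{A, V, L, I, P, F, M, W, G, C}.  Secondary structure comes from backbone
dihedral windows — helix φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] over runs of
≥ 4; sheet φ ∈ [−180°, −40°], ψ ∈ [50°, 180°] ∪ [−180°, −170°] over runs
of ≥ 3 — unless a DSSP output file is supplied, in which case its
8-state codes are collapsed (H,G,I→H; E,B→E; else C) and its per-residue
accessibilities replace the internal SASA.

The compactness reference D_ref(L) = c·L^(1/3)·s follows the
radius-of-gyration scaling law, giving a length-free [0, 1] mapping; its
constants (c = 5.54 Å, s = 2.0) and the Dope normalization range
(lower bound dope_slope·L·dope_span = −1.0·L·100 by default) are
package choices exposed in the config, as the source formulas for these
two quantities are not fully specified.

## Error model

`M_i` is the sample mean and `SD_i` the population (÷ n) standard
deviation of the errors — the distinction is negligible at training
scale.  SDs are floored at 0.01 to prevent delta-function densities;
features with fewer than 10 samples are flagged unusable.  Error pooling
is joint over all models, not per-target.

## Weight training

Grid coordinate descent on the per-target average top-1 loss: weights
live on {−0.80, −0.79, …, 0.80}; Min-Loss starts at 1; features are
swept in canonical order, each scanning all 161 grid values with the
rest fixed; sweeps repeat until one full sweep changes nothing (cap
100).  Acceptance of a scanned value requires a strictly lower loss;
among equal-loss candidates the value closest to zero wins (negative
before positive), and an equal-loss move strictly toward zero is itself
accepted — the (loss, |w_i|) pair decreases lexicographically, so
termination is preserved while flat directions get sparsified instead of
freezing.  Because the loss is non-convex and a purely random start
frequently strands the search at a noise-weight local optimum, the
trainer always descends once from the all-zero vector in addition to the
seeded random restarts and returns the best run.  Loss evaluation
exploits linearity of the combined density in the weights: per-model
density matrices over the grid are precomputed once and each coordinate
scan reuses the fixed-feature part.  (Renormalizing weights over present
features only rescales the combined density by a positive factor when
the present-weight sum is positive, so it cannot change a model's argmax
and is ignored inside the trainer.)

## Scoring details

Adjusted centres are clipped into [0, 1] (config-switchable) so the
argmax stays in the valid GDT-TS range; grid ties break toward the
smallest X; pool rankings break score ties by model id; output is
rounded to the 0.001 grid.  When some features are missing, the
remaining weights are scaled to preserve the full-set weight total, and
a model needs at least 4 present features to be scored.

## Ground truth and evaluation

GDT-TS is the mean over the 1/2/4/8 Å thresholds of the largest
fraction of shared CA atoms (matched by residue index, native-length
denominator) that a rigid superposition brings within the threshold.
For chains of ≤ 12 shared residues the optimum is computed exactly by
Kabsch-fitting every ≥ 3-residue subset; beyond that, a heuristic seeds
superpositions from all contiguous fragments of lengths 3/5/7 plus the
full set and refines each by iterative inclusion (≤ 10 rounds).  The
heuristic can only undercount, never overcount, relative to the exact
search; the tests bound its gap on 12-residue chains.  Ranking metrics:
Pearson/Spearman and tie-corrected Kendall tau-b per target (constant
vectors are reported missing and excluded from averages), top-1 loss
with ties resolved by model-id order (never optimistically), paired
two-sided Wilcoxon signed-rank (exact null for ≤ 25 non-zero
differences, else normal approximation with continuity correction,
zeros dropped, ≥ 6 non-zero pairs required), and per-target Z-scores of
each method's selection floored at −2 (CASP convention) and summed.

## Synthetic data

The generator mirrors the method's own noise model: per model a true
quality R ~ U[0.2, 0.9] is drawn and feature *i* takes
clip(R + N(μ_i, σ_i), 0, 1), independent across features.  Defaults —
20 targets × 30 models, σ = 0.1, μ = 0 — are a reduced-scale stand-in
for a QA training season (two orders of magnitude smaller than a real
one, chosen so the full train/score loop runs in seconds).  Coordinate
fixtures are ideal backbones built from standard internal geometry
(φ/ψ = −57°/−47° helix, −120°/130° extended) and decoys perturbed by
seeded Gaussian noise with per-coordinate SD rms_target/√3.  What the
generator does **not** emulate: correlated feature errors, per-target
difficulty structure, physically realistic decoy geometry, missing
residues.  Green tests on synthetic data therefore validate the
machinery and its statistical contracts, not performance on real CASP
pools.

## Limitations

- The four energy/ML features require externally computed raw scores;
  the potentials themselves are not reimplemented.
- Single chain only; no per-residue (local) quality estimates; no
  consensus or hybrid scoring.
- The internal secondary-structure and surface assigners are simplified
  stand-ins for DSSP; supply DSSP files for fidelity-critical runs.
- The GDT-TS heuristic approximates the LGA search from below on chains
  longer than 12 residues.
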