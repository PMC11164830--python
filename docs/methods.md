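# Methods

## Problem setting and model

Each tissue section pairs an RGB whole-slide H&E image with an N × M
spots × genes count matrix, per-spot pixel and array-grid coordinates, and
(optionally) a binary tumor/normal annotation per spot. The model treats
expression prediction as multi-output regression from the spot's image
patch, with hard parameter sharing: one convolutional encoder, three linear
heads (target genes, non-target genes, tumor probability). The target set
is the m genes with the highest mean normalized expression on the training
split (m = 250 by default at tissue scale; smaller for desk-scale runs);
lowly expressed genes have poor signal-to-noise, so they are demoted to an
auxiliary head whose only job is to shape the shared representation.

The objective is `L_prim + λ·L_aux + β·L_tmr + γ·L_spat`. The spatial term
encodes the prior that adjacent spots with the same pathological annotation
express similarly: over all (central, grid-neighbor) pairs within the 3 × 3
array window whose annotations match, it averages the squared difference of
predicted target expression and divides by the number K of such pairs
(returning 0 when K = 0). Annotations enter this term as ground-truth
labels, not predictions.

Interpretation choices where the formulation leaves room:

* **Vector reduction in the spatial term.** The squared difference between
  two predicted expression vectors is reduced by the *mean* over the m
  target genes (config-switchable to sum). The mean keeps γ's scale
  comparable to the primary MSE regardless of m.
* **K counts directed pairs.** All (central, neighbor) ordered pairs with
  matching labels inside the batch are counted; with both members of a pair
  in the batch each unordered pair contributes twice to both numerator and
  denominator, so the value is unchanged and the definition stays simple.
* **Spatial term acts on the target head only** (config-switchable); it is
  motivated as a constraint on the primary predictions.
* **Batching under γ > 0** samples central spots and pulls their available
  grid neighbors into the batch ("neighborhood batching") so K > 0 pairs
  exist; with γ = 0, plain shuffled batching is used.

## Backbone

The bundled `tiny_cnn` encoder is two 3 × 3 convolution + ReLU + 2 × 2
average-pool stages (8 then 16 channels) followed by one dense ReLU layer
(64 units) — implemented directly on numpy with explicit backpropagation
and trained with Adam. It accepts any patch side divisible by 4 and is
sized so that full train/evaluate cycles on simulated cohorts take seconds
on one CPU. The `resnet50` backbone name is reserved in the config surface
for externally supplied pretrained encoders; no pretrained weights ship
with the package, and requesting them raises a clear error. Warm-starting
from a previous checkpoint covers the no-train / fine-tune /
train-from-scratch evaluation modes.

Regression head biases are initialized to the per-gene training means so
the first epochs fit structure rather than the global offset; all other
weights use seeded He initialization. Two runs with the same data, config
and seed produce bit-identical loss trajectories.

## Preprocessing

Order: boundary exclusion → spot QC → gene QC → normalization. Gene
detection counts must reflect retained spots, hence gene QC after spot QC.

* **Boundary exclusion**: a patch window of side w centered at integer
  pixel c covers the half-open span `[c − ⌊w/2⌋, c − ⌊w/2⌋ + w)` per axis
  (float centers rounded to the nearest pixel first); spots whose window
  exits the image are excluded, never padded. Resizing to the model input
  size uses bilinear interpolation and is skipped exactly when the window
  already matches.
* **Spot QC** keeps a spot iff total UMIs ∈ [200, 20 000] (the bounds are
  inclusive: "fewer than" / "more than" are strict exclusions),
  mitochondrial fraction ≤ 5%, and ≥ 200 detected genes. Mitochondrial
  genes are recognized by the name prefix `MT-` (configurable).
* **Gene QC** keeps genes detected in ≥ 3 spots; in multi-sample cohorts
  detection is pooled across samples so all samples share one gene set
  (the shared heads require it).
* **Normalization**: `ln(1 + 10⁴ · c_ij / total_i)` (natural log,
  pseudocount 1). Target-gene ranking for the partition uses normalized
  means on the training split, matching the scale of the regression loss;
  ties break lexicographically by gene name so the partition is
  deterministic. Patch channel statistics (mean/std of pixel values / 255)
  are computed on training patches only and frozen into the checkpoint.

All of these thresholds sit in `QCThresholds`; `desk_scale_thresholds()`
provides the scaled-down variant used with the simulator (min 50 UMIs,
min 10 detected genes), since simulated libraries carry 50 genes rather
than tens of thousands.

## Training and evaluation

Patients are the unit of splitting: no spot from a validation or test
patient contributes to training, the gene partition, or the channel
statistics (verified by a test that training with held-out patients present
is bit-identical to training with them removed). Model selection keeps the
epoch with the best validation aPCC on target genes; optional early
stopping monitors the same quantity. Defaults: Adam, learning rate 3e-3,
batch size 64, flips/rotations augmentation off (on request via config).

Metrics: aMSE uses the same mean-over-spots-and-genes reduction as the
losses; aPCC is the mean per-gene Pearson correlation across spots, with
zero-variance genes assigned correlation 0 (not dropped) so denominators —
and hence NGPC, the count of genes with positive correlation — stay
comparable across methods; tumor ACC uses threshold 0.5; AUC/AUPRC are
reported as missing with a warning when the annotation set is single-class.
Probabilities are clamped to [1e-7, 1 − 1e-7] inside the cross-entropy.

The ablation runner trains one model per loss-term toggle pattern —
untrained (Random), primary-only, each auxiliary term in isolation, and the
full model with and without the spatial constraint — and emits a TSV with
one row per variant and seed.

`differential_gene_ranking` ranks target genes by the absolute difference
of mean normalized expression between tumor and normal spots, descending,
ties broken lexicographically; the signed differences are reported.

## Synthetic data generator

The simulator emulates the statistical structure the method relies on,
not tissue appearance:

* spots on an n_rows × n_cols array grid, pixel centers spaced one patch
  width apart (patches disjoint, none touching the slide boundary);
* tumor annotation as a union of disc-shaped blobs in grid space —
  spatially autocorrelated region-level labels, the structure the spatial
  loss exploits (a permutation test on neighbor label agreement confirms
  autocorrelation at p < 0.01);
* patches rendered procedurally: noisy pink base, per-spot mean-intensity
  shift and mock-nucleus density driven by the latent tumor state and a
  continuous per-spot morphology covariate z ~ N(0,1), both scaled by
  `image_signal_strength` (0 disconnects image from expression entirely);
* counts drawn per spot and gene from a negative binomial
  (variance μ + μ²/size, size = 16 by default). Ten "coupled" genes have
  state-dependent means additionally modulated by exp(±0.25·z); the
  remaining "decoy" genes share one low mean (2), providing the many
  near-zero counts typical of spot-level data. Technical dropout zeroes a
  count with probability `0.05 · exp(−μ/4)` — the usual zero-inflation
  pattern concentrating in lowly expressed genes;
* per-patient log-normal random effects (σ = 0.1) on gene means mimic
  batch effects between patients; sections of one patient share the effect.

Two deliberate design choices:

* **Coupled genes alternate up- and down-regulation in tumor with
  symmetric means (8 ↔ 32).** With one-sided up-regulation, library size
  itself becomes tumor-dependent, and total-count normalization then leaks
  tumor signal into every *decoy* gene — decoys would stop being noise-only
  after normalization. Symmetric coupling keeps per-spot totals
  approximately state-independent, which is also biologically sensible.
* **Dropout is mean-dependent.** Uniform dropout at these means produces
  catastrophic log-scale outliers (a zeroed count where ln ≈ 6 is expected)
  that cap the achievable per-gene correlation of *any* predictor near the
  recovery threshold; real technical dropout concentrates in weakly
  expressed genes, and modeling it that way keeps the coupled genes'
  noise ceiling high (oracle per-gene PCC ≈ 0.6 under the defaults).

What passing tests on this generator do **not** show: robustness to stain
variation, nucleus-level morphology, imperfect region-level annotations,
spatial gene–gene correlation beyond the shared latent state, or
transfer across imaging platforms. The generator exists to verify the
pipeline's mechanics and the direction of its design claims, not to
estimate tissue-scale performance.

## Measured behavior at desk scale

With the default simulator (3 patients, 16 × 16 grids, 32 px patches, 50
genes / 10 coupled) and 10 training epochs, held-out coupled-gene aPCC is
0.63–0.69 across seeds, decoy aPCC is within ±0.05 of zero, and tumor AUC
is ≈ 1.0. Comparing the full multi-task + spatial model against the
primary-task-only baseline over five independent replicates (each seed
regenerates the cohort and seeds the training) gives a mean aPCC
difference of about −0.01 with per-replicate spread of ±0.04: at this
scale the auxiliary tasks neither help nor hurt measurably, and the test
suite asserts only that the full model does not trail the baseline by more
than 0.02. Detecting the small positive effect reported on real tissue
cohorts would require far more data than a desk-scale run provides.

## Numerical and degenerate-input choices

* Probabilities clamped to [1e-7, 1 − 1e-7] in the cross-entropy; labels
  must be exactly 0/1.
* Spatial loss returns 0.0 when no same-annotation pair exists; it raises
  when any batch spot lacks an annotation while γ > 0.
* Zero-variance genes get Pearson correlation 0 (logged), keeping aPCC and
  NGPC denominators fixed.
* Zero-total spots make normalization raise with a pointer to run spot QC
  first; a channel with zero standard deviation makes patch normalization
  raise rather than divide by zero.
* All randomness flows through seeded `numpy.random.Generator` instances;
  cohort seeds spawn per-patient generators via `SeedSequence`.

## Known limitations

* The numpy backbone is deliberately small; it is not a path to
  tissue-scale accuracy, and no pretrained encoder is bundled.
* Pyramidal slide formats, stain deconvolution and serial-section
  registration are out of scope; images are plain 8-bit RGB.
* Batch-effect correction across patients, doublet detection and spot
  deconvolution are not implemented; the per-patient random effect in the
  simulator is the only batch structure modeled.
* Annotations are binary tumor/normal; multi-class pathological labels
  would require widening the classification head and the spatial-loss
  weight definition.
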