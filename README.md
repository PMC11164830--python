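# he2st

Multi-task prediction of **spot-level gene expression and tumor annotation
from H&E histology patches**, for sequencing-based spatial transcriptomics
(ST / Visium-style data).

ST assays measure an N × M counts matrix over N grid-arranged capture spots,
each paired with a patch of the H&E-stained whole-slide image, and often
with a pathologist's tumor/normal annotation per spot. Because the assay is
expensive while H&E imaging is routine, a model that predicts expression and
annotation directly from the image is a practical surrogate — and a probe of
how much transcriptional state is visible in morphology. This package is for
computational biologists who want a complete, testable implementation of
that pipeline: preprocessing, the multi-task model, evaluation, and a
synthetic paired-data simulator so everything runs offline at desk scale.

## Model

One shared convolutional encoder maps each normalized spot patch to an
embedding, from which three linear heads predict:

1. the *m* **target genes** (the most highly expressed; primary task),
2. the remaining *M − m* **non-target genes** (auxiliary task),
3. the probability the spot is **tumor** (auxiliary task).

With ĝ the predicted and g the true (log-library-size-normalized)
expression and ŷ the tumor probability, the training objective is

```
L = L_prim + λ·L_aux + β·L_tmr + γ·L_spat

L_prim = 1/(mN)   Σ_i Σ_{j≤m}  (g_ij − ĝ_ij)²
L_aux  = 1/((M−m)N) Σ_i Σ_{j>m} (g_ij − ĝ_ij)²
L_tmr  = −1/N Σ_i [ y_i ln ŷ_i + (1−y_i) ln(1−ŷ_i) ]
L_spat = 1/K Σ_(i,j) w_ij · mean_g (ĝ_i − ĝ_j)² ,  w_ij = 1{y_i = y_j}
```

where the spatial sum runs over (central spot, grid neighbor) pairs in the
3 × 3 array-grid window and K is the number of same-annotation pairs: spots
that are adjacent *and* share a pathological annotation are pushed toward
similar predicted expression.

Preprocessing follows ST conventions: boundary exclusion of spots whose
patch window exits the slide; spot QC on library size (200–20 000 UMIs),
mitochondrial fraction (≤5%) and detected genes (≥200); gene QC (detected
in ≥3 spots); log CPM-style normalization `ln(1 + 10⁴·c/total)`; patch
standardization `((raw/255) − mean)/std` with training-split channel
statistics. Evaluation reports aMSE, aPCC (mean per-gene Pearson
correlation), NGPC (genes with positive correlation), and ACC/AUC/AUPRC for
the tumor head, always on held-out *patients*.

## Worked example

Simulate a 3-patient cohort (16 × 16 spot grids, 32 px patches, 50 genes of
which 10 are coupled to the latent tumor state), train 10 epochs with all
loss terms, and evaluate on the held-out patient:

```python
import numpy as np
import he2st as H
from he2st.simulate import COUPLED_PREFIX

cfg = H.SimConfig(seed=0)                      # 16x16 grid, 50 genes, 10 coupled
samples = H.simulate_cohort(cfg, n_patients=3, sections_per_patient=1)
prepared = H.prepare_cohort(samples, H.desk_scale_thresholds(),
                            window_px=32, out_size_px=32)
split = H.SplitSpec(["P01"], ["P02"], ["P03"])
ckpt, history = H.train(prepared, split, H.LossWeights(1.0, 1.0, 1.0),
                        H.TrainConfig(epochs=10, m=20, seed=0))
test = [p for p in prepared if p.patient_id in split.test_patients]
report = H.evaluate(ckpt, test)

targets = ckpt.gene_names[ckpt.partition.target_idx].astype(str)
coupled = np.char.startswith(targets, COUPLED_PREFIX)
print(f"held-out aMSE (target genes): {report.amse_target:.3f}")
print(f"held-out aPCC (target genes): {report.apcc_target:.3f}")
print(f"  coupled genes: {report.per_gene_pcc[coupled].mean():.3f}")
print(f"  decoy genes:   {report.per_gene_pcc[~coupled].mean():.3f}")
print(f"NGPC: {report.ngpc} / {ckpt.partition.m}")
print(f"tumor ACC {report.acc:.3f}  AUC {report.auc:.3f}  AUPRC {report.auprc:.3f}")
```

Output:

```
held-out aMSE (target genes): 1.834
held-out aPCC (target genes): 0.341
  coupled genes: 0.687
  decoy genes:   -0.006
NGPC: 13 / 20
tumor ACC 0.992  AUC 1.000  AUPRC 0.999
```

The image-coupled genes are recovered with strong positive correlation on a
patient never seen in training, the decoy (noise-only) genes sit at zero —
the model does not hallucinate signal — and the tumor head separates the
annotated regions essentially perfectly.

The same workflow is available from the shell:

```sh
he2st simulate --out-dir cohort --n-patients 3
he2st train    --data-dir cohort --out-dir run --m 20 \
               --min-umi 50 --min-genes 10 --window 32 --out-size 32
he2st evaluate --checkpoint run/checkpoint.npz --data-dir cohort \
               --out eval_report.json --min-umi 50 --min-genes 10 \
               --window 32 --out-size 32
he2st predict  --checkpoint run/checkpoint.npz \
               --image cohort/P03_s1/image.png \
               --spots cohort/P03_s1/spots.tsv --out predictions.tsv
```

`he2st ablate` runs the loss-term ablation grid (untrained baseline,
primary-only, each auxiliary term in isolation, full model with and without
the spatial constraint) and writes a TSV, one row per variant and seed.

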