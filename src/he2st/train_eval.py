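"""Training loop, patient-level splits, evaluation metrics, ablation runner.

Evaluation follows the standard metric set for image-to-expression models:
aMSE (mean squared error over spots and genes), aPCC (mean of per-gene
Pearson correlations across spots), NGPC (number of genes with positive
correlation), plus ACC/AUC/AUPRC for the tumor-annotation head.  Splits are
always at the patient level: no spot from a validation or test patient ever
contributes to training, channel statistics, or the gene partition.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import model as M
from .exceptions import ConfigError, EmptySampleError
from .preprocess import (
    GenePartition,
    NeighborGraph,
    QCThresholds,
    build_neighbor_graph,
    merge_neighbor_graphs,
    normalize_expression,
    partition_genes,
    qc_filter_spots,
    qc_report,
)
from .st_data import (
    ExpressionMatrix,
    PatchSet,
    STSample,
    channel_stats,
    extract_patches,
    normalize_patches,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    """Disjoint patient-level train/validation/test assignment."""

    train_patients: list
    val_patients: list
    test_patients: list
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train_patients), set(self.val_patients), set(self.test_patients)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("a patient may appear in only one of train/val/test")
        if not self.train_patients:
            raise ValueError("training patient list must be non-empty")


def random_split(patient_ids: Sequence[str], n_val: int = 1, n_test: int = 1, seed: int = 0) -> SplitSpec:
    """Randomly assign whole patients to train/val/test."""
    ids = sorted(set(patient_ids))
    if len(ids) < n_val + n_test + 1:
        raise ValueError("not enough patients for the requested split")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(ids))
    return SplitSpec(perm[n_val + n_test :], perm[:n_val], perm[n_val : n_val + n_test], seed)


# ---------------------------------------------------------------------------
# Preparation: QC + normalization + patches + graph, per sample
# ---------------------------------------------------------------------------


@dataclass
class PreparedSample:
    """A QC-filtered sample ready for training: aligned arrays per spot."""

    sample_id: str
    patient_id: str
    spot_ids: np.ndarray
    patches_raw: np.ndarray  # N x S x S x 3, 0..255 floats
    expr: np.ndarray  # N x M normalized expression
    gene_names: np.ndarray
    annotations: np.ndarray  # float; NaN = unannotated
    graph: NeighborGraph
    qc: pd.DataFrame

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


def _prepare_one(
    sample: STSample,
    thresholds: QCThresholds,
    window_px: int,
    out_size_px: int,
) -> tuple[STSample, np.ndarray, pd.DataFrame, np.ndarray]:
    """Boundary exclusion + spot QC for one sample; returns the retained
    subsample, its raw patches, the QC report, and the per-gene detection
    count among retained spots."""
    patches, boundary_excluded = extract_patches(sample, window_px, out_size_px)
    keep = qc_filter_spots(sample, thresholds, boundary_excluded)
    report = qc_report(sample, thresholds, boundary_excluded)
    if not keep.any():
        raise EmptySampleError(f"sample {sample.sample_id}: no spots survive QC")
    sub = sample.subset_spots(keep)
    patch_keep = keep[~boundary_excluded]
    patches = patches.subset(patch_keep)
    detected = (np.asarray(sub.expression.values) > 0).sum(axis=0)
    return sub, patches.patches, report, detected


def prepare_cohort(
    samples: list[STSample],
    thresholds: Optional[QCThresholds] = None,
    window_px: int = 150,
    out_size_px: int = 224,
) -> list[PreparedSample]:
    """Run boundary exclusion, spot QC, cohort-level gene QC, and
    normalization over a list of samples sharing one gene set."""
    thresholds = thresholds or QCThresholds()
    genes = samples[0].expression.gene_names
    for s in samples[1:]:
        if not np.array_equal(s.expression.gene_names, genes):
            raise ValueError("all samples in a cohort must share one gene list")
    subs, patch_arrays, reports, detected = [], [], [], np.zeros(len(genes), int)
    for s in samples:
        sub, patches, report, det = _prepare_one(s, thresholds, window_px, out_size_px)
        subs.append(sub)
        patch_arrays.append(patches)
        reports.append(report)
        detected += det
    gene_mask = detected >= thresholds.min_spots_per_gene
    if not gene_mask.any():
        raise EmptySampleError("no genes survive the detection filter")
    prepared = []
    for sub, patches, report in zip(subs, patch_arrays, reports):
        expr = normalize_expression(sub.expression.subset_genes(gene_mask))
        prepared.append(
            PreparedSample(
                sub.sample_id,
                sub.patient_id,
                sub.spots.spot_ids,
                patches,
                np.asarray(expr.values, float),
                expr.gene_names,
                sub.spots.annotation,
                build_neighbor_graph(sub.spots),
                report,
            )
        )
    return prepared


def prepare_sample(
    sample: STSample,
    thresholds: Optional[QCThresholds] = None,
    window_px: int = 150,
    out_size_px: int = 224,
) -> PreparedSample:
    """Single-sample variant of :func:`prepare_cohort` (gene QC within sample)."""
    return prepare_cohort([sample], thresholds, window_px, out_size_px)[0]


def _select(prepared: list[PreparedSample], patients: Sequence[str]) -> list[PreparedSample]:
    sel = [p for p in prepared if p.patient_id in set(patients)]
    return sel


def _stack(
    prepared: list[PreparedSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, NeighborGraph, np.ndarray]:
    """Concatenate spots across samples: patches, expr, labels, merged graph, ids."""
    patches = np.concatenate([p.patches_raw for p in prepared], axis=0)
    expr = np.concatenate([p.expr for p in prepared], axis=0)
    labels = np.concatenate([p.annotations for p in prepared])
    graph = merge_neighbor_graphs([p.graph for p in prepared])
    ids = np.concatenate([p.spot_ids for p in prepared])
    return patches, expr, labels, graph, ids


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def per_gene_pcc(g_true: np.ndarray, g_hat: np.ndarray) -> np.ndarray:
    """Pearson correlation per gene (column) across spots (rows).

    Genes with zero variance in either argument are assigned correlation 0
    (logged) so averages keep a fixed denominator.
    """
    g_true = np.asarray(g_true, float)
    g_hat = np.asarray(g_hat, float)
    if g_true.shape != g_hat.shape:
        raise ValueError("shape mismatch")
    if g_true.shape[0] < 2:
        raise ValueError("need at least 2 spots for a correlation")
    t = g_true - g_true.mean(axis=0)
    h = g_hat - g_hat.mean(axis=0)
    st = np.sqrt((t**2).sum(axis=0))
    sh = np.sqrt((h**2).sum(axis=0))
    degenerate = (st == 0) | (sh == 0)
    if degenerate.any():
        logger.info("%d gene(s) with zero variance assigned PCC 0", int(degenerate.sum()))
    denom = np.where(degenerate, 1.0, st * sh)
    pcc = np.where(degenerate, 0.0, (t * h).sum(axis=0) / denom)
    return np.clip(pcc, -1.0, 1.0)


@dataclass
class EvalReport:
    """Metric bundle for one evaluation run (gene sets reported separately)."""

    amse_target: float
    apcc_target: float
    ngpc: int
    per_gene_pcc: np.ndarray
    amse_nontarget: Optional[float] = None
    apcc_nontarget: Optional[float] = None
    acc: Optional[float] = None
    auc: Optional[float] = None
    auprc: Optional[float] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_gene_pcc"] = np.asarray(self.per_gene_pcc).tolist()
        return d


def evaluate_arrays(
    g_true_target: np.ndarray,
    g_hat_target: np.ndarray,
    g_true_nontarget: Optional[np.ndarray] = None,
    g_hat_nontarget: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
    probs: Optional[np.ndarray] = None,
) -> EvalReport:
    """Compute the metric set from prediction arrays.

    aMSE uses the same mean-over-spots-and-genes reduction as the training
    losses; aPCC averages :func:`per_gene_pcc`; NGPC counts target genes with
    strictly positive correlation.  Annotation metrics are skipped (None,
    with a warning) when labels are absent or single-class.
    """
    pcc = per_gene_pcc(g_true_target, g_hat_target)
    rep = EvalReport(
        amse_target=float(np.mean((g_true_target - g_hat_target) ** 2)),
        apcc_target=float(pcc.mean()),
        ngpc=int((pcc > 0).sum()),
        per_gene_pcc=pcc,
    )
    if g_true_nontarget is not None and g_true_nontarget.shape[1] > 0:
        npcc = per_gene_pcc(g_true_nontarget, g_hat_nontarget)
        rep.amse_nontarget = float(np.mean((g_true_nontarget - g_hat_nontarget) ** 2))
        rep.apcc_nontarget = float(npcc.mean())
    if labels is not None and probs is not None:
        ok = ~np.isnan(np.asarray(labels, float))
        y = np.asarray(labels, float)[ok]
        p = np.asarray(probs, float)[ok]
        if len(y) > 0:
            rep.acc = float(np.mean((p >= 0.5) == (y == 1.0)))
            if len(np.unique(y)) < 2:
                warnings.warn("single-class annotation set: AUC/AUPRC undefined")
            else:
                rep.auc = float(roc_auc_score(y, p))
                rep.auprc = float(average_precision_score(y, p))
    return rep


# ---------------------------------------------------------------------------
# Checkpoint bundle
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    """Trained model plus everything needed to reproduce its preprocessing."""

    model: M.TinyCNN
    partition: GenePartition
    gene_names: np.ndarray
    channel_mean: np.ndarray
    channel_std: np.ndarray
    weights: M.LossWeights
    window_px: int = 150
    out_size_px: int = 224

    def save(self, path: Path) -> Path:
        meta = {
            "target_idx": self.partition.target_idx,
            "nontarget_idx": self.partition.nontarget_idx,
            "m": self.partition.m,
            "gene_names": self.gene_names,
            "channel_mean": self.channel_mean,
            "channel_std": self.channel_std,
            "loss_weights": dataclasses.asdict(self.weights),
            "window_px": self.window_px,
            "out_size_px": self.out_size_px,
        }
        return M.save_checkpoint(Path(path), self.model, meta)

    @classmethod
    def load(cls, path: Path) -> "Checkpoint":
        net, meta = M.load_checkpoint(Path(path))
        return cls(
            model=net,
            partition=GenePartition(
                np.asarray(meta["target_idx"], int),
                np.asarray(meta["nontarget_idx"], int),
                int(meta["m"]),
            ),
            gene_names=np.asarray(meta["gene_names"], dtype=object).astype(str),
            channel_mean=np.asarray(meta["channel_mean"], float),
            channel_std=np.asarray(meta["channel_std"], float),
            weights=M.LossWeights(**meta["loss_weights"]),
            window_px=int(meta["window_px"]),
            out_size_px=int(meta["out_size_px"]),
        )


def _normalize_raw_patches(
    patches_raw: np.ndarray, mean: np.ndarray, std: np.ndarray
) -> np.ndarray:
    side = patches_raw.shape[1]
    ps = PatchSet(patches_raw, np.arange(len(patches_raw)).astype(str), side, side)
    return normalize_patches(ps, mean, std).patches


def predict_batched(model: M.TinyCNN, patches_norm: np.ndarray, batch_size: int = 256):
    """Forward a (possibly large) patch stack in evaluation mode."""
    outs_t, outs_n, outs_y = [], [], []
    for i in range(0, len(patches_norm), batch_size):
        pred = model.forward(patches_norm[i : i + batch_size])
        outs_t.append(pred.g_hat_target)
        outs_n.append(pred.g_hat_nontarget)
        outs_y.append(pred.y_hat)
    return (
        np.concatenate(outs_t, axis=0),
        np.concatenate(outs_n, axis=0),
        np.concatenate(outs_y, axis=0),
    )


def evaluate(checkpoint: Checkpoint, prepared: list[PreparedSample]) -> EvalReport:
    """Evaluate a checkpoint on held-out prepared samples."""
    patches, expr, labels, _, _ = _stack(prepared)
    x = _normalize_raw_patches(patches, checkpoint.channel_mean, checkpoint.channel_std)
    g_t, g_n, probs = predict_batched(checkpoint.model, x)
    part = checkpoint.partition
    return evaluate_arrays(
        expr[:, part.target_idx],
        g_t,
        expr[:, part.nontarget_idx] if len(part.nontarget_idx) else None,
        g_n if len(part.nontarget_idx) else None,
        labels,
        probs,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    epochs: int = 10
    batch_size: int = 64
    lr: float = 3e-3
    seed: int = 0
    augment: bool = False  # random flips / 90-degree rotations
    patience: Optional[int] = None  # early stop on stalled validation aPCC
    m: int = 250  # target-gene count for the partition


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if rng.random() < 0.5:
        x = x[:, ::-1, :, :]
    if rng.random() < 0.5:
        x = x[:, :, ::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        x = np.rot90(x, k, axes=(1, 2))
    return np.ascontiguousarray(x)


def train(
    prepared: list[PreparedSample],
    split: SplitSpec,
    weights: M.LossWeights,
    train_config: TrainConfig,
    model_config: Optional[M.ModelConfig] = None,
    init: str = "random",
    warm_start: Optional[Checkpoint] = None,
) -> tuple[Checkpoint, pd.DataFrame]:
    """Fit the multi-task objective by mini-batch Adam.

    The gene partition and patch channel statistics are computed on the
    training patients only and frozen into the returned checkpoint.  The
    per-epoch history records each loss component and the validation aPCC
    on target genes, which also drives model selection (best epoch kept)
    and optional early stopping.

    ``init``: "random" (fresh weights), or "warm-start" with a compatible
    ``warm_start`` checkpoint ("no-train" evaluation is warm-start with
    epochs = 0; fine-tuning is warm-start with epochs > 0).
    """
    train_set = _select(prepared, split.train_patients)
    if not train_set:
        raise ValueError("empty training split")
    val_set = _select(prepared, split.val_patients)

    patches, expr, labels, graph, _ = _stack(train_set)
    n_train = len(patches)
    gene_names = train_set[0].gene_names

    if weights.gamma_spat > 0 and np.isnan(labels).any():
        raise ValueError("gamma_spat > 0 requires an annotation for every training spot")

    # train-split-only statistics, frozen with the model
    ps = PatchSet(patches, np.arange(n_train).astype(str), patches.shape[1], patches.shape[1])
    ch_mean, ch_std = channel_stats(ps)
    x_all = _normalize_raw_patches(patches, ch_mean, ch_std)
    train_expr_m = ExpressionMatrix(expr, gene_names, np.arange(n_train).astype(str), "normalized")
    m = min(train_config.m, len(gene_names))
    partition = partition_genes(train_expr_m, m=m)

    if model_config is None:
        model_config = M.ModelConfig(
            m=m, n_nontarget=len(partition.nontarget_idx), patch_px=patches.shape[1]
        )
    if model_config.m != m or model_config.n_nontarget != len(partition.nontarget_idx):
        raise ConfigError(
            f"model config (m={model_config.m}, n_nontarget={model_config.n_nontarget}) "
            f"does not match the partition (m={m}, n_nontarget={len(partition.nontarget_idx)})"
        )

    if init == "warm-start":
        if warm_start is None:
            raise ConfigError("init='warm-start' requires a checkpoint")
        if warm_start.partition.m != m:
            raise ConfigError(
                f"warm-start checkpoint has m={warm_start.partition.m}, run requests m={m}"
            )
        net = M.build_model(model_config, seed=train_config.seed)
        net.load_state_dict(warm_start.model.state_dict())
        # keep the checkpoint's frozen preprocessing statistics and partition
        ch_mean, ch_std = warm_start.channel_mean, warm_start.channel_std
        partition = warm_start.partition
        x_all = _normalize_raw_patches(patches, ch_mean, ch_std)
    elif init == "random":
        net = M.build_model(model_config, seed=train_config.seed)
        # start the regression heads at the training-set per-gene means so
        # early epochs fit structure rather than the global offset
        net.params["head_t_b"] = expr[:, partition.target_idx].mean(axis=0).astype(np.float32)
        if model_config.n_nontarget > 0:
            net.params["head_n_b"] = (
                expr[:, partition.nontarget_idx].mean(axis=0).astype(np.float32)
            )
    else:
        raise ConfigError(
            f"unknown init mode {init!r}; supported: 'random', 'warm-start' "
            "(pretrained ImageNet backbones are not bundled)"
        )

    y_t_all = expr[:, partition.target_idx]
    y_n_all = expr[:, partition.nontarget_idx]
    labeled = ~np.isnan(labels)

    opt = M.Adam(net.params, lr=train_config.lr)
    rng = np.random.default_rng(train_config.seed)
    history_rows = []
    best = {"apcc": -np.inf, "state": net.state_dict(), "epoch": -1}
    stall = 0

    val_ready = len(val_set) > 0
    if val_ready:
        val_patches, val_expr, _, _, _ = _stack(val_set)
        xv = _normalize_raw_patches(val_patches, ch_mean, ch_std)

    for epoch in range(train_config.epochs):
        order = rng.permutation(n_train)
        sums = {"primary": 0.0, "auxiliary": 0.0, "tumor": 0.0, "spatial": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n_train, train_config.batch_size):
            central = order[start : start + train_config.batch_size]
            if weights.gamma_spat > 0:
                # neighborhood batching: include grid neighbors so the
                # spatial term has same-annotation pairs to act on
                nbrs = np.concatenate([graph.neighbors[i] for i in central]) if len(central) else central
                batch = np.unique(np.concatenate([central, nbrs]))
            else:
                batch = central
            x = x_all[batch]
            if train_config.augment:
                x = _augment_batch(x, rng)
            pred = net.forward(x, cache=True)
            g_t, g_n, probs = pred.g_hat_target, pred.g_hat_nontarget, pred.y_hat

            comp = {"auxiliary": 0.0, "tumor": 0.0, "spatial": 0.0}
            comp["primary"] = M.loss_primary(y_t_all[batch], g_t)
            d_t = M.loss_primary_grad(y_t_all[batch], g_t)
            d_n = np.zeros_like(g_n)
            d_p = np.zeros_like(probs)
            if weights.lambda_aux > 0 and g_n.shape[1] > 0:
                comp["auxiliary"] = M.loss_auxiliary(y_n_all[batch], g_n)
                d_n = weights.lambda_aux * M.loss_auxiliary_grad(y_n_all[batch], g_n)
            if weights.beta_tmr > 0:
                lb = labeled[batch]
                if lb.any():
                    comp["tumor"] = M.loss_tumor(labels[batch][lb], probs[lb])
                    d_p[lb] = weights.beta_tmr * M.loss_tumor_grad(labels[batch][lb], probs[lb])
            if weights.gamma_spat > 0:
                comp["spatial"] = M.loss_spatial(
                    g_t, labels[batch], graph, batch, model_config.spatial_reduction
                )
                d_t = d_t + weights.gamma_spat * M.loss_spatial_grad(
                    g_t, labels[batch], graph, batch, model_config.spatial_reduction
                )
            total = M.loss_total(comp, weights)
            grads = net.backward(d_t, d_n, d_p)
            opt.step(net.params, grads)
            for k in ("primary", "auxiliary", "tumor", "spatial"):
                sums[k] += comp[k]
            sums["total"] += total
            n_batches += 1

        row = {"epoch": epoch, **{f"loss_{k}": v / n_batches for k, v in sums.items()}}
        if val_ready:
            vg_t, _, _ = predict_batched(net, xv)
            val_apcc = float(per_gene_pcc(val_expr[:, partition.target_idx], vg_t).mean())
            row["val_apcc_target"] = val_apcc
            if val_apcc > best["apcc"]:
                best = {"apcc": val_apcc, "state": net.state_dict(), "epoch": epoch}
                stall = 0
            else:
                stall += 1
                if train_config.patience is not None and stall >= train_config.patience:
                    history_rows.append(row)
                    logger.info("early stop at epoch %d", epoch)
                    break
        history_rows.append(row)

    if val_ready and best["epoch"] >= 0:
        net.load_state_dict(best["state"])

    checkpoint = Checkpoint(
        model=net,
        partition=partition,
        gene_names=gene_names,
        channel_mean=np.asarray(ch_mean, float),
        channel_std=np.asarray(ch_std, float),
        weights=weights,
        window_px=prepared[0].patches_raw.shape[1],
        out_size_px=prepared[0].patches_raw.shape[1],
    )
    history = pd.DataFrame(history_rows)
    return checkpoint, history


# ---------------------------------------------------------------------------
# Ablation runner
# ---------------------------------------------------------------------------

# variant name -> (lambda on, beta on, gamma on); None = untrained
ABLATION_VARIANTS = {
    "Random": None,
    "Baseline (Prim)": (0, 0, 0),
    "W/Aux": (1, 0, 0),
    "W/Tmr": (0, 1, 0),
    "W/Spat": (0, 0, 1),
    "MultiTask-Base": (1, 1, 0),
    "MultiTask-Spat": (1, 1, 1),
}


def run_ablation(
    prepared: list[PreparedSample],
    split: SplitSpec,
    train_config: TrainConfig,
    base_weights: M.LossWeights = None,
    variants: Optional[Sequence[str]] = None,
    seeds: Sequence[int] = (0,),
    out_path: Optional[Path] = None,
) -> pd.DataFrame:
    """Train/evaluate each loss-term toggle pattern; one row per (variant, seed).

    The variant set mirrors the standard ablation layout: an untrained
    Random baseline, the primary task alone, each auxiliary term added in
    isolation, and the full multi-task model with and without the spatial
    constraint.
    """
    base_weights = base_weights or M.LossWeights(1.0, 1.0, 1.0)
    names = list(variants) if variants is not None else list(ABLATION_VARIANTS)
    test_set = _select(prepared, split.test_patients)
    rows = []
    for seed in seeds:
        tc = dataclasses.replace(train_config, seed=int(seed))
        for name in names:
            toggles = ABLATION_VARIANTS[name]
            if toggles is None:
                ckpt, _ = train(
                    prepared, split, M.LossWeights(0, 0, 0),
                    dataclasses.replace(tc, epochs=0),
                )
            else:
                w = M.LossWeights(
                    base_weights.lambda_aux * toggles[0],
                    base_weights.beta_tmr * toggles[1],
                    base_weights.gamma_spat * toggles[2],
                )
                ckpt, _ = train(prepared, split, w, tc)
            rep = evaluate(ckpt, test_set)
            rows.append(
                {
                    "variant": name,
                    "seed": int(seed),
                    "amse_target": rep.amse_target,
                    "apcc_target": rep.apcc_target,
                    "ngpc": rep.ngpc,
                    "amse_nontarget": rep.amse_nontarget,
                    "apcc_nontarget": rep.apcc_nontarget,
                    "acc": rep.acc,
                    "auc": rep.auc,
                }
            )
    table = pd.DataFrame(rows)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path, sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# Differential gene ranking
# ---------------------------------------------------------------------------


def differential_gene_ranking(
    expr: np.ndarray,
    gene_names: Sequence[str],
    annotations: np.ndarray,
    k: int = 5,
) -> pd.DataFrame:
    """Rank genes by |mean(tumor) - mean(normal)| of (normalized) expression.

    Returns the top-k genes with their signed mean differences, descending by
    absolute difference with lexicographic tie-breaking.
    """
    expr = np.asarray(expr, float)
    annotations = np.asarray(annotations, float)
    ok = ~np.isnan(annotations)
    y = annotations[ok]
    x = expr[ok]
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both tumor and normal spots are required")
    tumor_mean = x[y == 1].mean(axis=0)
    normal_mean = x[y == 0].mean(axis=0)
    diff = tumor_mean - normal_mean
    names = np.asarray(gene_names, dtype=object).astype(str)
    order = sorted(range(len(names)), key=lambda j: (-abs(diff[j]), names[j]))[:k]
    return pd.DataFrame(
        {
            "gene": names[order],
            "tumor_mean": tumor_mean[order],
            "normal_mean": normal_mean[order],
            "mean_difference": diff[order],
        }
    ).reset_index(drop=True)
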