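"""Quality control, expression normalization, gene partitioning, neighbor graph.

QC follows the usual spot/gene filtering conventions for sequencing-based
spatial transcriptomics: spots are dropped when their library size falls
outside [min_umi, max_umi], when more than ``max_mito_frac`` of counts map to
mitochondrial genes (recognized by name prefix), or when fewer than
``min_genes_per_spot`` genes are detected; genes detected in fewer than
``min_spots_per_gene`` spots are dropped afterwards.  Expression is then
library-size normalized to ``scale`` counts per spot and log-transformed
with a pseudocount (natural log).

The gene partition splits the retained genes into the m most highly
expressed "target" genes (the primary regression task) and the remaining
"non-target" genes (the auxiliary task).  The neighbor graph connects each
spot to its <= 8 neighbors in the 3 x 3 array-grid window; it feeds the
spatial smoothness loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .st_data import ExpressionMatrix, STSample, SpotTable

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Spot- and gene-level quality-control thresholds.

    Bounds are inclusive: "fewer than 200 UMIs" and "more than 20000 UMIs"
    are strict exclusions, so a spot with exactly 200 or 20000 is retained.
    """

    min_umi: int = 200
    max_umi: int = 20_000
    max_mito_frac: float = 0.05
    min_genes_per_spot: int = 200
    min_spots_per_gene: int = 3
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must lie in [0, 1]")


@dataclass
class GenePartition:
    """Index split of the retained genes into target and non-target sets."""

    target_idx: np.ndarray
    nontarget_idx: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.target_idx = np.asarray(self.target_idx, dtype=int)
        self.nontarget_idx = np.asarray(self.nontarget_idx, dtype=int)
        if len(self.target_idx) != self.m:
            raise ValueError("len(target_idx) must equal m")
        both = np.concatenate([self.target_idx, self.nontarget_idx])
        if len(set(both.tolist())) != len(both):
            raise ValueError("target and non-target indices must be disjoint")

    @property
    def n_genes(self) -> int:
        return len(self.target_idx) + len(self.nontarget_idx)


@dataclass
class NeighborGraph:
    """For each spot, the indices of its <= 8 grid neighbors (3x3 window)."""

    neighbors: list

    @property
    def n_spots(self) -> int:
        return len(self.neighbors)

    def directed_pairs(self) -> np.ndarray:
        """All (central, neighbor) index pairs as a P x 2 array."""
        pairs = [
            (i, j) for i, nbrs in enumerate(self.neighbors) for j in nbrs
        ]
        return np.asarray(pairs, dtype=int).reshape(-1, 2)

    def degree(self) -> np.ndarray:
        return np.asarray([len(n) for n in self.neighbors], dtype=int)


# ---------------------------------------------------------------------------
# Spot QC
# ---------------------------------------------------------------------------


def spot_qc_stats(expr: ExpressionMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-spot totals, mitochondrial fraction, and detected-gene counts."""
    if expr.layer_tag != "raw_counts":
        raise ValueError("spot QC requires the raw-count layer")
    counts = np.asarray(expr.values, dtype=float)
    totals = counts.sum(axis=1)
    is_mito = np.char.startswith(expr.gene_names.astype(str), mito_prefix)
    mito_counts = counts[:, is_mito].sum(axis=1) if is_mito.any() else np.zeros(len(totals))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    detected = (counts > 0).sum(axis=1)
    return pd.DataFrame(
        {
            "spot_id": expr.spot_ids,
            "total_umi": totals,
            "mito_frac": mito_frac,
            "n_genes_detected": detected,
        }
    )


def qc_filter_spots(
    sample: STSample,
    thresholds: QCThresholds,
    boundary_excluded: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean keep-mask over spots.

    A spot is kept iff its total UMIs lie in [min_umi, max_umi], its
    mitochondrial fraction is <= max_mito_frac, it detects at least
    ``min_genes_per_spot`` genes, and it was not excluded by the image
    boundary check.
    """
    stats = spot_qc_stats(sample.expression, thresholds.mito_prefix)
    keep = (
        (stats["total_umi"] >= thresholds.min_umi)
        & (stats["total_umi"] <= thresholds.max_umi)
        & (stats["mito_frac"] <= thresholds.max_mito_frac)
        & (stats["n_genes_detected"] >= thresholds.min_genes_per_spot)
    ).to_numpy()
    if boundary_excluded is not None:
        keep &= ~np.asarray(boundary_excluded, bool)
    if not keep.any():
        logger.warning("sample %s: spot QC removed all %d spots", sample.sample_id, len(keep))
    return keep


def qc_report(
    sample: STSample,
    thresholds: QCThresholds,
    boundary_excluded: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-spot QC table with pass/fail flags for each criterion."""
    stats = spot_qc_stats(sample.expression, thresholds.mito_prefix)
    stats["fail_low_umi"] = stats["total_umi"] < thresholds.min_umi
    stats["fail_high_umi"] = stats["total_umi"] > thresholds.max_umi
    stats["fail_mito"] = stats["mito_frac"] > thresholds.max_mito_frac
    stats["fail_detected"] = stats["n_genes_detected"] < thresholds.min_genes_per_spot
    stats["fail_boundary"] = (
        np.asarray(boundary_excluded, bool)
        if boundary_excluded is not None
        else np.zeros(len(stats), bool)
    )
    fail_cols = [c for c in stats.columns if c.startswith("fail_")]
    stats["passed"] = ~stats[fail_cols].any(axis=1)
    return stats


def qc_filter_genes(expr: ExpressionMatrix, thresholds: QCThresholds) -> np.ndarray:
    """Keep genes detected (count > 0) in at least ``min_spots_per_gene`` spots."""
    if expr.layer_tag != "raw_counts":
        raise ValueError("gene QC requires the raw-count layer")
    detected_in = (np.asarray(expr.values) > 0).sum(axis=0)
    return detected_in >= thresholds.min_spots_per_gene


# ---------------------------------------------------------------------------
# Expression normalization
# ---------------------------------------------------------------------------


def normalize_expression(
    counts: ExpressionMatrix, scale: float = 10_000.0, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Library-size normalize and log-transform: ln(pc + scale * c_ij / total_i)."""
    values = np.asarray(counts.values, dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.spot_ids[totals <= 0].tolist()
        raise ValueError(
            f"spots with zero total counts: {bad}; run spot QC before normalization"
        )
    out = np.log(pseudocount + scale * values / totals[:, None])
    return ExpressionMatrix(out, counts.gene_names, counts.spot_ids, "normalized")


def denormalize_expression(
    normalized: ExpressionMatrix, scale: float = 10_000.0, pseudocount: float = 1.0
) -> np.ndarray:
    """Invert :func:`normalize_expression` up to per-spot totals.

    Returns ``counts / total`` per spot (the library-size-free profile); the
    absolute counts are not recoverable without the stored totals.
    """
    return (np.exp(np.asarray(normalized.values, float)) - pseudocount) / scale


# ---------------------------------------------------------------------------
# Gene partition
# ---------------------------------------------------------------------------


def partition_genes(expr_train: ExpressionMatrix, m: int = 250) -> GenePartition:
    """Select the m genes with the highest mean expression as the target set.

    Means are taken over *training* spots on the matrix passed in (normalized
    by default in the pipeline; the caller controls the layer).  Ties are
    broken by gene-name lexicographic order so the partition is deterministic.
    """
    M = expr_train.n_genes
    if m > M:
        raise ValueError(f"m={m} exceeds the number of genes M={M}")
    means = np.asarray(expr_train.values, float).mean(axis=0)
    names = expr_train.gene_names
    order = sorted(range(M), key=lambda j: (-means[j], names[j]))
    target = np.asarray(sorted(order[:m]), dtype=int)
    nontarget = np.asarray(sorted(order[m:]), dtype=int)
    return GenePartition(target, nontarget, m)


# ---------------------------------------------------------------------------
# Neighbor graph
# ---------------------------------------------------------------------------


def build_neighbor_graph(spots: SpotTable) -> NeighborGraph:
    """Connect each spot to the <= 8 spots in its 3x3 array-grid window.

    Missing grid positions simply yield fewer neighbors; the graph is
    symmetric and self-edge free by construction.
    """
    rc = spots.array_rc
    index = {}
    for i, (r, c) in enumerate(map(tuple, rc)):
        if (r, c) in index:
            raise ValueError(f"duplicate array coordinates {(r, c)}")
        index[(r, c)] = i
    neighbors = []
    for r, c in map(tuple, rc):
        nbrs = [
            index[(r + dr, c + dc)]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in index
        ]
        neighbors.append(np.asarray(sorted(nbrs), dtype=int))
    return NeighborGraph(neighbors)


def merge_neighbor_graphs(graphs: list[NeighborGraph]) -> NeighborGraph:
    """Disjoint union of per-sample graphs with index offsets applied."""
    neighbors: list = []
    offset = 0
    for g in graphs:
        for nbrs in g.neighbors:
            neighbors.append(np.asarray(nbrs, dtype=int) + offset)
        offset += g.n_spots
    return NeighborGraph(neighbors)
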