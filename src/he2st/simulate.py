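"""Synthetic paired histology / spatial-transcriptomics generator.

The generator produces desk-scale samples with the statistical structure an
image-to-expression model relies on, without any real tissue:

* spots on a regular array grid, pixel centers spaced ``patch_px`` apart so
  patches are disjoint and never exit the slide;
* a spatially autocorrelated tumor/normal annotation formed by the union of
  disc-shaped blobs in grid space (region-level labels, as pathologists
  annotate in practice);
* procedurally rendered patches whose mean intensity and mock-nucleus
  density shift with the latent tumor state and with a continuous per-spot
  morphology covariate, scaled by ``image_signal_strength``;
* per-gene negative-binomial counts.  "Coupled" genes have state-dependent
  means modulated by the morphology covariate, the remaining "decoy" genes
  share one low state-independent mean (giving the many near-zero genes
  typical of spot-level data); counts are additionally zeroed with a
  mean-dependent probability ``dropout_rate * exp(-mu / dropout_decay)``,
  the usual zero-inflation pattern where technical dropout concentrates in
  lowly expressed genes.

Coupled genes alternate between up- and down-regulation in tumor with
symmetric means, so per-spot library size is approximately independent of
the annotation; this keeps decoy genes signal-free *after* library-size
normalization as well, which is what "noise-only" should mean downstream.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import QCThresholds
from .st_data import ExpressionMatrix, STSample, SpotTable, write_sample

COUPLED_PREFIX = "GCPL"
DECOY_PREFIX = "GDEC"


def desk_scale_thresholds() -> QCThresholds:
    """QC thresholds sized for the simulator's default desk-scale libraries.

    The spot-level defaults of :class:`QCThresholds` target real tissue
    libraries (hundreds to thousands of genes); simulated samples carry tens
    of genes and correspondingly small totals, so QC is scaled to match.
    """
    return QCThresholds(min_umi=50, max_umi=100_000, min_genes_per_spot=10, min_spots_per_gene=3)


@dataclass
class SimConfig:
    """Generator parameters; defaults define the standard desk-scale cohort."""

    n_rows: int = 16
    n_cols: int = 16
    patch_px: int = 32
    n_genes: int = 50
    n_coupled: int = 10
    tumor_blob_count: int = 2
    tumor_blob_radius: float = 3.5  # grid units
    nb_mean_normal: float = 8.0  # low state mean of a coupled gene
    nb_mean_tumor: float = 32.0  # high state mean of a coupled gene
    decoy_mean: float = 2.0
    nb_dispersion: float = 16.0  # NB size parameter; var = mu + mu^2 / size
    image_signal_strength: float = 0.8  # 0 = patches carry no expression signal
    dropout_rate: float = 0.05  # zero-inflation probability at mu -> 0
    dropout_decay: float = 4.0  # counts scale of the dropout decay with mu
    cov_coef: float = 0.25  # morphology covariate effect on coupled log-means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coupled > self.n_genes:
            raise ValueError("n_coupled must be <= n_genes")
        for name in ("nb_mean_normal", "nb_mean_tumor", "decoy_mean", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.image_signal_strength <= 1.0:
            raise ValueError("image_signal_strength must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        r = self.tumor_blob_radius
        if self.tumor_blob_count > 0 and (
            self.n_rows <= 2 * r or self.n_cols <= 2 * r
        ):
            raise ValueError("grid too small for the requested tumor blobs")

    def gene_names(self) -> np.ndarray:
        names = [f"{COUPLED_PREFIX}{i:03d}" for i in range(self.n_coupled)]
        names += [f"{DECOY_PREFIX}{i:03d}" for i in range(self.n_genes - self.n_coupled)]
        return np.asarray(names)

    def gene_means(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-gene (normal_mean, tumor_mean, covariate_direction).

        Even-indexed coupled genes are up-regulated in tumor, odd-indexed
        down-regulated with swapped means; decoys share ``decoy_mean`` in
        both states and direction 0.
        """
        normal = np.full(self.n_genes, self.decoy_mean, float)
        tumor = np.full(self.n_genes, self.decoy_mean, float)
        direction = np.zeros(self.n_genes, float)
        for g in range(self.n_coupled):
            if g % 2 == 0:
                normal[g], tumor[g], direction[g] = self.nb_mean_normal, self.nb_mean_tumor, 1.0
            else:
                normal[g], tumor[g], direction[g] = self.nb_mean_tumor, self.nb_mean_normal, -1.0
        return normal, tumor, direction


# ---------------------------------------------------------------------------
# Single sample
# ---------------------------------------------------------------------------


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and size ``dispersion`` per element."""
    if not np.isfinite(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def _tumor_field(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Binary annotation per grid cell: union of random disc-shaped blobs."""
    rows, cols = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    state = np.zeros((config.n_rows, config.n_cols), bool)
    r = config.tumor_blob_radius
    for _ in range(config.tumor_blob_count):
        cr = rng.uniform(r, config.n_rows - 1 - r)
        cc = rng.uniform(r, config.n_cols - 1 - r)
        state |= (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2
    return state.ravel()


def _render_image(
    config: SimConfig,
    r0: np.ndarray,
    c0: np.ndarray,
    state: np.ndarray,
    z: np.ndarray,
    rng: np.random.Generator,
    height: int,
    width: int,
) -> np.ndarray:
    """Procedural H&E-like slide: noisy pink base + per-spot intensity/texture."""
    base = np.array([210.0, 185.0, 200.0])
    img = base + rng.normal(0.0, 12.0, size=(height, width, 3))
    s = config.image_signal_strength
    w = config.patch_px
    # pre-draw a small disc stamp for mock nuclei
    rad = max(w // 16, 1)
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disc = (yy**2 + xx**2) <= rad**2
    nucleus = np.array([90.0, 60.0, 120.0])
    for i in range(len(r0)):
        region = img[r0[i] : r0[i] + w, c0[i] : c0[i] + w, :]
        region += s * (-60.0 * state[i] + 12.0 * z[i])
        n_nuclei = 4 + int(round(8 * s * state[i]))
        for _ in range(n_nuclei):
            cy = rng.integers(rad, w - rad)
            cx = rng.integers(rad, w - rad)
            patch = region[cy - rad : cy + rad + 1, cx - rad : cx + rad + 1, :]
            patch[disc] = 0.5 * patch[disc] + 0.5 * nucleus
    return np.clip(img, 0, 255).astype(np.uint8)


def simulate_sample(
    config: SimConfig,
    sample_id: str = "S1",
    patient_id: str = "P1",
    rng: np.random.Generator | None = None,
    patient_log_shift: np.ndarray | None = None,
) -> STSample:
    """Generate one synthetic tissue section.

    The returned sample carries a ``truth`` table (spot_id, state, z) with
    the latent tumor state and morphology covariate for recovery tests.
    ``patient_log_shift`` (per-gene) multiplies all gene means by
    ``exp(shift)`` to mimic patient-level batch effects.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_rows * config.n_cols
    spacing = config.patch_px
    margin = config.patch_px
    rows, cols = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    rows, cols = rows.ravel(), cols.ravel()
    py = margin + rows * spacing
    px = margin + cols * spacing
    height = 2 * margin + (config.n_rows - 1) * spacing
    width = 2 * margin + (config.n_cols - 1) * spacing

    state = _tumor_field(config, rng).astype(float)
    z = rng.normal(0.0, 1.0, size=n)

    normal_mu, tumor_mu, direction = config.gene_means()
    mu = np.where(state[:, None] > 0, tumor_mu[None, :], normal_mu[None, :])
    mu = mu * np.exp(config.cov_coef * z[:, None] * direction[None, :])
    if patient_log_shift is not None:
        mu = mu * np.exp(np.asarray(patient_log_shift, float)[None, :])
    counts = _draw_counts(rng, mu, config.nb_dispersion).astype(np.int64)
    if config.dropout_rate > 0:
        p_drop = config.dropout_rate * np.exp(-mu / config.dropout_decay)
        counts[rng.random(counts.shape) < p_drop] = 0

    w = config.patch_px
    r0 = py - w // 2
    c0 = px - w // 2
    img = _render_image(config, r0, c0, state, z, rng, height, width)

    spot_ids = np.asarray([f"{sample_id}_r{r:02d}c{c:02d}" for r, c in zip(rows, cols)])
    spots = SpotTable(
        pd.DataFrame(
            {
                "spot_id": spot_ids,
                "pixel_x": px.astype(float),
                "pixel_y": py.astype(float),
                "array_row": rows,
                "array_col": cols,
                "annotation": state.astype(int),
            }
        )
    )
    expr = ExpressionMatrix(counts, config.gene_names(), spot_ids, "raw_counts")
    truth = pd.DataFrame({"spot_id": spot_ids, "state": state.astype(int), "z": z})
    return STSample(sample_id, patient_id, img, spots, expr, truth)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimConfig,
    n_patients: int = 3,
    sections_per_patient: int = 2,
    patient_effect_sd: float = 0.1,
) -> list[STSample]:
    """Generate ``n_patients`` x ``sections_per_patient`` sections.

    Each patient receives a per-gene log-normal random effect of standard
    deviation ``patient_effect_sd`` on the NB means, mimicking batch effects
    between patients; sections of one patient share that effect.
    """
    if n_patients < 3:
        raise ValueError("need >= 3 patients for patient-level train/val/test splits")
    seeds = np.random.SeedSequence(config.seed).spawn(n_patients)
    samples = []
    for p, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        shift = (
            rng.normal(0.0, patient_effect_sd, size=config.n_genes)
            if patient_effect_sd > 0
            else np.zeros(config.n_genes)
        )
        pid = f"P{p + 1:02d}"
        for s in range(sections_per_patient):
            samples.append(
                simulate_sample(
                    config,
                    sample_id=f"{pid}_s{s + 1}",
                    patient_id=pid,
                    rng=rng,
                    patient_log_shift=shift,
                )
            )
    return samples


def write_cohort(
    samples: list[STSample],
    out_dir: Path,
    config: SimConfig | None = None,
    counts_format: str = "tsv",
) -> Path:
    """Write samples to per-sample directories plus a cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        d = write_sample(s, out_dir / s.sample_id, counts_format=counts_format)
        counts_name = "counts.tsv" if counts_format == "tsv" else "counts.mtx"
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "image": f"{s.sample_id}/image.png",
                "spots": f"{s.sample_id}/spots.tsv",
                "counts": f"{s.sample_id}/{counts_name}",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    if config is not None:
        (out_dir / "sim_config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2)
        )
    return out_dir


def read_cohort(in_dir: Path) -> list[STSample]:
    """Read a cohort written by :func:`write_cohort` (or hand-assembled alike)."""
    from .st_data import read_sample

    in_dir = Path(in_dir)
    manifest = in_dir / "cohort.tsv"
    if not manifest.exists():
        raise IOError(f"no cohort manifest found at {manifest}")
    table = pd.read_csv(manifest, sep="\t")
    samples = []
    for _, row in table.iterrows():
        samples.append(
            read_sample(
                in_dir / row["image"],
                in_dir / row["spots"],
                in_dir / row["counts"],
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
            )
        )
    return samples
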