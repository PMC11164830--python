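"""Data model and I/O for paired histology / spatial-transcriptomics samples.

A sample couples three artifacts measured on one tissue section: an RGB
whole-slide image, a spot table (pixel and array-grid coordinates plus an
optional binary tumor/normal annotation per spot), and a spots x genes count
matrix.  This module defines the in-memory containers, readers/writers for
the plain-text exchange formats (TSV/CSV spot tables and counts, MatrixMarket
counts, PNG/JPEG/TIFF images), and the geometric patch extraction that turns
a slide plus spot centers into a stack of fixed-size patches.

Conventions
-----------
* Pixel coordinates are 0-based with ``pixel_x`` the column and ``pixel_y``
  the row, matching raster order.
* A patch window of side ``w`` centered at integer pixel ``c`` covers the
  half-open interval ``[c - w//2, c - w//2 + w)`` on each axis.  Float
  centers are rounded to the nearest integer pixel first.
* Spots whose window exits the image are *excluded*, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import mmread
from skimage.transform import resize

from .exceptions import AlignmentError, DegenerateChannelError, EmptySampleError

SPOT_COLUMNS = ("spot_id", "pixel_x", "pixel_y", "array_row", "array_col", "annotation")

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SpotTable:
    """Per-spot metadata: identifiers, pixel centers, grid position, label.

    ``annotation`` is 1 for tumor, 0 for normal, NaN when unannotated.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        df = self.table.reset_index(drop=True).copy()
        df["spot_id"] = df["spot_id"].astype(str)
        for c in ("pixel_x", "pixel_y", "annotation"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        for c in ("array_row", "array_col"):
            df[c] = df[c].astype(int)
        if df["spot_id"].duplicated().any():
            dup = df.loc[df["spot_id"].duplicated(), "spot_id"].tolist()
            raise ValueError(f"duplicate spot_ids: {dup}")
        if df.duplicated(subset=["array_row", "array_col"]).any():
            raise ValueError("duplicate (array_row, array_col) pairs")
        xy = df[["pixel_x", "pixel_y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)) or (xy < 0).any():
            raise ValueError("pixel coordinates must be finite and non-negative")
        self.table = df

    @property
    def n_spots(self) -> int:
        return len(self.table)

    @property
    def spot_ids(self) -> np.ndarray:
        return self.table["spot_id"].to_numpy()

    @property
    def pixel_xy(self) -> np.ndarray:
        return self.table[["pixel_x", "pixel_y"]].to_numpy(float)

    @property
    def array_rc(self) -> np.ndarray:
        return self.table[["array_row", "array_col"]].to_numpy(int)

    @property
    def annotation(self) -> np.ndarray:
        """Float vector; NaN marks unannotated spots."""
        return self.table["annotation"].to_numpy(float)

    def subset(self, mask: np.ndarray) -> "SpotTable":
        return SpotTable(self.table.loc[np.asarray(mask, bool)].reset_index(drop=True))


@dataclass
class ExpressionMatrix:
    """Spots x genes matrix with a layer tag distinguishing raw counts."""

    values: np.ndarray
    gene_names: np.ndarray
    spot_ids: np.ndarray
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_names = np.asarray(self.gene_names, dtype=object).astype(str)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object).astype(str)
        n, m = self.values.shape
        if n != len(self.spot_ids) or m != len(self.gene_names):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.spot_ids)} spots / {len(self.gene_names)} genes"
            )
        if len(set(self.gene_names)) != m:
            raise ValueError("gene names must be unique")
        if self.layer_tag == "raw_counts" and (self.values < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_spots(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, bool)
        return ExpressionMatrix(self.values[mask], self.gene_names, self.spot_ids[mask], self.layer_tag)

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, bool)
        return ExpressionMatrix(self.values[:, mask], self.gene_names[mask], self.spot_ids, self.layer_tag)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.gene_names)


@dataclass
class STSample:
    """One tissue section: image + spot table + expression, kept aligned."""

    sample_id: str
    patient_id: str
    image: Union[np.ndarray, Path]
    spots: SpotTable
    expression: ExpressionMatrix
    truth: Optional[pd.DataFrame] = None  # simulator ground truth, if any

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty (needed for patient-level splits)")
        if not np.array_equal(self.spots.spot_ids, self.expression.spot_ids):
            raise AlignmentError(
                f"sample {self.sample_id}: spot table and expression disagree on spot ids/order"
            )

    def load_image(self) -> np.ndarray:
        """Return the slide as an H x W x 3 uint8 array, reading from disk if lazy."""
        if isinstance(self.image, (str, Path)):
            img = iio.imread(self.image)
        else:
            img = self.image
        img = np.asarray(img)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.ndim != 3 or img.shape[2] < 3:
            raise IOError(f"expected an RGB image, got shape {img.shape}")
        return img[:, :, :3]

    @property
    def n_spots(self) -> int:
        return self.spots.n_spots

    def subset_spots(self, mask: np.ndarray) -> "STSample":
        mask = np.asarray(mask, bool)
        truth = None
        if self.truth is not None:
            truth = self.truth.loc[mask].reset_index(drop=True)
        return STSample(
            self.sample_id,
            self.patient_id,
            self.image,
            self.spots.subset(mask),
            self.expression.subset_spots(mask),
            truth,
        )


@dataclass
class PatchSet:
    """Per-spot image patches aligned to spot ids.

    ``patches`` is N x S x S x 3; raw patches are on the 0..255 scale,
    normalized ones are standardized floats (see :func:`normalize_patches`).
    """

    patches: np.ndarray
    spot_ids: np.ndarray
    window_px: int
    out_size_px: int

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object).astype(str)
        if self.patches.ndim != 4 or self.patches.shape[3] != 3:
            raise ValueError(f"patches must be N x S x S x 3, got {self.patches.shape}")
        if self.patches.shape[0] != len(self.spot_ids):
            raise ValueError("one patch per spot id required")
        if self.patches.shape[1] != self.out_size_px or self.patches.shape[2] != self.out_size_px:
            raise ValueError("patch side must equal out_size_px")

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    def subset(self, mask: np.ndarray) -> "PatchSet":
        mask = np.asarray(mask, bool)
        return PatchSet(self.patches[mask], self.spot_ids[mask], self.window_px, self.out_size_px)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path: PathLike) -> pd.DataFrame:
    """Read a TSV/CSV with auto-detected delimiter."""
    return pd.read_csv(path, sep=None, engine="python")


def _read_counts(counts_path: PathLike) -> pd.DataFrame:
    """Read a counts matrix as a spots x genes DataFrame.

    Two encodings are supported: a delimited table with spot ids in the first
    column and gene names in the header, or a MatrixMarket ``.mtx`` file with
    sibling ``genes.txt`` and ``spots.txt`` name files (one name per line,
    matrix rows = spots).
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        genes_file = counts_path.parent / "genes.txt"
        spots_file = counts_path.parent / "spots.txt"
        for f in (genes_file, spots_file):
            if not f.exists():
                raise IOError(f"MatrixMarket counts require sibling name file {f}")
        mat = mmread(counts_path)
        if hasattr(mat, "todense"):
            mat = mat.todense()
        mat = np.asarray(mat)
        genes = genes_file.read_text().split()
        spots = spots_file.read_text().split()
        return pd.DataFrame(mat, index=spots, columns=genes)
    df = pd.read_csv(counts_path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_sample(
    image_path: PathLike,
    spots_path: PathLike,
    counts_path: PathLike,
    *,
    sample_id: Optional[str] = None,
    patient_id: str = "unknown",
    lazy_image: bool = False,
) -> STSample:
    """Assemble an :class:`STSample` from its three on-disk artifacts.

    Counts rows are reordered to match the spot table; any mismatch in the
    spot id sets raises :class:`AlignmentError` listing the offenders.
    """
    for p in (image_path, spots_path, counts_path):
        if not Path(p).exists():
            raise IOError(f"input file not found: {p}")
    spots = SpotTable(_read_delimited(spots_path))
    counts = _read_counts(counts_path)
    table_ids = list(spots.spot_ids)
    missing = sorted(set(table_ids) - set(counts.index))
    extra = sorted(set(counts.index) - set(table_ids))
    if missing or extra:
        raise AlignmentError(
            f"spot id mismatch between spot table and counts: "
            f"missing from counts={missing}, not in spot table={extra}"
        )
    counts = counts.loc[table_ids]
    expr = ExpressionMatrix(
        counts.to_numpy(), counts.columns.to_numpy(), counts.index.to_numpy(), "raw_counts"
    )
    sid = sample_id or Path(image_path).parent.name or "sample"
    image: Union[np.ndarray, Path] = Path(image_path)
    if not lazy_image:
        image = STSample(sid, patient_id, Path(image_path), spots, expr).load_image()
    return STSample(sid, patient_id, image, spots, expr)


def write_sample(sample: STSample, out_dir: PathLike, counts_format: str = "tsv") -> Path:
    """Write a sample to ``out_dir`` in the exact formats :func:`read_sample` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / "image.png", sample.load_image())
    sample.spots.table.to_csv(out_dir / "spots.tsv", sep="\t", index=False)
    df = sample.expression.to_dataframe()
    if counts_format == "tsv":
        df.to_csv(out_dir / "counts.tsv", sep="\t")
    elif counts_format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(out_dir / "counts.mtx"), coo_matrix(df.to_numpy()))
        (out_dir / "genes.txt").write_text("\n".join(df.columns) + "\n")
        (out_dir / "spots.txt").write_text("\n".join(df.index) + "\n")
    else:
        raise ValueError(f"unknown counts_format {counts_format!r}")
    if sample.truth is not None:
        sample.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# Patch geometry
# ---------------------------------------------------------------------------


def extract_patches(
    sample: STSample, window_px: int = 150, out_size_px: int = 224
) -> tuple[PatchSet, np.ndarray]:
    """Crop one square patch per spot; flag spots whose window exits the slide.

    Returns ``(patch_set, boundary_mask)`` where ``boundary_mask[i]`` is True
    when spot ``i`` was *excluded* because its half-open window
    ``[c - w//2, c - w//2 + w)`` leaves ``[0, H) x [0, W)``.  The patch set
    contains only retained spots, resized to ``out_size_px`` with bilinear
    interpolation (identity when ``window_px == out_size_px``).
    """
    if window_px < 1:
        raise ValueError("window_px must be >= 1")
    img = sample.load_image()
    h, w = img.shape[:2]
    centers = np.rint(sample.spots.pixel_xy).astype(int)  # columns (x), rows (y)
    c0 = centers[:, 0] - window_px // 2
    r0 = centers[:, 1] - window_px // 2
    boundary_mask = (r0 < 0) | (c0 < 0) | (r0 + window_px > h) | (c0 + window_px > w)
    keep = np.flatnonzero(~boundary_mask)
    if keep.size == 0:
        raise EmptySampleError(
            f"sample {sample.sample_id}: all {sample.n_spots} spot windows exit the image"
        )
    patches = np.empty((keep.size, out_size_px, out_size_px, 3), dtype=np.float32)
    for k, i in enumerate(keep):
        crop = img[r0[i] : r0[i] + window_px, c0[i] : c0[i] + window_px, :]
        if window_px == out_size_px:
            patches[k] = crop.astype(np.float32)
        else:
            patches[k] = resize(
                crop.astype(np.float32),
                (out_size_px, out_size_px),
                order=1,
                preserve_range=True,
                anti_aliasing=False,
            )
    return (
        PatchSet(patches, sample.spots.spot_ids[keep], window_px, out_size_px),
        boundary_mask,
    )


def channel_stats(patches: PatchSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and std of patch pixels on the 0..1 scale.

    Computed on the *training* patches only; stored with the model so the
    same standardization is applied at inference time.
    """
    scaled = patches.patches.astype(np.float64) / 255.0
    return scaled.mean(axis=(0, 1, 2)), scaled.std(axis=(0, 1, 2))


def normalize_patches(
    patches: PatchSet, channel_mean: Sequence[float], channel_std: Sequence[float]
) -> PatchSet:
    """Standardize patches: ``((raw / 255) - mean) / std`` per channel."""
    mean = np.asarray(channel_mean, dtype=np.float64).reshape(1, 1, 1, 3)
    std = np.asarray(channel_std, dtype=np.float64).reshape(1, 1, 1, 3)
    if (std <= 0).any():
        raise DegenerateChannelError(f"channel std must be > 0, got {std.ravel()}")
    out = ((patches.patches.astype(np.float64) / 255.0) - mean) / std
    return PatchSet(out.astype(np.float32), patches.spot_ids, patches.window_px, patches.out_size_px)


# ---------------------------------------------------------------------------
# Prediction table I/O
# ---------------------------------------------------------------------------

TUMOR_PROB_COLUMN = "tumor_prob"


def write_predictions(
    spot_ids: Sequence[str],
    gene_names: Sequence[str],
    predicted: np.ndarray,
    tumor_prob: np.ndarray,
    out_path: PathLike,
) -> Path:
    """Write per-spot predicted expression and tumor probability as TSV."""
    predicted = np.asarray(predicted, dtype=float)
    tumor_prob = np.asarray(tumor_prob, dtype=float)
    gene_names = list(gene_names)
    if len(gene_names) == 0:
        raise ValueError("gene_names must be non-empty")
    if predicted.shape != (len(spot_ids), len(gene_names)):
        raise ValueError(
            f"predicted shape {predicted.shape} != ({len(spot_ids)}, {len(gene_names)})"
        )
    if tumor_prob.shape != (len(spot_ids),):
        raise ValueError("tumor_prob must have one entry per spot")
    df = pd.DataFrame(predicted, index=pd.Index(spot_ids, name="spot_id"), columns=gene_names)
    df[TUMOR_PROB_COLUMN] = tumor_prob
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, sep="\t")
    return out_path


def read_predictions(path: PathLike) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`write_predictions`: (spot_ids, gene_names, matrix, tumor_prob)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    tumor = df.pop(TUMOR_PROB_COLUMN).to_numpy()
    return (
        df.index.to_numpy().astype(str),
        df.columns.to_numpy().astype(str),
        df.to_numpy(),
        tumor,
    )
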