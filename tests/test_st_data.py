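from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import he2st as H
from he2st.exceptions import AlignmentError, DegenerateChannelError

from conftest import make_grid_sample


def write_fixture_trio(tmp_path, n_spots=4, n_genes=6, counts_format="tsv", seed=3):
    import imageio.v3 as iio

    rng = np.random.default_rng(seed)
    spots = pd.DataFrame(
        {
            "spot_id": [f"s{i}" for i in range(n_spots)],
            "pixel_x": np.linspace(40, 160, n_spots),
            "pixel_y": np.linspace(40, 160, n_spots),
            "array_row": np.arange(n_spots),
            "array_col": np.zeros(n_spots, int),
            "annotation": rng.integers(0, 2, n_spots),
        }
    )
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(n_spots, n_genes)),
        index=pd.Index(spots["spot_id"], name="spot_id"),
        columns=[f"G{j}" for j in range(n_genes)],
    )
    spots.to_csv(tmp_path / "spots.tsv", sep="\t", index=False)
    if counts_format == "tsv":
        counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        counts_path = tmp_path / "counts.tsv"
    else:
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(tmp_path / "counts.mtx"), coo_matrix(counts.to_numpy()))
        (tmp_path / "genes.txt").write_text("\n".join(counts.columns) + "\n")
        (tmp_path / "spots.txt").write_text("\n".join(counts.index) + "\n")
        counts_path = tmp_path / "counts.mtx"
    img = rng.integers(0, 256, size=(200, 200, 3), dtype=np.uint8)
    iio.imwrite(tmp_path / "image.png", img)
    return tmp_path / "image.png", tmp_path / "spots.tsv", counts_path, counts


class TestReadSample:
    def test_round_trip_tsv_trio(self, tmp_path):
        image, spots, counts_path, counts = write_fixture_trio(tmp_path)
        sample = H.read_sample(image, spots, counts_path, patient_id="P1")
        assert sample.n_spots == 4
        assert sample.expression.n_genes == 6
        np.testing.assert_array_equal(sample.expression.values, counts.to_numpy())

    def test_missing_spot_in_counts_is_alignment_error(self, tmp_path):
        image, spots, counts_path, counts = write_fixture_trio(tmp_path)
        counts.iloc[1:].to_csv(counts_path, sep="\t")
        with pytest.raises(AlignmentError, match="s0"):
            H.read_sample(image, spots, counts_path)

    def test_mtx_and_tsv_encodings_agree(self, tmp_path):
        d1 = tmp_path / "tsv"
        d2 = tmp_path / "mtx"
        d1.mkdir(), d2.mkdir()
        a = H.read_sample(*write_fixture_trio(d1, counts_format="tsv")[:3])
        b = H.read_sample(*write_fixture_trio(d2, counts_format="mtx")[:3])
        np.testing.assert_array_equal(a.expression.values, b.expression.values)
        np.testing.assert_array_equal(a.expression.gene_names, b.expression.gene_names)

    def test_sample_write_read_round_trip_preserves_counts_and_coords(self, tmp_path):
        sample = make_grid_sample(seed=9)
        H.write_sample(sample, tmp_path / "s")
        back = H.read_sample(
            tmp_path / "s" / "image.png",
            tmp_path / "s" / "spots.tsv",
            tmp_path / "s" / "counts.tsv",
        )
        np.testing.assert_array_equal(back.expression.values, sample.expression.values)
        np.testing.assert_allclose(back.spots.pixel_xy, sample.spots.pixel_xy)


def _sample_with_spot(x, y, img_side=300, window=150):
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, size=(img_side, img_side, 3), dtype=np.uint8)
    spots = H.SpotTable(
        pd.DataFrame(
            {
                "spot_id": ["a"],
                "pixel_x": [float(x)],
                "pixel_y": [float(y)],
                "array_row": [0],
                "array_col": [0],
                "annotation": [1],
            }
        )
    )
    expr = H.ExpressionMatrix(np.ones((1, 2)), np.array(["G0", "G1"]), spots.spot_ids)
    return H.STSample("s", "p", img, spots, expr), img


class TestExtractPatches:
    def test_half_open_window_convention(self):
        sample, img = _sample_with_spot(100, 100)
        ps, mask = H.extract_patches(sample, window_px=150, out_size_px=150)
        assert not mask[0]
        np.testing.assert_array_equal(ps.patches[0], img[25:175, 25:175, :].astype(np.float32))

    def test_spot_too_close_to_boundary_is_excluded(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(300, 300, 3), dtype=np.uint8)
        spots = H.SpotTable(
            pd.DataFrame(
                {
                    "spot_id": ["edge", "interior"],
                    "pixel_x": [50.0, 150.0],
                    "pixel_y": [50.0, 150.0],
                    "array_row": [0, 1],
                    "array_col": [0, 0],
                    "annotation": [0, 0],
                }
            )
        )
        expr = H.ExpressionMatrix(np.ones((2, 1)), np.array(["G"]), spots.spot_ids)
        sample = H.STSample("s", "p", img, spots, expr)
        ps, mask = H.extract_patches(sample, window_px=150, out_size_px=150)
        np.testing.assert_array_equal(mask, [True, False])
        assert list(ps.spot_ids) == ["interior"]

    def test_all_spots_on_boundary_is_empty_sample_error(self):
        sample, _ = _sample_with_spot(50, 50)
        with pytest.raises(H.EmptySampleError):
            H.extract_patches(sample, window_px=150)

    def test_boundary_mask_matches_brute_force_scan(self, rng):
        img_side, window = 120, 30
        n = 40
        xs = rng.integers(0, img_side, n)
        ys = rng.integers(0, img_side, n)
        spots = H.SpotTable(
            pd.DataFrame(
                {
                    "spot_id": [f"s{i}" for i in range(n)],
                    "pixel_x": xs.astype(float),
                    "pixel_y": ys.astype(float),
                    "array_row": np.arange(n),
                    "array_col": np.zeros(n, int),
                    "annotation": np.zeros(n),
                }
            )
        )
        expr = H.ExpressionMatrix(np.ones((n, 1)), np.array(["G"]), spots.spot_ids)
        img = rng.integers(0, 256, size=(img_side, img_side, 3), dtype=np.uint8)
        sample = H.STSample("s", "p", img, spots, expr)
        _, mask = H.extract_patches(sample, window_px=window, out_size_px=window)
        for i in range(n):
            r0 = int(ys[i]) - window // 2
            c0 = int(xs[i]) - window // 2
            outside = r0 < 0 or c0 < 0 or r0 + window > img_side or c0 + window > img_side
            assert mask[i] == outside

    def test_translation_consistency(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, size=(90, 90, 3), dtype=np.uint8)
        dx, dy = 7, 11
        shifted = np.zeros((101, 97, 3), np.uint8)
        shifted[dy : dy + 90, dx : dx + 90] = img

        def sample_at(x, y, image):
            spots = H.SpotTable(
                pd.DataFrame(
                    {
                        "spot_id": ["a"],
                        "pixel_x": [float(x)],
                        "pixel_y": [float(y)],
                        "array_row": [0],
                        "array_col": [0],
                        "annotation": [0],
                    }
                )
            )
            expr = H.ExpressionMatrix(np.ones((1, 1)), np.array(["G"]), spots.spot_ids)
            return H.STSample("s", "p", image, spots, expr)

        a, _ = H.extract_patches(sample_at(45, 45, img), 20, 20)
        b, _ = H.extract_patches(sample_at(45 + dx, 45 + dy, shifted), 20, 20)
        np.testing.assert_array_equal(a.patches, b.patches)


class TestNormalizePatches:
    def _ps(self, value, n=2, side=4):
        arr = np.full((n, side, side, 3), value, np.float32)
        return H.PatchSet(arr, [f"s{i}" for i in range(n)], side, side)

    def test_constant_255_with_unit_stats_is_zero(self):
        out = H.normalize_patches(self._ps(255.0), (1, 1, 1), (1, 1, 1))
        np.testing.assert_allclose(out.patches, 0.0)

    def test_zero_pixel_with_half_mean_quarter_std(self):
        out = H.normalize_patches(self._ps(0.0), (0.5, 0.5, 0.5), (0.25, 0.25, 0.25))
        np.testing.assert_allclose(out.patches, -2.0)

    def test_train_set_standardization_gives_zero_mean_unit_std(self, rng):
        arr = rng.integers(0, 256, size=(10, 8, 8, 3)).astype(np.float32)
        ps = H.PatchSet(arr, [f"s{i}" for i in range(10)], 8, 8)
        mean, std = H.channel_stats(ps)
        out = H.normalize_patches(ps, mean, std)
        np.testing.assert_allclose(out.patches.mean(axis=(0, 1, 2)), 0.0, atol=1e-4)
        np.testing.assert_allclose(out.patches.std(axis=(0, 1, 2)), 1.0, atol=1e-4)

    def test_zero_std_channel_rejected(self):
        with pytest.raises(DegenerateChannelError):
            H.normalize_patches(self._ps(1.0), (0, 0, 0), (1, 0, 1))


class TestPredictionIO:
    def test_round_trip(self, tmp_path, rng):
        ids = ["a", "b"]
        genes = ["G1", "G2", "G3", "G4"]
        mat = rng.normal(size=(2, 4))
        prob = rng.random(2)
        path = H.write_predictions(ids, genes, mat, prob, tmp_path / "pred.tsv")
        rids, rgenes, rmat, rprob = H.read_predictions(path)
        assert list(rids) == ids and list(rgenes) == genes
        np.testing.assert_allclose(rmat, mat)
        np.testing.assert_allclose(rprob, prob)

    def test_empty_gene_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="non-empty"):
            H.write_predictions(["a"], [], np.zeros((1, 0)), np.zeros(1), tmp_path / "p.tsv")

    def test_shape_mismatch_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            H.write_predictions(["a", "b"], ["G"], np.zeros((3, 1)), np.zeros(3), tmp_path / "p.tsv")
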