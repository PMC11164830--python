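from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import he2st as H
from he2st.preprocess import merge_neighbor_graphs

from _oracles import grid_neighbors_loop
from conftest import make_grid_sample


def _expr(counts, genes=None, layer="raw_counts"):
    counts = np.asarray(counts)
    genes = genes if genes is not None else [f"G{j}" for j in range(counts.shape[1])]
    return H.ExpressionMatrix(
        counts, np.asarray(genes), [f"s{i}" for i in range(counts.shape[0])], layer
    )


def _sample_from_counts(counts, genes=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    side = int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), side)
    spots = H.SpotTable(
        pd.DataFrame(
            {
                "spot_id": [f"s{i}" for i in range(n)],
                "pixel_x": cols * 10.0 + 50,
                "pixel_y": rows * 10.0 + 50,
                "array_row": rows,
                "array_col": cols,
                "annotation": np.zeros(n),
            }
        )
    )
    img = np.zeros((400, 400, 3), np.uint8)
    return H.STSample("s", "p", img, spots, _expr(counts, genes))


class TestSpotQC:
    def _counts(self, n_genes=300):
        # clean spot template: 250 detected genes, ~2500 UMIs, no mito counts
        row = np.zeros(n_genes)
        row[:250] = 10
        return row

    def test_planted_violations_each_trip_their_rule(self):
        genes = [f"MT-{j}" for j in range(3)] + [f"G{j}" for j in range(297)]
        clean = np.zeros(300)
        clean[3:253] = 10  # 250 detected, 2500 UMIs, 0% mito
        low = np.zeros(300)
        low[3:253] = 0.0
        low[3:153] = 1  # 150 UMIs
        high = np.zeros(300)
        high[3:253] = 101  # 25250 UMIs
        mito = clean.copy()
        mito[0] = 160  # 160 / 2660 ~ 6% mitochondrial
        few = np.zeros(300)
        few[3:153] = 14  # 2100 UMIs but only 150 detected genes
        counts = np.stack([clean, low, high, mito, few])
        sample = _sample_from_counts(counts, genes)
        keep = H.qc_filter_spots(sample, H.QCThresholds())
        np.testing.assert_array_equal(keep, [True, False, False, False, False])
        report = H.qc_report(sample, H.QCThresholds())
        assert report.loc[1, "fail_low_umi"] and report.loc[2, "fail_high_umi"]
        assert report.loc[3, "fail_mito"] and report.loc[4, "fail_detected"]

    def test_exact_threshold_boundaries_are_retained(self):
        # exactly 200 UMIs over exactly 200 genes, 0% mito
        row = np.zeros(300)
        row[:200] = 1
        sample = _sample_from_counts(np.stack([row, row * 10]))
        keep = H.qc_filter_spots(sample, H.QCThresholds())
        assert keep.all()

    def test_boundary_exclusion_feeds_into_mask(self):
        row = np.zeros(300)
        row[:250] = 10
        sample = _sample_from_counts(np.stack([row, row]))
        keep = H.qc_filter_spots(sample, H.QCThresholds(), boundary_excluded=[False, True])
        np.testing.assert_array_equal(keep, [True, False])

    def test_idempotent(self):
        sample = make_grid_sample(n_genes=30, seed=2)
        thr = H.QCThresholds(min_umi=50, max_umi=400, min_genes_per_spot=5)
        keep1 = H.qc_filter_spots(sample, thr)
        sub = sample.subset_spots(keep1)
        keep2 = H.qc_filter_spots(sub, thr)
        assert keep2.all()


class TestGeneQC:
    @pytest.mark.parametrize("n_detected,kept", [(2, False), (3, True), (0, False)])
    def test_detection_boundary(self, n_detected, kept):
        counts = np.zeros((5, 1))
        counts[:n_detected, 0] = 4
        mask = H.qc_filter_genes(_expr(counts), H.QCThresholds())
        assert mask[0] == kept

    def test_matches_brute_force_and_is_order_independent(self, rng):
        counts = rng.integers(0, 3, size=(20, 15))
        mask = H.qc_filter_genes(_expr(counts), H.QCThresholds())
        brute = np.array(
            [sum(counts[i, j] > 0 for i in range(20)) >= 3 for j in range(15)]
        )
        np.testing.assert_array_equal(mask, brute)
        perm = rng.permutation(20)
        mask_p = H.qc_filter_genes(_expr(counts[perm]), H.QCThresholds())
        np.testing.assert_array_equal(mask, mask_p)


class TestNormalizeExpression:
    def test_known_values(self):
        counts = np.array([[1.0, 9999.0]])
        out = H.normalize_expression(_expr(counts))
        assert out.layer_tag == "normalized"
        np.testing.assert_allclose(out.values[0, 0], np.log(2.0))  # 1/10000*1e4 = 1

    def test_zero_count_maps_to_zero(self):
        out = H.normalize_expression(_expr(np.array([[0.0, 5.0]])))
        assert out.values[0, 0] == 0.0

    def test_scale_invariance_to_library_size(self, rng):
        counts = rng.integers(1, 50, size=(3, 8)).astype(float)
        a = H.normalize_expression(_expr(counts))
        b = H.normalize_expression(_expr(counts * 2))
        np.testing.assert_allclose(a.values, b.values)

    def test_exact_inverse(self, rng):
        counts = rng.integers(0, 40, size=(6, 10)).astype(float)
        counts[:, 0] += 1
        norm = H.normalize_expression(_expr(counts))
        profile = H.preprocess.denormalize_expression(norm)
        np.testing.assert_allclose(
            profile, counts / counts.sum(axis=1, keepdims=True), atol=1e-12
        )

    def test_zero_total_spot_rejected(self):
        with pytest.raises(ValueError, match="QC"):
            H.normalize_expression(_expr(np.zeros((2, 3))))


class TestPartitionGenes:
    def test_tie_break_by_gene_name(self):
        # means (3, 1, 2, 0, 2): rank 1 = A (3); tie at 2 between C and E -> C by name
        counts = np.array([[3.0, 1.0, 2.0, 0.0, 2.0]] * 2)
        expr = _expr(counts, ["A", "B", "C", "E", "D"], layer="normalized")
        part = H.partition_genes(expr, m=2)
        assert set(expr.gene_names[part.target_idx]) == {"A", "C"}

    def test_m_equal_total_leaves_no_nontargets(self):
        expr = _expr(np.ones((2, 4)), layer="normalized")
        part = H.partition_genes(expr, m=4)
        assert len(part.nontarget_idx) == 0

    def test_m_too_large_rejected(self):
        with pytest.raises(ValueError):
            H.partition_genes(_expr(np.ones((2, 3))), m=4)

    def test_permutation_invariance_of_selected_names(self, rng):
        vals = rng.normal(size=(10, 12))
        names = [f"G{j:02d}" for j in range(12)]
        expr = _expr(vals, names, layer="normalized")
        part = H.partition_genes(expr, m=5)
        perm = rng.permutation(12)
        expr_p = _expr(vals[:, perm], list(np.asarray(names)[perm]), layer="normalized")
        part_p = H.partition_genes(expr_p, m=5)
        assert set(expr.gene_names[part.target_idx]) == set(expr_p.gene_names[part_p.target_idx])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_strictly_ordered_means_select_top_m(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(3, 15))
        means = rng.permutation(np.arange(n_genes, dtype=float))  # strictly ordered
        vals = np.tile(means, (4, 1))
        expr = _expr(vals, layer="normalized")
        m = int(rng.integers(1, n_genes + 1))
        part = H.partition_genes(expr, m=m)
        expected = set(np.argsort(-means)[:m])
        assert set(part.target_idx.tolist()) == expected


def _spot_table_from_rc(rc):
    rc = np.asarray(rc)
    return H.SpotTable(
        pd.DataFrame(
            {
                "spot_id": [f"s{i}" for i in range(len(rc))],
                "pixel_x": np.arange(len(rc), dtype=float),
                "pixel_y": np.arange(len(rc), dtype=float),
                "array_row": rc[:, 0],
                "array_col": rc[:, 1],
                "annotation": np.zeros(len(rc)),
            }
        )
    )


class TestNeighborGraph:
    def test_full_grid_degrees(self):
        rc = [(r, c) for r in range(5) for c in range(5)]
        g = H.build_neighbor_graph(_spot_table_from_rc(rc))
        deg = g.degree().reshape(5, 5)
        assert deg[2, 2] == 8  # interior
        assert deg[0, 0] == deg[0, 4] == deg[4, 0] == deg[4, 4] == 3  # corners
        assert deg[0, 2] == 5  # edge

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sparse_grid_matches_brute_force_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        side = int(rng.integers(2, 7))
        all_rc = [(r, c) for r in range(side) for c in range(side)]
        take = rng.random(len(all_rc)) < 0.6
        take[0] = True
        rc = np.asarray([p for p, t in zip(all_rc, take) if t])
        g = H.build_neighbor_graph(_spot_table_from_rc(rc))
        brute = grid_neighbors_loop(rc)
        for i in range(len(rc)):
            assert list(g.neighbors[i]) == brute[i]
            for j in g.neighbors[i]:
                assert i in g.neighbors[j]  # symmetry
            assert i not in g.neighbors[i]
            assert len(g.neighbors[i]) <= 8

    def test_duplicate_array_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _spot_table_from_rc([(0, 0), (0, 0)])

    def test_merge_offsets_indices(self):
        rc = [(0, 0), (0, 1)]
        g = H.build_neighbor_graph(_spot_table_from_rc(rc))
        merged = merge_neighbor_graphs([g, g])
        assert list(merged.neighbors[2]) == [3]
        assert merged.n_spots == 4
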