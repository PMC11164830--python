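from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import he2st as H


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_grid_sample(
    n_rows=4,
    n_cols=4,
    n_genes=6,
    window=16,
    seed=0,
    sample_id="S1",
    patient_id="P1",
    annotate=True,
):
    """Small deterministic sample on a regular grid with disjoint windows."""
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    spacing = window
    margin = window
    spots = H.SpotTable(
        pd.DataFrame(
            {
                "spot_id": [f"{sample_id}_{i}" for i in range(n)],
                "pixel_x": (margin + cols * spacing).astype(float),
                "pixel_y": (margin + rows * spacing).astype(float),
                "array_row": rows,
                "array_col": cols,
                "annotation": (rows < n_rows // 2).astype(int) if annotate else np.nan,
            }
        )
    )
    counts = rng.integers(0, 20, size=(n, n_genes))
    counts[:, 0] += 5  # keep totals positive
    expr = H.ExpressionMatrix(
        counts, np.array([f"G{j}" for j in range(n_genes)]), spots.spot_ids, "raw_counts"
    )
    h = 2 * margin + (n_rows - 1) * spacing
    w = 2 * margin + (n_cols - 1) * spacing
    img = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    return H.STSample(sample_id, patient_id, img, spots, expr)


@pytest.fixture
def grid_sample():
    return make_grid_sample()


@pytest.fixture(scope="session")
def recovery_cohorts():
    """Simulated 3-patient cohorts (one per seed) with their trained models.

    Shared across tests that probe signal recovery so the expensive training
    runs happen once per session.
    """
    results = {}
    for seed in (0, 1, 2):
        cfg = H.SimConfig(seed=seed)
        samples = H.simulate_cohort(cfg, n_patients=3, sections_per_patient=1)
        prepared = H.prepare_cohort(
            samples, H.desk_scale_thresholds(), window_px=32, out_size_px=32
        )
        split = H.SplitSpec(["P01"], ["P02"], ["P03"], seed=seed)
        ckpt, history = H.train(
            prepared,
            split,
            H.LossWeights(1.0, 1.0, 1.0),
            H.TrainConfig(epochs=10, m=20, seed=seed),
        )
        test_set = [p for p in prepared if p.patient_id in split.test_patients]
        report = H.evaluate(ckpt, test_set)
        results[seed] = {
            "config": cfg,
            "prepared": prepared,
            "split": split,
            "checkpoint": ckpt,
            "history": history,
            "report": report,
        }
    return results
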