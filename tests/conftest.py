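"""Shared fixtures: a small simulated cohort reused across test modules."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pleuroflow import annotation, matrix, sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    return sim.SimConfig(n_patients=3, cells_per_patient=250, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cm, truth = sim.simulate_mpe(small_config)
    return cm, truth


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    cm, _ = small_cohort
    return matrix.lognormalize(cm)


@pytest.fixture(scope="session")
def truth_annotation(small_cohort):
    """Annotation seeded with the ground-truth labels (no gate applied)."""
    cm, truth = small_cohort
    return annotation.annotation_from_labels(truth.true_labels(), cm.cell_meta)


def toy_count_matrix(counts: np.ndarray, symbols=None, chromosome="1") -> matrix.CountMatrix:
    """Build a minimal CountMatrix around a dense genes x cells array."""
    g, c = counts.shape
    symbols = symbols or [f"G{i}" for i in range(g)]
    gene_meta = pd.DataFrame(
        {"symbol": symbols, "chromosome": chromosome, "start": np.arange(1, g + 1) * 100}
    )
    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(c)],
            "patient": "P1",
            "sample": "P1",
            "enriched": False,
        }
    )
    return matrix.CountMatrix(sp.csr_matrix(counts), gene_meta, cell_meta)


def toy_norm_matrix(values: np.ndarray, symbols=None, patients=None) -> matrix.NormMatrix:
    """Build a minimal NormMatrix around a dense genes x cells array."""
    g, c = values.shape
    symbols = symbols or [f"G{i}" for i in range(g)]
    gene_meta = pd.DataFrame(
        {"symbol": symbols, "chromosome": "1", "start": np.arange(1, g + 1) * 100}
    )
    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(c)],
            "patient": patients if patients is not None else ["P1"] * c,
            "sample": "P1",
            "enriched": False,
        }
    )
    return matrix.NormMatrix(sp.csr_matrix(values), gene_meta, cell_meta)
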