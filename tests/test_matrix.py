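"""Matrix core: IO round-trips, QC, normalization, aggregation, descriptives."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from pleuroflow import annotation, matrix

from conftest import toy_count_matrix, toy_norm_matrix


# ---------------------------------------------------------------------------
# MatrixMarket IO
# ---------------------------------------------------------------------------

def test_count_matrix_roundtrip_toy(tmp_path):
    cm = toy_count_matrix(np.array([[1, 0], [0, 3], [2, 2]]))
    paths = matrix.write_count_matrix(cm, tmp_path)
    back = matrix.read_count_matrix(paths["mtx"], paths["genes"], paths["barcodes"])
    assert (back.counts != cm.counts).nnz == 0
    pd.testing.assert_frame_equal(back.gene_meta, cm.gene_meta)
    pd.testing.assert_frame_equal(back.cell_meta, cm.cell_meta)


def test_count_matrix_roundtrip_simulated(tmp_path, small_cohort):
    cm, _ = small_cohort
    paths = matrix.write_count_matrix(cm, tmp_path)
    back = matrix.read_count_matrix(paths["mtx"], paths["genes"], paths["barcodes"])
    a, b = cm.counts.tocoo(), back.counts.tocoo()
    assert (a.row == b.row).all() and (a.col == b.col).all()
    assert (a.data == b.data).all()


def test_dimension_mismatch_rejected(tmp_path):
    cm = toy_count_matrix(np.array([[1, 0], [0, 3]]))
    paths = matrix.write_count_matrix(cm, tmp_path)
    barcodes = pd.read_csv(paths["barcodes"], sep="\t").iloc[:1]
    barcodes.to_csv(paths["barcodes"], sep="\t", index=False)
    with pytest.raises(ValueError, match="dimension mismatch"):
        matrix.read_count_matrix(paths["mtx"], paths["genes"], paths["barcodes"])


@pytest.mark.parametrize(
    "counts, message",
    [
        (np.array([[-1, 0], [0, 1]]), "negative"),
        (np.array([[0.5, 0], [0, 1]]), "non-integer"),
    ],
)
def test_invalid_counts_rejected(counts, message):
    with pytest.raises(ValueError, match=message):
        toy_count_matrix(counts)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate gene symbol"):
        toy_count_matrix(np.eye(2, dtype=int), symbols=["A", "A"])


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_identity_with_permissive_thresholds(small_cohort):
    cm, _ = small_cohort
    out = matrix.qc_filter(cm, min_genes_per_cell=0, max_mito_frac=1.0)
    assert out.n_cells == cm.n_cells


def test_qc_removes_all_mito_cell():
    counts = np.array([[0, 5], [0, 5], [9, 1]])  # cell 1 is ~91% mito
    cm = toy_count_matrix(counts, symbols=["MT-CO1", "MT-ND1", "ACTB"])
    out = matrix.qc_filter(cm, min_genes_per_cell=0, max_mito_frac=0.5)
    assert list(out.cell_meta["cell_id"]) == ["c0"]


def test_qc_removes_exactly_planted_low_depth_cells(small_cohort):
    cm, _ = small_cohort
    rng = np.random.default_rng(0)
    dense = cm.counts.toarray()
    victim = rng.choice(cm.n_cells, size=10, replace=False)
    for c in victim:
        keep = rng.choice(cm.n_genes, size=20, replace=False)
        col = np.zeros(cm.n_genes, dtype=dense.dtype)
        col[keep] = 1
        dense[:, c] = col
    dirty = matrix.CountMatrix(sp.csr_matrix(dense), cm.gene_meta, cm.cell_meta)
    out = matrix.qc_filter(dirty, min_genes_per_cell=100, max_mito_frac=1.0)
    removed = set(cm.cell_meta["cell_id"]) - set(out.cell_meta["cell_id"])
    assert removed == set(cm.cell_meta["cell_id"].iloc[victim])


def test_qc_idempotent(small_cohort):
    cm, _ = small_cohort
    once = matrix.qc_filter(cm, 100, 0.3)
    twice = matrix.qc_filter(once, 100, 0.3)
    assert list(twice.cell_meta["cell_id"]) == list(once.cell_meta["cell_id"])


def test_qc_threshold_validation(small_cohort):
    cm, _ = small_cohort
    with pytest.raises(ValueError):
        matrix.qc_filter(cm, min_genes_per_cell=-1)
    with pytest.raises(ValueError):
        matrix.qc_filter(cm, max_mito_frac=1.5)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_lognormalize_closed_form():
    cm = toy_count_matrix(np.array([[1], [1]]))
    n = matrix.lognormalize(cm)
    expected = np.log2(1 + 1e4 * 1 / 2)
    assert n.values.toarray() == pytest.approx(np.full((2, 1), expected))


def test_lognormalize_preserves_zeros(small_norm, small_cohort):
    cm, _ = small_cohort
    assert small_norm.values.nnz == cm.counts.nnz
    assert small_norm.values.min() >= 0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 50), min_size=4, max_size=12),
    factor=st.integers(2, 9),
)
def test_lognormalize_scale_invariance(counts, factor):
    """Multiplying a cell's counts by any factor leaves its profile unchanged."""
    col = np.array(counts)[:, None]
    if col.sum() == 0:
        col[0, 0] = 1
    a = matrix.lognormalize(toy_count_matrix(col)).values.toarray()
    b = matrix.lognormalize(toy_count_matrix(col * factor)).values.toarray()
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_lognormalize_rejects_empty_cell():
    cm = toy_count_matrix(np.array([[1, 0], [1, 0]]))
    with pytest.raises(ValueError, match="c1"):
        matrix.lognormalize(cm)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _two_blob_norm(n_per=100, seed=0):
    rng = np.random.default_rng(seed)
    g = 60
    centers = np.zeros((g, 2))
    centers[:20, 0] = 5.0
    centers[20:40, 1] = 5.0
    blob = np.repeat([0, 1], n_per)
    x = np.abs(centers[:, blob] + rng.normal(0, 0.3, (g, 2 * n_per)))
    return toy_norm_matrix(x), blob


def test_cluster_separates_two_blobs():
    n, blob = _two_blob_norm()
    labels = matrix.cluster_cells(n, n_pcs=10, k_neighbors=15, resolution=0.3, seed=0)
    tab = pd.crosstab(labels.to_numpy(), blob)
    # each cluster maps to exactly one blob and covers it completely
    assert labels.nunique() == 2
    assert (tab.max(axis=1) == tab.sum(axis=1)).all()


def test_cluster_deterministic_under_seed():
    n, _ = _two_blob_norm(seed=4)
    a = matrix.cluster_cells(n, n_pcs=10, k_neighbors=15, seed=9)
    b = matrix.cluster_cells(n, n_pcs=10, k_neighbors=15, seed=9)
    assert (a == b).all()


def test_cluster_identical_cells_single_cluster():
    x = np.tile(np.arange(30, dtype=float)[:, None], (1, 40))
    n = toy_norm_matrix(x)
    labels = matrix.cluster_cells(n, k_neighbors=10, seed=0)
    assert labels.nunique() == 1


def test_cluster_rejects_too_few_cells():
    n, _ = _two_blob_norm(n_per=5)
    with pytest.raises(ValueError, match="k_neighbors"):
        matrix.cluster_cells(n, k_neighbors=20)


# ---------------------------------------------------------------------------
# Pseudo-bulk aggregation
# ---------------------------------------------------------------------------

def test_pseudobulk_single_cell_group():
    cm = toy_count_matrix(np.array([[1, 4], [2, 5], [3, 6]]))
    pb = matrix.pseudobulk_aggregate(cm, {"c0": "solo"})
    assert list(pb.counts["solo"]) == [1, 2, 3]
    assert pb.sample_meta["n_cells"].iloc[0] == 1


def test_pseudobulk_conserves_totals(small_cohort):
    cm, truth = small_cohort
    grouping = pd.Series(
        np.where(np.arange(cm.n_cells) % 2 == 0, "even", "odd"),
        index=cm.cell_ids,
    )
    pb = matrix.pseudobulk_aggregate(cm, grouping)
    total = pb.counts.sum(axis=1).to_numpy()
    np.testing.assert_array_equal(
        total, np.asarray(cm.counts.sum(axis=1)).ravel()
    )


def test_pseudobulk_matches_bruteforce_three_way(small_cohort):
    cm, _ = small_cohort
    rng = np.random.default_rng(5)
    part = rng.integers(0, 3, size=cm.n_cells)
    grouping = pd.Series([f"g{p}" for p in part], index=cm.cell_ids)
    pb = matrix.pseudobulk_aggregate(cm, grouping)
    dense = cm.counts.toarray()
    for i in range(3):
        expected = dense[:, part == i].sum(axis=1)
        np.testing.assert_array_equal(pb.counts[f"g{i}"].to_numpy(), expected)


def test_pseudobulk_rejects_unknown_cell(small_cohort):
    cm, _ = small_cohort
    with pytest.raises(KeyError, match="ghost"):
        matrix.pseudobulk_aggregate(cm, {"ghost": "g"})


# ---------------------------------------------------------------------------
# Composition, prevalence, profile correlation
# ---------------------------------------------------------------------------

def test_composition_half_and_half():
    ann = annotation.annotation_from_labels(
        pd.Series({"a": "T", "b": "T", "c": "B", "d": "B"}),
        pd.DataFrame({"cell_id": list("abcd"), "patient": "P1"}),
    )
    tab = matrix.composition_table(ann)
    assert dict(zip(tab["cell_type"], tab["fraction"])) == {"B": 0.5, "T": 0.5}


def test_composition_recovers_truth_exactly(small_cohort, truth_annotation):
    _, truth = small_cohort
    tab = matrix.composition_table(truth_annotation)
    expected = truth.cells.groupby(["patient", "cell_type"]).size()
    for _, row in tab.iterrows():
        assert row["n_cells"] == expected[(row["patient"], row["cell_type"])]
    sums = tab.groupby("patient")["fraction"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_prevalence_extremes():
    values = np.array(
        [[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 0.0, 0.0]]
    )  # G0 silent, G1 only in T cells
    n = toy_norm_matrix(values)
    ann = annotation.annotation_from_labels(
        pd.Series({"c0": "T", "c1": "T", "c2": "B", "c3": "B"}),
        n.cell_meta,
    )
    prev = matrix.expression_prevalence(n, ann, ["G0", "G1"])
    assert prev.loc["T", "G0"] == 0.0 and prev.loc["B", "G0"] == 0.0
    assert prev.loc["T", "G1"] == 1.0 and prev.loc["B", "G1"] == 0.0


def test_prevalence_missing_gene_rejected(small_norm, truth_annotation):
    with pytest.raises(KeyError, match="NOPE"):
        matrix.expression_prevalence(small_norm, truth_annotation, ["NOPE"])


def test_prevalence_marker_panels_dominant(small_norm, truth_annotation, small_config):
    prev = matrix.expression_prevalence(
        small_norm, truth_annotation, list(small_config.marker_panels["mesothelial"])
    )
    meso = prev.loc["mesothelial"]
    for other in prev.index:
        if other != "mesothelial":
            assert (meso > prev.loc[other]).all()


def test_profile_correlation_identical_and_reversed_groups():
    rng = np.random.default_rng(0)
    base = rng.normal(size=30)
    x = np.column_stack([base, base, -base, -base])
    n = toy_norm_matrix(np.abs(x.min()) + x, patients=["P1", "P2", "P1", "P2"])
    ann = annotation.annotation_from_labels(
        pd.Series({"c0": "T", "c1": "T", "c2": "B", "c3": "B"}), n.cell_meta
    )
    corr, order = matrix.celltype_profile_correlation(n, ann)
    assert corr.loc["P1|T", "P2|T"] == pytest.approx(1.0)
    assert corr.loc["P1|T", "P1|B"] == pytest.approx(-1.0)
    assert sorted(order) == sorted(corr.index)


def test_profile_correlation_matches_scipy(small_norm, truth_annotation):
    corr, _ = matrix.celltype_profile_correlation(small_norm, truth_annotation)
    # brute-force oracle on three groups
    tab = truth_annotation.active_table()
    groups = list(corr.index)[:3]
    profs = []
    for g in groups:
        patient, label = g.split("|")
        cells = tab.index[(tab["patient"] == patient) & (tab["label"] == label)]
        pos = small_norm.cell_positions(cells)
        profs.append(np.asarray(small_norm.values[:, pos].mean(axis=1)).ravel())
    for i in range(3):
        for j in range(i + 1, 3):
            rho = spearmanr(profs[i], profs[j]).statistic
            assert corr.loc[groups[i], groups[j]] == pytest.approx(rho, abs=1e-12)
    np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
    np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0, atol=1e-12)
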