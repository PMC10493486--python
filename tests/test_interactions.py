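"""Ligand-receptor ranking, directional filtering and stratified testing."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pleuroflow import annotation, interactions, matrix, sim
from pleuroflow.signatures import GeneSet, score_signatures

from conftest import toy_norm_matrix


def _two_type_stats(rng, genes=12, per_type=20):
    """Random fixture with 'sender'/'receiver' labelled cells."""
    x = np.abs(rng.normal(0, 1.5, (genes, 2 * per_type)))
    x[x < 0.8] = 0.0
    n = toy_norm_matrix(x)
    labels = pd.Series(
        ["mesothelial"] * per_type + ["malignant"] * per_type, index=n.cell_ids
    )
    ann = annotation.annotation_from_labels(labels, n.cell_meta)
    return n, ann, x


def test_expression_stats_extremes():
    x = np.zeros((2, 6))
    x[0, :3] = 2.0  # G0 expressed in every mesothelial cell only
    n = toy_norm_matrix(x)
    ann = annotation.annotation_from_labels(
        pd.Series(["mesothelial"] * 3 + ["malignant"] * 3, index=n.cell_ids),
        n.cell_meta,
    )
    stats = interactions.expression_stats_by_type(n, ann, ["G0", "G1"])
    assert stats.fraction.loc["mesothelial", "G0"] == 1.0
    assert stats.fraction.loc["malignant", "G0"] == 0.0
    assert stats.fraction.loc["mesothelial", "G1"] == 0.0
    assert stats.mean_log.loc["malignant", "G1"] == 0.0


def test_expression_stats_match_bruteforce():
    rng = np.random.default_rng(0)
    n, ann, x = _two_type_stats(rng)
    genes = [f"G{i}" for i in range(12)]
    stats = interactions.expression_stats_by_type(n, ann, genes)
    for label, cols in (("mesothelial", slice(0, 20)), ("malignant", slice(20, 40))):
        for i, g in enumerate(genes):
            block = x[i, cols]
            assert stats.fraction.loc[label, g] == pytest.approx((block > 0).mean())
            assert stats.mean_log.loc[label, g] == pytest.approx(block.mean())


def test_expression_stats_missing_gene_rejected(small_norm, truth_annotation):
    with pytest.raises(KeyError, match="GHOST"):
        interactions.expression_stats_by_type(small_norm, truth_annotation, ["GHOST"])


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _toy_db(n=20, seed=1):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        lig, rec = rng.choice(12, 2, replace=False)
        rows.append((f"LR{i:02d}", f"G{lig}", f"G{rec}"))
    return pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor"])


def test_ranking_matches_bruteforce_toy_db():
    rng = np.random.default_rng(2)
    n, ann, _ = _two_type_stats(rng)
    db = _toy_db()
    genes = [f"G{i}" for i in range(12)]
    stats = interactions.expression_stats_by_type(n, ann, genes)
    edges = interactions.rank_lr_interactions(stats, db, "mesothelial", "malignant", k=20)
    expected = []
    for _, r in db.iterrows():
        score = (
            stats.fraction.loc["mesothelial", r["ligand"]]
            * stats.mean_log.loc["mesothelial", r["ligand"]]
            * stats.fraction.loc["malignant", r["receptor"]]
            * stats.mean_log.loc["malignant", r["receptor"]]
        )
        expected.append((r["pair_id"], score))
    expected.sort(key=lambda t: (-t[1], t[0]))
    assert list(edges["pair_id"]) == [pid for pid, _ in expected]
    np.testing.assert_allclose(edges["score"], [s for _, s in expected], atol=1e-12)


def test_ranking_invariant_to_db_row_order():
    rng = np.random.default_rng(3)
    n, ann, _ = _two_type_stats(rng)
    db = _toy_db()
    stats = interactions.expression_stats_by_type(n, ann, [f"G{i}" for i in range(12)])
    a = interactions.rank_lr_interactions(stats, db, "mesothelial", "malignant", k=10)
    b = interactions.rank_lr_interactions(
        stats, db.sample(frac=1.0, random_state=9), "mesothelial", "malignant", k=10
    )
    pd.testing.assert_frame_equal(a, b)


def test_zero_fraction_ligand_scores_zero():
    x = np.zeros((3, 4))
    x[1] = 1.0
    x[2] = 2.0
    n = toy_norm_matrix(x)
    ann = annotation.annotation_from_labels(
        pd.Series(["mesothelial"] * 2 + ["malignant"] * 2, index=n.cell_ids),
        n.cell_meta,
    )
    db = pd.DataFrame(
        {"pair_id": ["a", "b"], "ligand": ["G0", "G1"], "receptor": ["G2", "G2"]}
    )
    stats = interactions.expression_stats_by_type(n, ann, ["G0", "G1", "G2"])
    edges = interactions.rank_lr_interactions(stats, db, "mesothelial", "malignant", k=1)
    assert list(edges["pair_id"]) == ["b"]  # the zero-score pair never makes top-k


def test_absent_gene_pairs_dropped_and_bad_k_rejected():
    rng = np.random.default_rng(4)
    n, ann, _ = _two_type_stats(rng)
    db = pd.DataFrame(
        {"pair_id": ["ok", "bad"], "ligand": ["G0", "MISSING"], "receptor": ["G1", "G2"]}
    )
    stats = interactions.expression_stats_by_type(n, ann, [f"G{i}" for i in range(12)])
    edges = interactions.rank_lr_interactions(stats, db, "mesothelial", "malignant", k=10)
    assert list(edges["pair_id"]) == ["ok"]
    with pytest.raises(ValueError):
        interactions.rank_lr_interactions(stats, db, "mesothelial", "malignant", k=0)


# ---------------------------------------------------------------------------
# Directional filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "f_sender, f_receiver, flagged",
    [(0.6, 0.01, True), (0.6, 0.6, False), (0.0, 0.0, False), (0.10, 0.05, True)],
)
def test_directional_predicate(f_sender, f_receiver, flagged):
    stats = interactions.TypeExpressionStats(
        fraction=pd.DataFrame(
            {"L": [f_sender, f_receiver], "R": [0.1, 0.5]},
            index=["mesothelial", "malignant"],
        ),
        mean_log=pd.DataFrame(
            {"L": [1.0, 0.1], "R": [0.2, 1.0]}, index=["mesothelial", "malignant"]
        ),
    )
    edges = pd.DataFrame(
        [{
            "pair_id": "p", "ligand": "L", "receptor": "R",
            "sender": "mesothelial", "receiver": "malignant",
            "ligand_fraction": f_sender, "ligand_mean": 1.0,
            "receptor_fraction": 0.5, "receptor_mean": 1.0, "score": 1.0,
        }]
    )
    out = interactions.filter_directional_pairs(edges, stats)
    assert out["directional"].iloc[0] == flagged


# ---------------------------------------------------------------------------
# Stratification and downstream testing
# ---------------------------------------------------------------------------

def test_stratify_all_zero_receptor_all_negative():
    x = np.zeros((2, 5))
    x[1] = 1.0
    n = toy_norm_matrix(x)
    ann = annotation.annotation_from_labels(
        pd.Series("malignant", index=n.cell_ids), n.cell_meta
    )
    part = interactions.stratify_by_receptor(n, ann, "G0", "malignant")
    assert (~part).all()
    assert len(part) == 5  # disjoint cover of all receiver cells


def test_stratify_matches_planted_truth_exactly(small_cohort, small_norm, truth_annotation):
    _, truth = small_cohort
    part = interactions.stratify_by_receptor(
        small_norm, truth_annotation, "FGFR2", "malignant"
    )
    assert set(part.index[part]) == set(truth.receptor_positive_cells)
    mal = truth.cells[truth.cells["cell_type"] == "malignant"]
    assert set(part.index) == set(mal["cell_id"])


def test_stratify_missing_receptor_rejected(small_norm, truth_annotation):
    with pytest.raises(KeyError, match="GHOST"):
        interactions.stratify_by_receptor(small_norm, truth_annotation, "GHOST", "malignant")


def test_signalling_null_is_flat():
    rng = np.random.default_rng(5)
    idx = pd.Index([f"c{i}" for i in range(400)])
    scores = pd.DataFrame({"s": rng.uniform(size=400)}, index=idx)
    part = pd.Series([True] * 200 + [False] * 200, index=idx)
    libs = pd.Series(rng.lognormal(10, 0.3, 400), index=idx)
    res = interactions.test_signalling_activity(scores, part, libs)
    assert 0.05 < res["set_pvalues"]["s"] < 0.95


def test_signalling_detects_planted_shift():
    rng = np.random.default_rng(6)
    idx = pd.Index([f"c{i}" for i in range(400)])
    base = rng.uniform(size=400)
    base[:200] += 0.15
    scores = pd.DataFrame({"s": base}, index=idx)
    part = pd.Series([True] * 200 + [False] * 200, index=idx)
    libs = pd.Series(rng.lognormal(10, 0.3, 400), index=idx)
    res = interactions.test_signalling_activity(scores, part, libs)
    assert res["set_pvalues"]["s"] < 0.01
    assert not res["libsize_confound"]["warn"]


def test_signalling_confound_flag_rarely_fires_under_null():
    rng = np.random.default_rng(7)
    idx = pd.Index([f"c{i}" for i in range(200)])
    warns = 0
    for _ in range(100):
        scores = pd.DataFrame({"s": rng.uniform(size=200)}, index=idx)
        part = pd.Series(rng.uniform(size=200) < 0.3, index=idx)
        if part.sum() == 0 or (~part).sum() == 0:
            continue
        libs = pd.Series(rng.lognormal(10, 0.3, 200), index=idx)
        res = interactions.test_signalling_activity(scores, part, libs)
        warns += res["libsize_confound"]["warn"]
    assert warns <= 10


def test_signalling_rejects_empty_side():
    idx = pd.Index(["a", "b"])
    scores = pd.DataFrame({"s": [0.1, 0.2]}, index=idx)
    part = pd.Series([True, True], index=idx)
    libs = pd.Series([1.0, 2.0], index=idx)
    with pytest.raises(ValueError, match="non-empty"):
        interactions.test_signalling_activity(scores, part, libs)


def test_planted_circuit_recovered_end_to_end(small_cohort, small_norm, small_config, truth_annotation):
    """Planted FGF2->FGFR2 chain: top-k, directional, active downstream."""
    cm, truth = small_cohort
    db = sim.make_lr_database(small_config, n_pairs=120, seed=9)
    genes = sorted((set(db["ligand"]) | set(db["receptor"])) & set(small_norm.gene_symbols))
    stats = interactions.expression_stats_by_type(small_norm, truth_annotation, genes)
    edges = interactions.rank_lr_interactions(stats, db, "mesothelial", "malignant", k=40)
    edges = interactions.filter_directional_pairs(edges, stats)
    row = edges[edges["pair_id"] == "LR_FGF2_FGFR2"]
    assert len(row) == 1
    assert row["directional"].iloc[0]
    part = interactions.stratify_by_receptor(small_norm, truth_annotation, "FGFR2", "malignant")
    pos = small_norm.cell_positions(part.index)
    sub = matrix.NormMatrix(
        small_norm.values[:, pos],
        small_norm.gene_meta,
        small_norm.cell_meta.iloc[pos].reset_index(drop=True),
    )
    scores = score_signatures(sub, [GeneSet("ds", sim.FGF_DOWNSTREAM)])
    libs = cm.libsizes().loc[part.index]
    res = interactions.test_signalling_activity(scores, part, libs)
    assert res["set_pvalues"]["ds"] < 1e-10


def test_graph_export_roundtrip():
    rng = np.random.default_rng(8)
    n, ann, _ = _two_type_stats(rng)
    db = _toy_db(n=8)
    stats = interactions.expression_stats_by_type(n, ann, [f"G{i}" for i in range(12)])
    edges = interactions.rank_lr_interactions(stats, db, "mesothelial", "malignant", k=8)
    g = interactions.to_graph(edges)
    assert g.number_of_edges() == len(edges)
    for _, _, data in g.edges(data=True):
        assert data["score"] >= 0
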