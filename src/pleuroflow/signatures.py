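"""Rank-based per-cell signature scoring and pseudo-bulk subtype calls.

The signature score is a normalized mean-rank statistic (singscore-like):
within each cell, all genes are ranked by expression (average ranks on ties,
so the zeros share the lowest ranks), and the mean rank of the set genes is
rescaled by the minimum and maximum attainable mean rank to land in [0, 1].
The score is therefore invariant under any strictly monotone transform of a
cell's expression vector. Genes absent from the matrix are dropped (and
logged), not zero-imputed.

Molecular subtype calls on pseudo-bulk profiles are nearest-centroid by
Spearman correlation against a pluggable centroid table (breast-cancer
intrinsic subtypes in the shipped toy fixture: LumA, LumB, Her2, Basal,
Normal-like).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._utils import spearman_vs_centroids
from .matrix import NormMatrix, PseudoBulk

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (unique, at least two)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"gene set {self.name!r} needs >= 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


@dataclass(frozen=True)
class CentroidTable:
    """Subtype centroids over a common gene space, with a label vocabulary."""

    table: pd.DataFrame  # genes x subtypes
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.table.columns) != set(self.vocabulary):
            raise ValueError("centroid columns must match the vocabulary")


def score_signature(n: NormMatrix, gene_set: GeneSet) -> pd.Series:
    """Normalized mean-rank signature score per cell, in [0, 1]."""
    present = [g for g in gene_set.genes if g in set(n.gene_symbols)]
    absent = sorted(set(gene_set.genes) - set(present))
    if not present:
        raise ValueError(
            f"no gene of set {gene_set.name!r} present in the matrix"
        )
    if absent:
        log.info(
            "score_signature(%s): dropped %d absent genes (first: %r)",
            gene_set.name, len(absent), absent[0],
        )
    x = n.dense()
    ranks = rankdata(x, axis=0)  # per-cell ranks over all genes, ties averaged
    gidx = n.gene_symbols.get_indexer(present)
    s = len(present)
    g = n.n_genes
    mean_rank = ranks[gidx].mean(axis=0)
    lo = (s + 1) / 2.0
    hi = g - (s - 1) / 2.0
    score = (mean_rank - lo) / (hi - lo)
    return pd.Series(score, index=n.cell_ids, name=gene_set.name)


def score_signatures(n: NormMatrix, sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Cells x sets score frame (see :func:`score_signature`)."""
    return pd.DataFrame({gs.name: score_signature(n, gs) for gs in sets})


def classify_pseudobulk_subtype(
    pb: PseudoBulk | pd.DataFrame,
    centroids: CentroidTable,
    min_shared_genes: int = 50,
) -> pd.DataFrame:
    """Nearest-centroid Spearman subtype call per pseudo-bulk sample.

    Accepts a :class:`PseudoBulk` or a plain genes x samples log-expression
    frame. Ties break by the centroid table's vocabulary order. Returns a
    frame indexed by sample with the call and the full correlation vector.
    """
    profile = pb.logcpm if isinstance(pb, PseudoBulk) else pb
    shared = profile.index.intersection(centroids.table.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids; "
            f"need >= {min_shared_genes}"
        )
    vocab = list(centroids.vocabulary)
    rho = spearman_vs_centroids(
        profile.loc[shared].to_numpy(), centroids.table.loc[shared, vocab].to_numpy()
    )
    best = np.argmax(rho, axis=1)  # first index wins ties -> vocabulary order
    out = pd.DataFrame(rho, index=profile.columns, columns=vocab)
    out.insert(0, "subtype", [vocab[i] for i in best])
    return out


def split_clusters_by_gene(
    n: NormMatrix, clustering: Mapping[str, object] | pd.Series, gene: str
) -> tuple[dict[str, str], pd.Series]:
    """Partition clusters into high/low expressors of one gene.

    A cluster is 'high' iff its mean log-expression of ``gene`` strictly
    exceeds the across-cluster midpoint (the mean of cluster means); with
    identical means everything is 'low'. Returns the assignment and the
    per-cluster means.
    """
    clustering = (
        pd.Series(dict(clustering)) if not isinstance(clustering, pd.Series) else clustering
    )
    values = pd.Series(n.gene_values(gene), index=n.cell_ids)  # KeyError if absent
    clusters = sorted(clustering.map(str).unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to split")
    means = pd.Series(
        {c: values[clustering.index[clustering.map(str) == c]].mean() for c in clusters}
    )
    midpoint = means.mean()
    assignment = {c: ("high" if means[c] > midpoint else "low") for c in clusters}
    return assignment, means
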