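"""Core containers and operations for gene x cell count data.

The central object is :class:`CountMatrix`: a sparse genes x cells integer
count matrix with gene metadata (symbol, chromosome, 1-based start position)
and cell metadata (cell id, patient, sample, enrichment flag). Normalization
follows the log counts-per-10K convention: ``log2(1 + 1e4 * count / libsize)``,
so a zero count maps to exactly 0 and the transform is invariant to per-cell
scaling of the raw counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, leaves_list
from scipy.io import mmread, mmwrite
from scipy.spatial.distance import squareform

from ._utils import spearman_matrix

log = logging.getLogger(__name__)

GENE_META_COLUMNS = ("symbol", "chromosome", "start")
CELL_META_COLUMNS = ("cell_id", "patient", "sample", "enriched")


def _check_unique(values: pd.Series, what: str) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {what}: {dup.iloc[0]!r}")


@dataclass
class CountMatrix:
    """Sparse genes x cells raw integer counts with gene and cell metadata."""

    counts: sp.csr_matrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_meta), len(self.cell_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with metadata "
                f"({len(self.gene_meta)} genes, {len(self.cell_meta)} cells)"
            )
        for col in GENE_META_COLUMNS:
            if col not in self.gene_meta.columns:
                raise ValueError(f"gene_meta missing column {col!r}")
        for col in CELL_META_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing column {col!r}")
        _check_unique(self.gene_meta["symbol"], "gene symbol")
        _check_unique(self.cell_meta["cell_id"], "cell_id")
        starts = self.gene_meta["start"]
        bad = starts[starts.notna() & (starts < 1)]
        if len(bad):
            raise ValueError(
                f"gene start must be >= 1 (1-based bp); offender "
                f"{self.gene_meta.loc[bad.index[0], 'symbol']!r}"
            )
        if self.counts.nnz:
            data = self.counts.data
            if np.any(data < 0):
                g, c = self._locate_entry(np.flatnonzero(data < 0)[0])
                raise ValueError(f"negative count at gene {g!r}, cell {c!r}")
            if not np.issubdtype(data.dtype, np.integer):
                if np.any(data != np.round(data)):
                    g, c = self._locate_entry(
                        np.flatnonzero(data != np.round(data))[0]
                    )
                    raise ValueError(
                        f"non-integer count at gene {g!r}, cell {c!r}"
                    )
                self.counts = self.counts.astype(np.int64)
        self.gene_meta = self.gene_meta.reset_index(drop=True)
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    def _locate_entry(self, data_idx: int) -> tuple[str, str]:
        coo = self.counts.tocoo()
        return (
            self.gene_meta["symbol"].iloc[coo.row[data_idx]],
            self.cell_meta["cell_id"].iloc[coo.col[data_idx]],
        )

    # -- conveniences -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_symbols(self) -> pd.Index:
        return pd.Index(self.gene_meta["symbol"])

    @property
    def cell_ids(self) -> pd.Index:
        return pd.Index(self.cell_meta["cell_id"])

    def gene_index(self, symbol: str) -> int:
        idx = self.gene_symbols.get_indexer([symbol])
        if idx[0] < 0:
            raise KeyError(f"gene {symbol!r} not in matrix")
        return int(idx[0])

    def libsizes(self) -> pd.Series:
        total = np.asarray(self.counts.sum(axis=0)).ravel()
        return pd.Series(total, index=self.cell_ids, name="libsize")

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        pos = self.cell_ids.get_indexer(cell_ids)
        if np.any(pos < 0):
            missing = np.asarray(cell_ids)[pos < 0][0]
            raise KeyError(f"unknown cell {missing!r}")
        return CountMatrix(
            self.counts[:, pos].tocsr(),
            self.gene_meta.copy(),
            self.cell_meta.iloc[pos].reset_index(drop=True),
        )


@dataclass
class NormMatrix:
    """log2(1 + counts-per-10K) values with provenance to the source counts."""

    values: sp.csr_matrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame
    source: CountMatrix | None = field(default=None, repr=False)
    _dense: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def gene_symbols(self) -> pd.Index:
        return pd.Index(self.gene_meta["symbol"])

    @property
    def cell_ids(self) -> pd.Index:
        return pd.Index(self.cell_meta["cell_id"])

    def gene_index(self, symbol: str) -> int:
        idx = self.gene_symbols.get_indexer([symbol])
        if idx[0] < 0:
            raise KeyError(f"gene {symbol!r} not in matrix")
        return int(idx[0])

    def dense(self) -> np.ndarray:
        """Dense genes x cells array, cached after first materialization."""
        if self._dense is None:
            self._dense = self.values.toarray()
        return self._dense

    def gene_values(self, symbol: str) -> np.ndarray:
        return np.asarray(self.values[self.gene_index(symbol)].todense()).ravel()

    def cell_positions(self, cell_ids: Sequence[str]) -> np.ndarray:
        pos = self.cell_ids.get_indexer(cell_ids)
        if np.any(pos < 0):
            missing = np.asarray(cell_ids)[pos < 0][0]
            raise KeyError(f"unknown cell {missing!r}")
        return pos


@dataclass
class PseudoBulk:
    """Group-aggregated counts and log2(CPM+1) profiles.

    ``counts`` and ``logcpm`` are genes x samples frames sharing columns with
    ``sample_meta`` (one row per sample: sample name, patient, group label and
    the number of member cells).
    """

    counts: pd.DataFrame
    logcpm: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.sample_meta["n_cells"] < 1).any():
            bad = self.sample_meta.loc[self.sample_meta["n_cells"] < 1, "sample"]
            raise ValueError(f"pseudo-bulk sample with no cells: {bad.iloc[0]!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_meta["sample"])


# ---------------------------------------------------------------------------
# MatrixMarket + TSV sidecar IO
# ---------------------------------------------------------------------------

def write_count_matrix(m: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write counts as MatrixMarket coordinate (1-based) plus TSV sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "counts.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    mmwrite(paths["mtx"], m.counts.tocoo(), field="integer")
    m.gene_meta[list(GENE_META_COLUMNS)].to_csv(paths["genes"], sep="\t", index=False)
    m.cell_meta[list(CELL_META_COLUMNS)].to_csv(
        paths["barcodes"], sep="\t", index=False
    )
    return paths


def read_count_matrix(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> CountMatrix:
    """Read a MatrixMarket count matrix with genes/barcodes TSV sidecars."""
    counts = sp.csr_matrix(mmread(mtx_path))
    gene_meta = pd.read_csv(genes_path, sep="\t", dtype={"chromosome": str})
    cell_meta = pd.read_csv(barcodes_path, sep="\t")
    if counts.shape[0] != len(gene_meta):
        raise ValueError(
            f"dimension mismatch: matrix has {counts.shape[0]} rows but "
            f"{genes_path} lists {len(gene_meta)} genes"
        )
    if counts.shape[1] != len(cell_meta):
        raise ValueError(
            f"dimension mismatch: matrix has {counts.shape[1]} columns but "
            f"{barcodes_path} lists {len(cell_meta)} cells"
        )
    return CountMatrix(counts, gene_meta, cell_meta)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    m: CountMatrix,
    min_genes_per_cell: int = 200,
    max_mito_frac: float = 0.2,
    mito_prefix: str = "MT-",
) -> CountMatrix:
    """Drop cells with too few detected genes or too high a mitochondrial load.

    Genes are never removed; the operation is idempotent. Mitochondrial genes
    are identified by symbol prefix (default ``MT-``).
    """
    if min_genes_per_cell < 0:
        raise ValueError("min_genes_per_cell must be >= 0")
    if not 0.0 <= max_mito_frac <= 1.0:
        raise ValueError("max_mito_frac must be in [0, 1]")
    detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    total = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    mito_mask = m.gene_meta["symbol"].str.startswith(mito_prefix).to_numpy()
    mito = np.asarray(m.counts[mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
    keep = (detected >= min_genes_per_cell) & (mito_frac <= max_mito_frac)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "qc_filter removed %d/%d cells (min_genes=%d, max_mito=%.3g)",
            n_dropped, m.n_cells, min_genes_per_cell, max_mito_frac,
        )
    return CountMatrix(
        m.counts[:, keep].tocsr(),
        m.gene_meta.copy(),
        m.cell_meta.loc[keep].reset_index(drop=True),
    )


def lognormalize(m: CountMatrix, scale: float = 1e4) -> NormMatrix:
    """Per-cell library-size normalization to log2(1 + counts-per-10K)."""
    total = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    if np.any(total == 0):
        bad = m.cell_meta["cell_id"].iloc[int(np.flatnonzero(total == 0)[0])]
        raise ValueError(f"cell {bad!r} has zero total count; run qc_filter first")
    x = m.counts.tocsc().astype(float)
    percol = np.repeat(scale / total, np.diff(x.indptr))
    x.data = np.log2(1.0 + x.data * percol)
    return NormMatrix(x.tocsr(), m.gene_meta.copy(), m.cell_meta.copy(), source=m)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_cells(
    n: NormMatrix,
    cells_subset: Sequence[str] | None = None,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    seed: int = 0,
    resolution: float = 0.8,
    n_hvgs: int = 2000,
) -> pd.Series:
    """Leiden community detection on a kNN graph in PC space of scaled HVGs.

    Highly variable genes are the top ``n_hvgs`` by variance of the
    log-normalized values. Deterministic for a fixed seed. Returns a Series
    mapping cell_id to an integer cluster label.
    """
    import scanpy as sc
    from anndata import AnnData

    if cells_subset is None:
        pos = np.arange(n.n_cells)
        ids = n.cell_ids
    else:
        pos = n.cell_positions(cells_subset)
        ids = pd.Index(cells_subset)
    if len(pos) <= k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={k_neighbors} cells, got {len(pos)}"
        )
    x = n.values[:, pos].T.tocsr()  # cells x genes
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = sq - mean**2
    # tolerance absorbs cancellation error for constant (identical-cell) input
    if var.max() <= 1e-10 * max(1.0, float(np.max(np.abs(mean)) ** 2)):
        # all cells identical in expression: one cluster
        return pd.Series(np.zeros(len(pos), dtype=int), index=ids, name="cluster")
    hvg = np.sort(np.argsort(var)[::-1][: min(n_hvgs, x.shape[1])])
    ad = AnnData(x[:, hvg].toarray())
    sc.pp.scale(ad, max_value=10)
    n_comps = int(min(n_pcs, ad.n_obs - 1, ad.n_vars - 1))
    sc.tl.pca(ad, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(ad, n_neighbors=k_neighbors, random_state=seed)
    sc.tl.leiden(
        ad,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    labels = ad.obs["leiden"].astype(int).to_numpy()
    return pd.Series(labels, index=ids, name="cluster")


# ---------------------------------------------------------------------------
# Pseudo-bulk aggregation
# ---------------------------------------------------------------------------

def _sample_name(key: Hashable) -> str:
    if isinstance(key, tuple):
        return "|".join(str(k) for k in key)
    return str(key)


def pseudobulk_aggregate(
    m: CountMatrix, grouping: Mapping[str, Hashable] | pd.Series
) -> PseudoBulk:
    """Sum counts over cell groups; log2(CPM+1) computed on the group sums.

    ``grouping`` maps cell_id -> group key. A ``(patient, group)`` tuple key
    is split into the patient/group columns of ``sample_meta``; any other key
    is stored as the group label alone. Cells absent from ``grouping`` are
    left out; groups are emitted in sorted order of their name.
    """
    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    pos = m.cell_ids.get_indexer(grouping.index)
    if np.any(pos < 0):
        missing = grouping.index[pos < 0][0]
        raise KeyError(f"cell {missing!r} in grouping but not in matrix")
    key_list = list(grouping.values)
    name_arr = np.array([_sample_name(k) for k in key_list])
    key_by_name = {name_arr[i]: key_list[i] for i in range(len(key_list))}
    names, patients, groups, ncells = [], [], [], []
    cols = {}
    for name in sorted(key_by_name):
        member_pos = pos[name_arr == name]
        key = key_by_name[name]
        names.append(name)
        if isinstance(key, tuple) and len(key) == 2:
            patients.append(str(key[0]))
            groups.append(str(key[1]))
        else:
            patients.append(None)
            groups.append(str(key))
        ncells.append(len(member_pos))
        cols[name] = np.asarray(m.counts[:, member_pos].sum(axis=1)).ravel()
    counts = pd.DataFrame(cols, index=m.gene_symbols)
    totals = counts.sum(axis=0).astype(float)
    logcpm = np.log2(1.0 + counts / totals * 1e6)
    meta = pd.DataFrame(
        {"sample": names, "patient": patients, "group": groups, "n_cells": ncells}
    )
    return PseudoBulk(counts=counts, logcpm=logcpm, sample_meta=meta)


# ---------------------------------------------------------------------------
# Descriptive tables
# ---------------------------------------------------------------------------

def composition_table(ann) -> pd.DataFrame:
    """Per-patient cell-type composition (absolute counts and fractions).

    Gate-excluded cells are left out; rows for each patient sum to 1.
    Patients with no retained cells are absent.
    """
    tab = ann.active_table()
    rows = []
    for patient, sub in tab.groupby("patient", sort=True):
        n_total = len(sub)
        for label, n in sub["label"].value_counts().sort_index().items():
            rows.append(
                {
                    "patient": patient,
                    "cell_type": label,
                    "n_cells": int(n),
                    "fraction": n / n_total,
                }
            )
    return pd.DataFrame(rows, columns=["patient", "cell_type", "n_cells", "fraction"])


def expression_prevalence(
    n: NormMatrix, ann, genes: Sequence[str]
) -> pd.DataFrame:
    """Fraction of cells per type with non-zero expression of each gene."""
    gidx = [n.gene_index(g) for g in genes]  # raises naming missing symbol
    tab = ann.active_table()
    pos = n.cell_positions(tab.index)
    x = n.values[gidx][:, pos]
    nonzero = (x > 0).toarray()
    out = {}
    labels = tab["label"].to_numpy()
    for label in sorted(set(labels)):
        mask = labels == label
        out[label] = nonzero[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=list(genes)).T


def celltype_profile_correlation(
    n: NormMatrix, ann
) -> tuple[pd.DataFrame, list[str]]:
    """Spearman correlations between per-(patient, type) mean profiles.

    Returns the symmetric unit-diagonal correlation matrix and the leaf order
    of an average-linkage hierarchical clustering with 1 - rho distance.
    """
    tab = ann.active_table()
    groups = []
    profiles = []
    for (patient, label), sub in tab.groupby(["patient", "label"], sort=True):
        if len(sub) < 1:
            raise ValueError(f"group ({patient}, {label}) has no cells")
        pos = n.cell_positions(sub.index)
        profiles.append(np.asarray(n.values[:, pos].mean(axis=1)).ravel())
        groups.append(f"{patient}|{label}")
    if len(groups) < 2:
        raise ValueError("need at least 2 (patient, type) groups")
    prof = np.column_stack(profiles)
    rho = spearman_matrix(prof)
    rho = (rho + rho.T) / 2.0
    dist = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average(squareform(dist, checks=False)))
    corr = pd.DataFrame(rho, index=groups, columns=groups)
    return corr, [groups[i] for i in order]
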