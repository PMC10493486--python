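"""Small numeric helpers shared across modules."""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests


def split_seed(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _standardize_columns(ranks: np.ndarray) -> np.ndarray:
    """Z-score each column; constant columns map to all-zero columns."""
    mu = ranks.mean(axis=0, keepdims=True)
    sd = ranks.std(axis=0, keepdims=True)
    z = np.zeros_like(ranks, dtype=float)
    nz = sd[0] > 0
    z[:, nz] = (ranks[:, nz] - mu[:, nz]) / sd[:, nz]
    return z


def spearman_vs_centroids(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Spearman correlation of every column of ``x`` with every centroid column.

    Parameters
    ----------
    x:
        genes x observations dense array.
    centroids:
        genes x k dense array over the same gene axis.

    Returns
    -------
    observations x k array of rank correlations. A constant observation (or
    centroid) yields 0 against everything rather than NaN.
    """
    rx = rankdata(x, axis=0)
    rc = rankdata(centroids, axis=0)
    zx = _standardize_columns(rx)
    zc = _standardize_columns(rc)
    return (zx.T @ zc) / x.shape[0]


def spearman_matrix(profiles: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix between columns of a genes x m array."""
    r = rankdata(profiles, axis=0)
    z = _standardize_columns(r)
    m = (z.T @ z) / profiles.shape[0]
    np.fill_diagonal(m, 1.0)
    return m
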