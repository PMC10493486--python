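"""Expression-based copy-number inference along genomic gene order.

Malignant cells carry somatic copy-number aberrations that shift the average
expression of contiguous runs of genes; mesothelial and immune cells do not.
The estimator here is the minimal well-defined variant of expression-CNV
inference:

1. subtract the per-gene mean of a baseline of known non-malignant cells;
2. centre each cell by its median residual (removes per-cell offsets);
3. moving average along genomic gene order within each chromosome, with
   shrinking (asymmetric) windows at chromosome ends;
4. clamp to +/- ``clamp`` (default 1.0 log2 units).

Gains appear as positive plateaus, losses as negative ones.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import NormMatrix

log = logging.getLogger(__name__)

_CHROM_SORT = {c: i for i, c in enumerate([str(i) for i in range(1, 23)] + ["X"])}


@dataclass(frozen=True)
class GenomicOrder:
    """Genes ordered by (chromosome 1..22,X; start position)."""

    symbols: tuple[str, ...]
    chromosomes: tuple[str, ...]
    boundaries: Mapping[str, tuple[int, int]]  # chrom -> [start, stop) in order

    def chrom_slice(self, chromosome: str) -> slice:
        lo, hi = self.boundaries[str(chromosome)]
        return slice(lo, hi)


@dataclass
class CnvMatrix:
    """Cells x ordered-genes smoothed baseline-relative log-ratios."""

    values: np.ndarray  # cells x genes, |value| <= clamp
    cell_ids: tuple[str, ...]
    order: GenomicOrder
    window: int
    clamp: float
    baseline: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.cell_ids), columns=list(self.order.symbols)
        )


def build_genomic_order(gene_meta: pd.DataFrame) -> GenomicOrder:
    """Deterministic genomic ordering; genes without coordinates are dropped."""
    meta = gene_meta.copy()
    known = meta["chromosome"].astype(str).isin(_CHROM_SORT)
    has_coord = meta["start"].notna() & known
    dropped = meta.loc[~has_coord, "symbol"]
    if len(dropped):
        log.info(
            "build_genomic_order dropped %d genes without usable coordinates "
            "(first: %r)", len(dropped), dropped.iloc[0],
        )
    meta = meta[has_coord]
    meta = meta.assign(_ck=meta["chromosome"].astype(str).map(_CHROM_SORT))
    meta = meta.sort_values(["_ck", "start", "symbol"], kind="mergesort")
    symbols = tuple(meta["symbol"])
    chroms = tuple(meta["chromosome"].astype(str))
    boundaries: dict[str, tuple[int, int]] = {}
    i = 0
    while i < len(chroms):
        j = i
        while j < len(chroms) and chroms[j] == chroms[i]:
            j += 1
        boundaries[chroms[i]] = (i, j)
        i = j
    return GenomicOrder(symbols=symbols, chromosomes=chroms, boundaries=boundaries)


def moving_average_genomic(x: np.ndarray, order: GenomicOrder, window: int) -> np.ndarray:
    """Windowed mean along gene order within each chromosome.

    ``x`` is cells x ordered-genes. Windows shrink asymmetrically at
    chromosome ends; ``window`` must be odd and >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for chrom, (lo, hi) in order.boundaries.items():
        block = x[:, lo:hi]
        g = hi - lo
        cs = np.concatenate(
            [np.zeros((x.shape[0], 1)), np.cumsum(block, axis=1)], axis=1
        )
        starts = np.maximum(np.arange(g) - half, 0)
        stops = np.minimum(np.arange(g) + half + 1, g)
        out[:, lo:hi] = (cs[:, stops] - cs[:, starts]) / (stops - starts)
    return out


def infer_cnv_matrix(
    n: NormMatrix,
    order: GenomicOrder,
    baseline_cells: Sequence[str],
    cells: Sequence[str] | None = None,
    window: int = 101,
    clamp: float = 1.0,
) -> CnvMatrix:
    """Smoothed baseline-relative log-ratio profiles along the genome.

    ``baseline_cells`` is the reference of known non-malignant cells (immune
    labels by default in the pipeline); ``cells`` restricts scoring to a
    subset (default: all cells of the matrix).
    """
    if len(baseline_cells) == 0:
        raise ValueError("baseline_cells must be non-empty")
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    gidx = n.gene_symbols.get_indexer(order.symbols)
    if np.any(gidx < 0):
        missing = np.asarray(order.symbols)[gidx < 0][0]
        raise KeyError(f"ordered gene {missing!r} absent from matrix")
    base_pos = n.cell_positions(baseline_cells)
    if cells is None:
        target_ids = list(n.cell_ids)
        target_pos = np.arange(n.n_cells)
    else:
        target_ids = list(cells)
        target_pos = n.cell_positions(cells)
    dense = n.dense()
    ordered = dense[gidx]
    baseline_mean = ordered[:, base_pos].mean(axis=1)
    r = ordered[:, target_pos].T - baseline_mean  # cells x genes
    r = r - np.median(r, axis=1, keepdims=True)
    smooth = moving_average_genomic(r, order, window)
    np.clip(smooth, -clamp, clamp, out=smooth)
    return CnvMatrix(
        values=smooth,
        cell_ids=tuple(target_ids),
        order=order,
        window=window,
        clamp=clamp,
        baseline=f"mean of {len(base_pos)} baseline cells",
    )


def summarize_cnv_regions(
    cnv: CnvMatrix,
    ann,
    regions: Sequence[tuple[str, int, int]],
    tau: float = 0.15,
) -> pd.DataFrame:
    """Aggregate CNV signal per (patient, type) over genomic regions.

    Regions are (chromosome, start_index, end_index) with indices into the
    chromosome's ordered genes, end exclusive. Reports the group mean signal
    and the fraction of cells whose region-mean magnitude exceeds ``tau``.
    """
    tab = ann.active_table()
    shared = tab.index.intersection(list(cnv.cell_ids))
    tab = tab.loc[shared]
    cell_pos = {c: i for i, c in enumerate(cnv.cell_ids)}
    rows = []
    for chrom, start, end in regions:
        lo, hi = cnv.order.boundaries[str(chrom)]
        if not (0 <= start < end <= hi - lo):
            raise ValueError(
                f"empty or out-of-range region chr{chrom}[{start}:{end}]"
            )
        cols = slice(lo + start, lo + end)
        for (patient, label), sub in tab.groupby(["patient", "label"], sort=True):
            pos = [cell_pos[c] for c in sub.index]
            per_cell = cnv.values[pos, cols].mean(axis=1)
            rows.append(
                {
                    "patient": patient,
                    "cell_type": label,
                    "region": f"chr{chrom}[{start}:{end}]",
                    "n_cells": len(pos),
                    "mean_signal": float(per_cell.mean()),
                    "fraction_above_tau": float((np.abs(per_cell) > tau).mean()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "cell_type", "region", "n_cells",
            "mean_signal", "fraction_above_tau",
        ],
    )


def subsample_cells_per_cluster(
    groups: Mapping[str, object] | pd.Series, per_cluster: int, seed: int = 0
) -> list[str]:
    """Uniform subsample of up to ``per_cluster`` cells from each group.

    ``groups`` maps cell_id -> group key (e.g. (patient, cluster)). Sampling
    is without replacement and deterministic for a fixed seed.
    """
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    names = groups.map(str)
    for name in sorted(names.unique()):
        members = sorted(groups.index[names == name])
        if len(members) <= per_cluster:
            chosen.extend(members)
        else:
            pick = rng.choice(len(members), size=per_cluster, replace=False)
            chosen.extend(members[i] for i in sorted(pick))
    return chosen
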