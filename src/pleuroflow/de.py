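"""Pseudo-bulk differential expression and over-representation analysis.

Testing happens on aggregated (pseudo-bulk) samples, never on single cells,
so patients are the unit of replication. Per gene the engine is a Welch
two-sample t-test on log2(CPM+1) profiles, or a paired t-test across
patient-matched samples; multiple testing is controlled by Benjamini-Hochberg
throughout. Pathway over-representation uses the hypergeometric upper tail.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ttest_ind, ttest_rel

from ._utils import bh_adjust
from .matrix import PseudoBulk
from .signatures import GeneSet


def pseudobulk_de(
    pb: PseudoBulk,
    group1: Sequence[str],
    group2: Sequence[str],
    paired_by_patient: bool = False,
) -> pd.DataFrame:
    """Per-gene DE between two sets of pseudo-bulk samples.

    ``group1``/``group2`` name samples of ``pb``. log2 fold-change is the
    group1 minus group2 mean log2-CPM. Genes with zero counts in every
    selected sample are dropped before testing; BH-FDR is computed over the
    tested genes. Paired mode matches samples by patient and requires the
    same patients on both sides.
    """
    samples = set(pb.samples)
    for s in list(group1) + list(group2):
        if s not in samples:
            raise KeyError(f"unknown pseudo-bulk sample {s!r}")
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(group1)} vs {len(group2)}"
        )
    g1 = list(group1)
    g2 = list(group2)
    if paired_by_patient:
        meta = pb.sample_meta.set_index("sample")
        p1 = meta.loc[g1, "patient"]
        p2 = meta.loc[g2, "patient"]
        if p1.isna().any() or p2.isna().any():
            raise ValueError("paired mode requires patient metadata on samples")
        if sorted(p1) != sorted(p2):
            raise ValueError(
                f"paired mode requires matched patients; got {sorted(p1)} vs {sorted(p2)}"
            )
        g1 = list(pd.Series(g1, index=p1.values).sort_index())
        g2 = list(pd.Series(g2, index=p2.values).sort_index())
    tested = pb.counts[g1 + g2].sum(axis=1) > 0
    x1 = pb.logcpm.loc[tested, g1].to_numpy()
    x2 = pb.logcpm.loc[tested, g2].to_numpy()
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    if paired_by_patient:
        res = ttest_rel(x1, x2, axis=1)
    else:
        res = ttest_ind(x1, x2, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate genes (zero variance on both sides): no evidence when the
    # means agree, overwhelming evidence otherwise
    bad = ~np.isfinite(p)
    p[bad & (logfc == 0)] = 1.0
    p[bad & (logfc != 0)] = 0.0
    t[~np.isfinite(t)] = 0.0
    out = pd.DataFrame(
        {
            "gene": pb.counts.index[tested],
            "log2fc": logfc,
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
        }
    ).reset_index(drop=True)
    return out


def top_table(de: pd.DataFrame, k: int = 20, alpha: float = 0.05) -> dict[str, list[str]]:
    """Top-``k`` up/down genes by t-statistic among FDR-significant genes."""
    sig = de[de["fdr"] < alpha]
    up = sig[sig["t"] > 0].sort_values(["t", "gene"], ascending=[False, True])
    down = sig[sig["t"] < 0].sort_values(["t", "gene"], ascending=[True, True])
    return {"up": list(up["gene"].head(k)), "down": list(down["gene"].head(k))}


@dataclass(frozen=True)
class EnrichmentResult:
    table: pd.DataFrame

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.table.head(k)


def ora_enrich(
    query: Sequence[str],
    universe: Sequence[str],
    collection: Sequence[GeneSet],
) -> EnrichmentResult:
    """Hypergeometric over-representation of each gene set in the query.

    ``query`` must be a subset of ``universe``; sets are intersected with the
    universe before testing. The p-value is the upper tail
    P(overlap >= observed). Results are BH-adjusted and sorted by p.
    """
    uni = set(universe)
    q = set(query)
    if not q or not uni:
        raise ValueError("query and universe must be non-empty")
    stray = q - uni
    if stray:
        raise ValueError(f"query gene {sorted(stray)[0]!r} not in universe")
    m_total = len(uni)
    n_query = len(q)
    rows = []
    for gs in collection:
        members = set(gs.genes) & uni
        overlap = len(members & q)
        p = float(hypergeom.sf(overlap - 1, m_total, len(members), n_query))
        rows.append(
            {
                "set": gs.name,
                "overlap": overlap,
                "set_size": len(members),
                "universe_size": m_total,
                "query_size": n_query,
                "p": p,
            }
        )
    tab = pd.DataFrame(rows).sort_values(["p", "set"], kind="mergesort")
    tab["fdr"] = bh_adjust(tab["p"].to_numpy())
    with np.errstate(divide="ignore"):
        tab["neglog10_p"] = -np.log10(tab["p"])
    return EnrichmentResult(table=tab.reset_index(drop=True))
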