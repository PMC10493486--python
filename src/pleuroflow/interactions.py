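"""Directed ligand-receptor inference between cell populations.

Candidate interactions are ranked by a product of the two per-node statistics
used to draw such networks: the fraction of cells expressing a gene and its
mean log-expression, for the ligand in the sender population and the receptor
in the receiver population:

    score = (frac_sender(L) * mean_sender(L)) * (frac_receiver(R) * mean_receiver(R))

A directional filter keeps pairs whose ligand is expressed by the sender but
essentially absent from the receiver, pointing to a directed flow of
information (mesothelial -> malignant in the default pipeline). Receiver
cells can then be stratified by receptor positivity and downstream signature
activity compared between the strata, with a library-size confound check.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import mannwhitneyu

from .matrix import NormMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TypeExpressionStats:
    """Per-(type, gene) expressing fraction and mean log-expression."""

    fraction: pd.DataFrame  # types x genes, in [0, 1]
    mean_log: pd.DataFrame  # types x genes

    def __post_init__(self) -> None:
        f = self.fraction.to_numpy()
        if f.size and (f.min() < 0 or f.max() > 1):
            raise ValueError("expressing fractions must lie in [0, 1]")


def load_lr_database(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a ligand-receptor table (pair_id, ligand, receptor)."""
    for col in ("pair_id", "ligand", "receptor"):
        if col not in df.columns:
            raise ValueError(f"LR database missing column {col!r}")
    if df["pair_id"].duplicated().any():
        dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise ValueError(f"duplicate pair id {dup!r}")
    if (df["ligand"].astype(str).str.len() == 0).any() or (
        df["receptor"].astype(str).str.len() == 0
    ).any():
        raise ValueError("empty gene symbol in LR database")
    return df.reset_index(drop=True)


def expression_stats_by_type(
    n: NormMatrix, ann, genes: Sequence[str]
) -> TypeExpressionStats:
    """Exact per-type expressing fractions and mean log-expression.

    Computed on the gated annotation (excluded cells do not contribute).
    """
    gidx = [n.gene_index(g) for g in genes]  # raises naming the symbol
    tab = ann.active_table()
    pos = n.cell_positions(tab.index)
    x = n.values[gidx][:, pos].toarray()
    labels = tab["label"].to_numpy()
    frac_rows, mean_rows, types = [], [], []
    for label in sorted(set(labels)):
        mask = labels == label
        types.append(label)
        frac_rows.append((x[:, mask] > 0).mean(axis=1))
        mean_rows.append(x[:, mask].mean(axis=1))
    return TypeExpressionStats(
        fraction=pd.DataFrame(frac_rows, index=types, columns=list(genes)),
        mean_log=pd.DataFrame(mean_rows, index=types, columns=list(genes)),
    )


def rank_lr_interactions(
    stats: TypeExpressionStats,
    db: pd.DataFrame,
    sender: str,
    receiver: str,
    k: int = 100,
) -> pd.DataFrame:
    """Top-``k`` ligand-receptor edges from sender to receiver.

    Pairs whose ligand or receptor is absent from the statistics are dropped
    with a log entry. Ties in score break by pair id, so the edge list is
    deterministic and invariant to database row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    db = load_lr_database(db)
    known = set(stats.fraction.columns)
    usable = db[db["ligand"].isin(known) & db["receptor"].isin(known)]
    n_dropped = len(db) - len(usable)
    if n_dropped:
        log.info("rank_lr_interactions dropped %d pairs with absent genes", n_dropped)
    rows = []
    for _, r in usable.iterrows():
        fl = float(stats.fraction.loc[sender, r["ligand"]])
        ml = float(stats.mean_log.loc[sender, r["ligand"]])
        fr = float(stats.fraction.loc[receiver, r["receptor"]])
        mr = float(stats.mean_log.loc[receiver, r["receptor"]])
        rows.append(
            {
                "pair_id": r["pair_id"],
                "ligand": r["ligand"],
                "receptor": r["receptor"],
                "sender": sender,
                "receiver": receiver,
                "ligand_fraction": fl,
                "ligand_mean": ml,
                "receptor_fraction": fr,
                "receptor_mean": mr,
                "score": (fl * ml) * (fr * mr),
            }
        )
    edges = pd.DataFrame(rows)
    edges = edges.sort_values(
        ["score", "pair_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return edges.head(k)


def filter_directional_pairs(
    edges: pd.DataFrame,
    stats: TypeExpressionStats,
    sender_on: float = 0.10,
    receiver_off: float = 0.05,
) -> pd.DataFrame:
    """Flag edges whose ligand is sender-expressed but receiver-silent.

    An edge is directional iff the ligand's expressing fraction is at least
    ``sender_on`` in the sender type and at most ``receiver_off`` in the
    receiver type.
    """
    out = edges.copy()
    flags = []
    for _, r in out.iterrows():
        f_send = float(stats.fraction.loc[r["sender"], r["ligand"]])
        f_recv = float(stats.fraction.loc[r["receiver"], r["ligand"]])
        flags.append(bool(f_send >= sender_on and f_recv <= receiver_off))
    out["directional"] = flags
    return out


def stratify_by_receptor(
    n: NormMatrix, ann, receptor: str, receiver_type: str
) -> pd.Series:
    """Boolean receptor-positive partition over the gated receiver cells."""
    values = pd.Series(n.gene_values(receptor), index=n.cell_ids)
    receiver_cells = ann.cells_of_type(receiver_type)
    if len(receiver_cells) == 0:
        raise ValueError(f"no gated cells of type {receiver_type!r}")
    return (values.loc[receiver_cells] > 0).rename("receptor_positive")


def test_signalling_activity(
    scores: pd.DataFrame,
    partition: pd.Series,
    libsizes: pd.Series,
    patients: pd.Series | None = None,
) -> dict:
    """Compare downstream signature scores between receptor strata.

    Returns one-sided Wilcoxon rank-sum p-values (positive > negative) per
    score column, a library-size confound report (two-sided rank-sum between
    strata, flagged when p < 0.05), and per-patient median scores per side
    when patient labels are supplied.
    """
    cells_pos = partition.index[partition.astype(bool)]
    cells_neg = partition.index[~partition.astype(bool)]
    if len(cells_pos) == 0 or len(cells_neg) == 0:
        raise ValueError(
            f"both strata must be non-empty (positive={len(cells_pos)}, "
            f"negative={len(cells_neg)})"
        )
    pvals = {}
    for name in scores.columns:
        s_pos = scores.loc[cells_pos, name]
        s_neg = scores.loc[cells_neg, name]
        pvals[name] = float(
            mannwhitneyu(s_pos, s_neg, alternative="greater").pvalue
        )
    lib_p = float(
        mannwhitneyu(
            libsizes.loc[cells_pos], libsizes.loc[cells_neg], alternative="two-sided"
        ).pvalue
    )
    per_patient = None
    if patients is not None:
        rows = []
        pats = patients.loc[partition.index]
        for patient in sorted(pats.unique()):
            in_pat = pats.index[pats == patient]
            for side, cells in (("positive", cells_pos), ("negative", cells_neg)):
                sel = in_pat.intersection(cells)
                if len(sel) == 0:
                    continue
                for name in scores.columns:
                    rows.append(
                        {
                            "patient": patient,
                            "side": side,
                            "set": name,
                            "n_cells": len(sel),
                            "median_score": float(scores.loc[sel, name].median()),
                        }
                    )
        per_patient = pd.DataFrame(
            rows, columns=["patient", "side", "set", "n_cells", "median_score"]
        )
    return {
        "set_pvalues": pvals,
        "libsize_confound": {"p": lib_p, "warn": lib_p < 0.05},
        "per_patient_medians": per_patient,
    }


def to_graph(edges: pd.DataFrame):
    """Directed graph of the edge list (networkx), for graph tooling export."""
    import networkx as nx

    g = nx.DiGraph()
    for _, r in edges.iterrows():
        lig = f"{r['sender']}:{r['ligand']}"
        rec = f"{r['receiver']}:{r['receptor']}"
        g.add_node(lig, gene=r["ligand"], cell_type=r["sender"],
                   fraction=r["ligand_fraction"], mean_log=r["ligand_mean"])
        g.add_node(rec, gene=r["receptor"], cell_type=r["receiver"],
                   fraction=r["receptor_fraction"], mean_log=r["receptor_mean"])
        g.add_edge(lig, rec, pair_id=r["pair_id"], score=r["score"],
                   directional=bool(r.get("directional", False)))
    return g
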