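"""Cell-type annotation: consensus reference voting, marker gates, T cells.

Malignant pleural effusions mix carcinoma cells with mesothelial cells that
share much of their phenotype (keratins, VIM, CD44), so automated annotation
alone is unreliable. The workflow here is:

1. nearest-centroid Spearman annotation against one or more pluggable
   reference profiles (:func:`reference_correlation_annotate`);
2. a modal-vote consensus across references (:func:`consensus_annotate`);
3. a hard marker gate on the non-immune labels: malignant cells must express
   EPCAM, mesothelial cells must express DES (desmin) and not EPCAM, with a
   two-marker panel fallback when the primary gate gene is not detected
   (:func:`gate_nonimmune_cells`);
4. CD4/CD8 calling and nearest-centroid T-subtype projection, with removal of
   cells whose CD4/CD8 expression contradicts the projected subtype.

"Expressed" everywhere means raw count >= 1 (equivalently a positive
log-normalized value).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._utils import bh_adjust, spearman_vs_centroids
from .matrix import NormMatrix

log = logging.getLogger(__name__)

CELL_TYPE_LABELS = (
    "malignant",
    "mesothelial",
    "T",
    "NK",
    "B",
    "myeloid",
    "DC",
    "unassigned",
)

T_SUBTYPES = (
    "CD8 Naïve-like",
    "CD8 Early Active",
    "CD8 Effector Memory",
    "Th1",
    "Tfh",
    "CD4 Naïve-like",
    "CD8 Tex",
    "CD8 Tpex",
    "Treg",
)

# conflict sets for the CD4/CD8 vs projected-subtype discordance rule
_CD8_SUBTYPE_CONFLICTS = ("CD8 Naïve-like", "CD8 Early Active", "CD8 Effector Memory")
_CD4_SUBTYPE_CONFLICTS = ("Th1", "Tfh", "CD4 Naïve-like")

GATE_STATUSES = ("passed", "fallback", "excluded", "not_gated")

# prefixes removed from data-driven marker lists
_MARKER_EXCLUDE_PREFIXES = ("MT-", "RPL", "RPS")


@dataclass(frozen=True)
class MarkerPanel:
    """Discriminatory marker panels for the epithelial/mesothelial gate."""

    epithelial: tuple[str, ...] = (
        "CLDN4", "IMP3", "MUC1", "CDH1", "CEACAM5", "SCGB2A2", "CLDN3", "CLDN7",
    )
    mesothelial: tuple[str, ...] = (
        "CALB2", "WT1", "UPK3B", "CDH2", "COL1A2", "S100A4", "MSLN",
    )
    overlapping: tuple[str, ...] = ("KRT8", "KRT19", "VIM", "CD44", "ACTB")
    gate_epithelial: str = "EPCAM"
    gate_mesothelial: str = "DES"

    def __post_init__(self) -> None:
        panels = [set(self.epithelial), set(self.mesothelial), set(self.overlapping)]
        for i in range(3):
            for j in range(i + 1, 3):
                common = panels[i] & panels[j]
                if common:
                    raise ValueError(f"marker panels overlap: {sorted(common)}")


@dataclass(frozen=True)
class ReferenceProfile:
    """Named reference of per-type mean log-expression centroids."""

    name: str
    profiles: pd.DataFrame  # genes x types

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError(f"reference {self.name!r} needs >= 2 types")
        if not np.all(np.isfinite(self.profiles.to_numpy())):
            raise ValueError(f"reference {self.name!r} contains non-finite values")

    @property
    def types(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class CellAnnotation:
    """Per-cell label, gate status, T-subtype and CD4/CD8 call.

    ``table`` is indexed by cell_id with columns ``label``, ``patient``,
    ``gate_status``, ``t_subtype`` and ``cd_class``. Gate-excluded cells keep
    their original label for bookkeeping but carry no downstream label: all
    consumers go through :meth:`active_table`.
    """

    table: pd.DataFrame
    votes: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for col, default in (
            ("gate_status", "not_gated"),
            ("t_subtype", None),
            ("cd_class", None),
        ):
            if col not in self.table.columns:
                self.table[col] = default
        bad = set(self.table["label"]) - set(CELL_TYPE_LABELS)
        if bad:
            raise ValueError(f"labels outside fixed vocabulary: {sorted(bad)}")
        bad_status = set(self.table["gate_status"]) - set(GATE_STATUSES)
        if bad_status:
            raise ValueError(f"unknown gate status: {sorted(bad_status)}")

    @property
    def cell_ids(self) -> pd.Index:
        return self.table.index

    def active_table(self) -> pd.DataFrame:
        """Rows for cells that were not gated out."""
        return self.table[self.table["gate_status"] != "excluded"]

    def cells_of_type(self, label: str, gated_only: bool = True) -> pd.Index:
        tab = self.active_table() if gated_only else self.table
        return tab.index[tab["label"] == label]

    def copy(self) -> "CellAnnotation":
        return CellAnnotation(
            self.table.copy(), None if self.votes is None else self.votes.copy()
        )


def annotation_from_labels(
    labels: Mapping[str, str] | pd.Series, cell_meta: pd.DataFrame | None = None
) -> CellAnnotation:
    """Build a CellAnnotation from a plain cell -> label mapping."""
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    tab = pd.DataFrame({"label": labels})
    tab.index.name = "cell_id"
    if cell_meta is not None:
        patients = cell_meta.set_index("cell_id")["patient"]
        tab["patient"] = patients.reindex(tab.index)
    else:
        tab["patient"] = "unknown"
    return CellAnnotation(tab)


# ---------------------------------------------------------------------------
# Reference annotation and consensus
# ---------------------------------------------------------------------------

def reference_correlation_annotate(
    n: NormMatrix,
    ref: ReferenceProfile,
    min_shared_genes: int = 50,
    low_confidence_rho: float = 0.1,
) -> pd.DataFrame:
    """Label every cell with its nearest reference centroid by Spearman rho.

    Ties are broken lexicographically by type name. Returns a frame indexed
    by cell_id with columns ``label``, ``rho`` and ``low_confidence``
    (rho < 0.1).
    """
    shared = n.gene_symbols.intersection(ref.profiles.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared with reference {ref.name!r}; "
            f"need >= {min_shared_genes}"
        )
    gidx = n.gene_symbols.get_indexer(shared)
    x = n.values[gidx].toarray()
    types = sorted(ref.types)
    c = ref.profiles.loc[shared, types].to_numpy()
    rho = spearman_vs_centroids(x, c)  # cells x types
    best = np.argmax(rho, axis=1)  # argmax takes first (lexicographic) on ties
    best_rho = rho[np.arange(len(best)), best]
    return pd.DataFrame(
        {
            "label": [types[i] for i in best],
            "rho": best_rho,
            "low_confidence": best_rho < low_confidence_rho,
        },
        index=n.cell_ids,
    )


def consensus_annotate(
    votes: Sequence[pd.Series | pd.DataFrame],
    cell_meta: pd.DataFrame | None = None,
    min_agreement: float = 0.5,
) -> CellAnnotation:
    """Modal-vote consensus across per-reference labelings.

    A cell keeps the modal label when its modal fraction reaches
    ``min_agreement`` (ties between equally common labels break
    lexicographically); otherwise it is 'unassigned'.
    """
    if len(votes) < 1:
        raise ValueError("need at least one labeling")
    series = [v["label"] if isinstance(v, pd.DataFrame) else v for v in votes]
    index = series[0].index
    for s in series[1:]:
        if not index.equals(s.index):
            raise ValueError("labelings cover different cell universes")
    vote_df = pd.DataFrame(
        {f"ref{i}": s for i, s in enumerate(series)}, index=index
    )
    arr = vote_df.to_numpy(dtype=object)
    labels = []
    for row in arr:
        uniq, counts = np.unique(row.astype(str), return_counts=True)
        top = counts.max()
        modal = sorted(uniq[counts == top])[0]
        labels.append(modal if top / len(row) >= min_agreement else "unassigned")
    ann = annotation_from_labels(pd.Series(labels, index=index), cell_meta)
    ann.votes = vote_df
    return ann


# ---------------------------------------------------------------------------
# Marker gate
# ---------------------------------------------------------------------------

def _positive(n: NormMatrix, symbol: str) -> np.ndarray:
    """Boolean expressed mask over all cells (raw count >= 1)."""
    try:
        return n.gene_values(symbol) > 0
    except KeyError:
        raise KeyError(f"gate/panel gene {symbol!r} absent from matrix")


def gate_nonimmune_cells(
    ann: CellAnnotation, n: NormMatrix, panel: MarkerPanel | None = None
) -> CellAnnotation:
    """Apply the EPCAM/DES gate to malignant and mesothelial labels.

    * malignant: kept when EPCAM is expressed ('passed'); when EPCAM is
      absent, kept when at least two epithelial panel markers are expressed
      ('fallback'); otherwise excluded.
    * mesothelial: kept when DES is expressed and EPCAM is not ('passed');
      when DES and EPCAM are both absent, kept when at least two mesothelial
      panel markers are expressed ('fallback'); any EPCAM-positive
      mesothelial cell is excluded.

    Immune labels are untouched; the gate never relabels a cell.
    """
    panel = panel or MarkerPanel()
    epcam = _positive(n, panel.gate_epithelial)
    des = _positive(n, panel.gate_mesothelial)
    epi_hits = np.zeros(n.n_cells, dtype=int)
    for g in panel.epithelial:
        epi_hits += _positive(n, g)
    meso_hits = np.zeros(n.n_cells, dtype=int)
    for g in panel.mesothelial:
        meso_hits += _positive(n, g)

    out = ann.copy()
    pos = n.cell_positions(out.table.index)
    lab = out.table["label"].to_numpy()
    status = out.table["gate_status"].to_numpy(dtype=object).copy()

    is_mal = lab == "malignant"
    is_mes = lab == "mesothelial"
    cell_epcam, cell_des = epcam[pos], des[pos]
    cell_epi, cell_meso = epi_hits[pos], meso_hits[pos]

    status[is_mal & cell_epcam] = "passed"
    status[is_mal & ~cell_epcam & (cell_epi >= 2)] = "fallback"
    status[is_mal & ~cell_epcam & (cell_epi < 2)] = "excluded"

    status[is_mes & cell_des & ~cell_epcam] = "passed"
    status[is_mes & ~cell_des & ~cell_epcam & (cell_meso >= 2)] = "fallback"
    status[is_mes & ~cell_des & ~cell_epcam & (cell_meso < 2)] = "excluded"
    status[is_mes & cell_epcam] = "excluded"

    out.table["gate_status"] = status
    n_excl = int((status == "excluded").sum())
    if n_excl:
        log.info("gate excluded %d non-immune cells", n_excl)
    return out


# ---------------------------------------------------------------------------
# T cells
# ---------------------------------------------------------------------------

def classify_t_cd4_cd8(n: NormMatrix, ann: CellAnnotation) -> CellAnnotation:
    """Call CD4/CD8 status for T cells from CD4, CD8A and CD8B expression.

    CD8: CD8A or CD8B expressed and CD4 not; CD4: CD4 expressed and neither
    CD8 gene; double: both sides positive; neither otherwise.
    """
    for g in ("CD4", "CD8A", "CD8B"):
        if g not in set(n.gene_symbols):
            raise KeyError(f"gene {g!r} absent from matrix")
    cd4 = _positive(n, "CD4")
    cd8 = _positive(n, "CD8A") | _positive(n, "CD8B")
    out = ann.copy()
    t_cells = out.cells_of_type("T", gated_only=False)
    pos = n.cell_positions(t_cells)
    call = np.where(
        cd8[pos] & ~cd4[pos], "CD8",
        np.where(cd4[pos] & ~cd8[pos], "CD4",
                 np.where(cd4[pos] & cd8[pos], "double", "neither")),
    )
    out.table.loc[t_cells, "cd_class"] = call
    return out


def project_t_subtypes(
    n: NormMatrix, ann: CellAnnotation, t_ref: ReferenceProfile
) -> CellAnnotation:
    """Assign every T cell the nearest T-subtype centroid by Spearman rho."""
    if t_ref.profiles.shape[1] == 0:
        raise ValueError("empty T-subtype reference")
    unknown = set(t_ref.types) - set(T_SUBTYPES)
    if unknown:
        raise ValueError(f"unknown T subtypes in reference: {sorted(unknown)}")
    out = ann.copy()
    t_cells = out.cells_of_type("T", gated_only=False)
    if len(t_cells) == 0:
        return out
    shared = n.gene_symbols.intersection(t_ref.profiles.index)
    gidx = n.gene_symbols.get_indexer(shared)
    pos = n.cell_positions(t_cells)
    x = n.values[gidx][:, pos].toarray()
    types = sorted(t_ref.types)
    rho = spearman_vs_centroids(x, t_ref.profiles.loc[shared, types].to_numpy())
    out.table.loc[t_cells, "t_subtype"] = [types[i] for i in np.argmax(rho, axis=1)]
    return out


def exclude_discordant_t(ann: CellAnnotation) -> CellAnnotation:
    """Exclude T cells whose CD4/CD8 call contradicts the projected subtype.

    CD4-positive cells projected to a CD8 subtype (CD8 Naïve-like, CD8 Early
    Active, CD8 Effector Memory) and CD8-positive cells projected to a CD4
    subtype (Th1, Tfh, CD4 Naïve-like) are excluded. Double-positive cells
    are retained whatever their projection. Idempotent.
    """
    out = ann.copy()
    tab = out.table
    is_t = tab["label"] == "T"
    cd4_conflict = is_t & (tab["cd_class"] == "CD4") & tab["t_subtype"].isin(
        _CD8_SUBTYPE_CONFLICTS
    )
    cd8_conflict = is_t & (tab["cd_class"] == "CD8") & tab["t_subtype"].isin(
        _CD4_SUBTYPE_CONFLICTS
    )
    out.table.loc[cd4_conflict | cd8_conflict, "gate_status"] = "excluded"
    return out


# ---------------------------------------------------------------------------
# Data-driven marker curation
# ---------------------------------------------------------------------------

def select_celltype_markers(
    n: NormMatrix,
    ann: CellAnnotation,
    min_cluster_size: int = 100,
    alpha: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], dict[str, list[str]]]:
    """One-vs-rest Wilcoxon marker selection with unique-gene assignment.

    Cell types with fewer than ``min_cluster_size`` cells are excluded from
    testing. Mitochondrial (MT-) and ribosomal (RPL/RPS) genes are removed
    up front. Per type, genes with BH-FDR < ``alpha`` and a positive effect
    (mean log-expression difference) are kept, ranked by the standardized
    rank-sum statistic. A gene significant for several types is assigned to
    the type with the larger effect; the overlaps are reported alongside.
    """
    tab = ann.active_table()
    tab = tab[~tab["label"].isin(["unassigned"])]
    sizes = tab["label"].value_counts()
    types = sorted(sizes.index[sizes >= min_cluster_size])
    if len(types) < 2:
        raise ValueError(
            f"need >= 2 cell types with >= {min_cluster_size} cells; "
            f"sizes: {sizes.to_dict()}"
        )
    keep_gene = ~n.gene_symbols.str.startswith(_MARKER_EXCLUDE_PREFIXES)
    genes = n.gene_symbols[keep_gene]
    gidx = np.flatnonzero(np.asarray(keep_gene))
    tested = tab[tab["label"].isin(types)]
    pos = n.cell_positions(tested.index)
    x = n.values[gidx][:, pos].toarray()
    labels = tested["label"].to_numpy()

    per_type: dict[str, pd.DataFrame] = {}
    for t in types:
        mask = labels == t
        a, b = x[:, mask], x[:, ~mask]
        res = mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
        n1, n2 = a.shape[1], b.shape[1]
        z = (res.statistic - n1 * n2 / 2.0) / np.sqrt(
            n1 * n2 * (n1 + n2 + 1) / 12.0
        )
        effect = a.mean(axis=1) - b.mean(axis=1)
        fdr = bh_adjust(res.pvalue)
        df = pd.DataFrame(
            {"gene": genes, "statistic": z, "p": res.pvalue, "fdr": fdr, "effect": effect}
        )
        df = df[(df["fdr"] < alpha) & (df["effect"] > 0)]
        per_type[t] = df.sort_values("statistic", ascending=False).reset_index(drop=True)

    # unique-gene assignment: a shared gene goes to the type with max effect
    owner: dict[str, str] = {}
    best_effect: dict[str, float] = {}
    claimed: dict[str, list[str]] = {}
    for t in types:
        for gene, eff in zip(per_type[t]["gene"], per_type[t]["effect"]):
            claimed.setdefault(gene, []).append(t)
            if gene not in owner or eff > best_effect[gene]:
                owner[gene] = t
                best_effect[gene] = eff
    overlaps = {g: ts for g, ts in claimed.items() if len(ts) > 1}
    markers = {
        t: per_type[t][per_type[t]["gene"].map(owner.get) == t].reset_index(drop=True)
        for t in types
    }
    return markers, overlaps
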