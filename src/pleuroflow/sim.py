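"""Synthetic malignant-pleural-effusion scRNA-seq data with known truth.

The generator emulates the structure of a breast-cancer MPE cohort: several
patients, six major cell types (malignant, mesothelial, T, NK, B, myeloid),
patient-specific copy-number segments in the malignant cells, shared immune
phenotypes across patients, a CAF-like transcriptional program in the
mesothelial cells, and a directed FGF2 -> FGFR2 ligand/receptor circuit from
mesothelial (sender) to malignant (receiver) cells.

Counts follow a negative-binomial model: for gene ``g`` in cell ``c``

    mean_gc = libsize_c * baseline_g * type_effect_g * cnv_fold_g * circuit_g

with per-cell library sizes drawn log-normally and gamma-Poisson sampling at
a fixed dispersion ``phi`` (variance = mean * (1 + phi * mean)). The gene
universe (symbols, chromosomes, 1-based start positions) is generated
procedurally; named marker/program genes are kept off the chromosomes that
carry the planted CNV segments so the copy-number truth stays clean.

One global seed is split into per-stage substreams (genome, cell assignment,
library sizes, receptor choice, count sampling), so identical (config, seed)
pairs give bit-identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import ReferenceProfile
from .matrix import CountMatrix, PseudoBulk

CELL_TYPES = ("malignant", "mesothelial", "T", "NK", "B", "myeloid")

DEFAULT_TYPE_PROPORTIONS: dict[str, float] = {
    "malignant": 0.40,
    "mesothelial": 0.12,
    "T": 0.20,
    "NK": 0.10,
    "B": 0.06,
    "myeloid": 0.12,
}

DEFAULT_MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "malignant": (
        "EPCAM", "CLDN4", "IMP3", "MUC1", "CDH1", "CEACAM5", "SCGB2A2",
        "CLDN3", "CLDN7",
    ),
    "mesothelial": (
        "DES", "CALB2", "WT1", "UPK3B", "CDH2", "COL1A2", "S100A4", "MSLN",
    ),
    "T": (
        "CD3D", "CD3E", "CD3G", "CD2", "IL7R", "TRAC", "TRBC2", "CD27",
        "LTB", "CD69", "LCK", "SKAP1",
    ),
    "NK": (
        "KLRF1", "NCAM1", "GNLY", "NKG7", "KLRD1", "PRF1", "GZMB", "CD7",
        "FCER1G", "KLRB1", "NCR1", "EOMES",
    ),
    "B": (
        "CD79A", "CD79B", "MS4A1", "IGHM", "JCHAIN", "CD19", "BANK1",
        "TNFRSF13B", "IGKC", "BLNK", "PAX5", "CD37",
    ),
    "myeloid": (
        "CD14", "LYZ", "CD68", "FCGR3A", "ITGAM", "CD74", "S100A8",
        "S100A9", "FCN1", "AIF1", "C1QA", "CSF1R",
    ),
}

OVERLAPPING_MARKERS = ("KRT8", "KRT19", "VIM", "CD44", "ACTB")

# CAF-like program planted in mesothelial cells (growth factors, ECM,
# matrix remodelling) and an epithelial/luminal program in malignant cells.
CAF_PROGRAM = (
    "FAP", "PDPN", "ACTA2", "PDGFRB", "FN1", "SPARC", "COL1A1", "COL3A1",
    "COL5A2", "MMP2", "LRP1", "VEGFC", "PDGFD", "IGF1", "TAGLN", "THY1",
    "POSTN", "DCN", "LUM", "TNC",
)
EPITHELIAL_PROGRAM = (
    "KRT18", "KRT7", "ELF3", "GATA3", "FOXA1", "ESR1", "TFF1", "TFF3",
    "AGR2", "PVRL4", "WNT7B", "KRT17", "SPINT2", "RAB25", "GRHL2", "CLDN6",
    "EHF", "MAL2", "AP1M2", "TACSTD2",
)
FGF_DOWNSTREAM = (
    "SPRY2", "SPRY4", "DUSP6", "ETV4", "ETV5", "FRS2", "SHC1", "PLCG1",
    "MAPK3", "CCND1", "MYC", "JUNB", "FOSL1", "EGR1", "IER3",
)
PROLIFERATION_PROGRAM = ("MKI67", "TOP2A", "CCNB1", "CDK1", "UBE2C", "BIRC5")

MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB")
RIBO_GENES = ("RPL3", "RPL13A", "RPS4X", "RPS6", "RPL7", "RPS18")

CHROMOSOMES = tuple(str(i) for i in range(1, 23))
_CNV_CHROMS = ("8", "17")  # named genes stay off these


@dataclass(frozen=True)
class CnvSegment:
    """A planted copy-number segment in one patient's malignant cells."""

    patient: str
    chromosome: str
    start_gene_index: int  # 0-based index into that chromosome's gene order
    n_genes: int
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass(frozen=True)
class LrCircuit:
    """A directed ligand/receptor circuit with a downstream response program."""

    ligand: str = "FGF2"
    receptor: str = "FGFR2"
    sender_type: str = "mesothelial"
    receiver_type: str = "malignant"
    downstream_genes: tuple[str, ...] = FGF_DOWNSTREAM
    effect_log2fc: float = 2.0
    receptor_positive_fraction: float = 0.3
    ligand_log2fc: float = 9.5
    receptor_mean: float = 30.0


@dataclass(frozen=True)
class SubsetProgram:
    """A within-type cell subset expressing extra genes (e.g. CD4 T cells)."""

    cell_type: str
    name: str
    fraction: float
    genes: tuple[str, ...]
    log2fc: float


def _default_subsets() -> tuple[SubsetProgram, ...]:
    return (
        SubsetProgram("T", "CD8", 0.50, ("CD8A", "CD8B"), 7.0),
        SubsetProgram("T", "CD4", 0.35, ("CD4",), 7.0),
        SubsetProgram("malignant", "proliferative", 0.30, PROLIFERATION_PROGRAM, 3.0),
    )


def _default_de_program() -> dict[str, tuple[tuple[str, ...], float]]:
    """Default per-type expression programs.

    The non-immune types carry broad transcriptional programs (epithelial /
    CAF-like) on top of their marker panels; immune identities are carried by
    the marker panels alone, which keeps the immune CNV baseline free of
    large planted expression blocks, as in real data where immune cells are
    copy-number neutral.
    """
    return {
        "malignant": (EPITHELIAL_PROGRAM, 2.0),
        "mesothelial": (CAF_PROGRAM, 2.0),
    }


def _default_cnv_segments(n_patients: int = 7) -> tuple[CnvSegment, ...]:
    segs = []
    for i in range(n_patients):
        p = f"P{i + 1}"
        segs.append(CnvSegment(p, "8", 30, 150, 2.0))
        segs.append(CnvSegment(p, "17", 20, 120, 0.5))
    return tuple(segs)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic MPE cohort."""

    n_patients: int = 7
    cells_per_patient: int = 700
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    nb_dispersion: float = 0.03
    libsize_log_mu: float = 10.8  # ~49,000 counts per cell
    libsize_log_sigma: float = 0.35
    marker_panels: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PANELS)
    )
    marker_log2fc: float = 7.0
    cnv_segments: tuple[CnvSegment, ...] | None = None  # None -> defaults per patient
    lr_circuit: LrCircuit | None = field(default_factory=LrCircuit)
    de_program: Mapping[str, tuple[tuple[str, ...], float]] = field(
        default_factory=_default_de_program
    )
    subset_programs: tuple[SubsetProgram, ...] = field(
        default_factory=_default_subsets
    )
    n_background_genes: int = 2000
    gene_universe: tuple[str, ...] | None = None
    seed: int = 0

    def patients(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    def resolved_cnv_segments(self) -> tuple[CnvSegment, ...]:
        if self.cnv_segments is None:
            return _default_cnv_segments(self.n_patients)
        return tuple(self.cnv_segments)

    def validate(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"type_proportions sum to {total!r}, expected 1 (±1e-9)"
            )
        unknown = set(self.type_proportions) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types in proportions: {sorted(unknown)}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        for seg in self.resolved_cnv_segments():
            if seg.patient not in self.patients():
                raise ValueError(f"CNV segment patient {seg.patient!r} not simulated")
        frac_by_type: dict[str, float] = {}
        for sub in self.subset_programs:
            frac_by_type[sub.cell_type] = frac_by_type.get(sub.cell_type, 0) + sub.fraction
        for t, f in frac_by_type.items():
            if f > 1.0 + 1e-9:
                raise ValueError(f"subset fractions for {t!r} exceed 1")


# ---------------------------------------------------------------------------
# Gene universe and generative model
# ---------------------------------------------------------------------------

def _named_gene_raw_abundance() -> dict[str, float]:
    """Baseline abundance (arbitrary units; background genes average ~5)."""
    raw: dict[str, float] = {}
    for genes in DEFAULT_MARKER_PANELS.values():
        for g in genes:
            raw[g] = 0.006  # discriminative markers: rare off-type
    for g in OVERLAPPING_MARKERS:
        raw[g] = 3.0
    for g in CAF_PROGRAM + EPITHELIAL_PROGRAM:
        raw[g] = 0.5
    for g in FGF_DOWNSTREAM:
        raw[g] = 1.0
    for g in PROLIFERATION_PROGRAM:
        raw[g] = 0.5
    for g in ("CD4", "CD8A", "CD8B", "FGF2", "FGFR2"):
        raw[g] = 0.006
    for g in MITO_GENES:
        raw[g] = 150.0
    for g in RIBO_GENES:
        raw[g] = 30.0
    return raw


class _SimModel:
    """Deterministic generative state derived from a SimConfig."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        seeds = np.random.SeedSequence(config.seed).spawn(5)
        self.rng_genome = np.random.default_rng(seeds[0])
        self.rng_assign = np.random.default_rng(seeds[1])
        self.rng_libsize = np.random.default_rng(seeds[2])
        self.rng_receptor = np.random.default_rng(seeds[3])
        self.rng_counts = np.random.default_rng(seeds[4])
        self._build_genome()
        self._build_effects()

    # -- genome ----------------------------------------------------------
    def _build_genome(self) -> None:
        cfg = self.config
        named_raw = _named_gene_raw_abundance()
        named = sorted(named_raw)
        if cfg.gene_universe is not None:
            universe = list(cfg.gene_universe)
            missing = self._program_genes() - set(universe)
            if missing:
                raise ValueError(
                    f"program gene {sorted(missing)[0]!r} not in gene universe"
                )
            background = [g for g in universe if g not in named_raw]
            named = [g for g in universe if g in named_raw]
        else:
            background = [f"GENE{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
            missing = self._program_genes() - set(background) - set(named)
            if missing:
                raise ValueError(
                    f"program gene {sorted(missing)[0]!r} not in gene universe"
                )
        # chromosome allocation: CNV chromosomes get only background genes
        n_bg = len(background)
        alloc: dict[str, list[str]] = {c: [] for c in CHROMOSOMES}
        n_chr8 = max(200, n_bg // 10)
        n_chr17 = max(160, n_bg // 12)
        if n_chr8 + n_chr17 > n_bg:
            raise ValueError("gene universe too small to host the CNV chromosomes")
        bg_order = list(self.rng_genome.permutation(background))
        alloc["8"] = bg_order[:n_chr8]
        alloc["17"] = bg_order[n_chr8 : n_chr8 + n_chr17]
        rest = bg_order[n_chr8 + n_chr17 :] + sorted(named)
        other_chroms = [c for c in CHROMOSOMES if c not in _CNV_CHROMS]
        for i, g in enumerate(rest):
            alloc[other_chroms[i % len(other_chroms)]].append(g)
        rows = []
        for chrom in CHROMOSOMES:
            genes = list(self.rng_genome.permutation(alloc[chrom]))
            gaps = self.rng_genome.integers(1_000, 900_000, size=len(genes))
            starts = np.cumsum(gaps)
            for g, s in zip(genes, starts):
                rows.append((g, chrom, int(s)))
        self.gene_meta = pd.DataFrame(rows, columns=["symbol", "chromosome", "start"])
        self.symbols = pd.Index(self.gene_meta["symbol"])
        if len(self.symbols) < 2000:
            raise ValueError(
                f"gene universe has {len(self.symbols)} genes; need >= 2000"
            )
        raw = np.empty(len(self.symbols))
        is_named = self.symbols.isin(list(named_raw))
        raw[~is_named] = self.rng_genome.lognormal(
            mean=0.0, sigma=1.8, size=int((~is_named).sum())
        )
        for i in np.flatnonzero(is_named):
            raw[i] = named_raw[self.symbols[i]]
        self.baseline = raw / raw.sum()

    def _program_genes(self) -> set[str]:
        cfg = self.config
        out: set[str] = set()
        for genes in cfg.marker_panels.values():
            out.update(genes)
        for genes, _ in cfg.de_program.values():
            out.update(genes)
        for sub in cfg.subset_programs:
            out.update(sub.genes)
        if cfg.lr_circuit is not None:
            out.add(cfg.lr_circuit.ligand)
            out.add(cfg.lr_circuit.receptor)
            out.update(cfg.lr_circuit.downstream_genes)
        return out

    # -- multiplicative effects ------------------------------------------
    def _gene_pos(self, symbol: str) -> int:
        idx = self.symbols.get_indexer([symbol])
        if idx[0] < 0:
            raise ValueError(f"program gene {symbol!r} not in gene universe")
        return int(idx[0])

    def _build_effects(self) -> None:
        cfg = self.config
        g = len(self.symbols)
        self.type_mult: dict[str, np.ndarray] = {t: np.ones(g) for t in CELL_TYPES}
        for t, genes in cfg.marker_panels.items():
            for sym in genes:
                self.type_mult[t][self._gene_pos(sym)] *= 2.0**cfg.marker_log2fc
        for t, (genes, lfc) in cfg.de_program.items():
            for sym in genes:
                self.type_mult[t][self._gene_pos(sym)] *= 2.0**lfc
        if cfg.lr_circuit is not None:
            c = cfg.lr_circuit
            self.type_mult[c.sender_type][self._gene_pos(c.ligand)] *= (
                2.0**c.ligand_log2fc
            )
        self.subset_mult: dict[tuple[str, str], np.ndarray] = {}
        for sub in cfg.subset_programs:
            v = np.ones(g)
            for sym in sub.genes:
                v[self._gene_pos(sym)] *= 2.0**sub.log2fc
            self.subset_mult[(sub.cell_type, sub.name)] = v
        self.downstream_mult = np.ones(g)
        if cfg.lr_circuit is not None:
            c = cfg.lr_circuit
            for sym in c.downstream_genes:
                self.downstream_mult[self._gene_pos(sym)] *= 2.0**c.effect_log2fc
        # genes x patients CNV folds (1.0 outside segments)
        self.cnv_folds = pd.DataFrame(
            1.0, index=self.symbols, columns=cfg.patients()
        )
        for seg in cfg.resolved_cnv_segments():
            chrom_genes = self.gene_meta[self.gene_meta["chromosome"] == seg.chromosome]
            chrom_genes = chrom_genes.sort_values("start")
            if seg.start_gene_index + seg.n_genes > len(chrom_genes):
                raise ValueError(
                    f"CNV segment on chr{seg.chromosome} exceeds its "
                    f"{len(chrom_genes)} genes"
                )
            hit = chrom_genes["symbol"].iloc[
                seg.start_gene_index : seg.start_gene_index + seg.n_genes
            ]
            self.cnv_folds.loc[hit, seg.patient] *= seg.fold_change

    # -- expected profiles (for reference centroids) ---------------------
    def expected_log_profile(self, cell_type: str) -> np.ndarray:
        """Expected log2(1+CP10K) profile of a cell type (no CNV, no subsets)."""
        mu = self.baseline * self.type_mult[cell_type]
        rel = mu / mu.sum()
        return np.log2(1.0 + 1e4 * rel)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted truth behind one simulated cohort."""

    cells: pd.DataFrame  # cell_id, patient, cell_type, subset, receptor_positive
    cnv_folds: pd.DataFrame  # genes x patients, 1.0 outside segments
    receptor_positive_cells: tuple[str, ...]
    de_sets: dict[str, tuple[str, ...]]
    circuit: LrCircuit | None
    config: SimConfig

    def true_labels(self) -> pd.Series:
        return pd.Series(
            self.cells["cell_type"].to_numpy(), index=self.cells["cell_id"], name="label"
        )


def ground_truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Per-patient per-type cell counts plus a planted-effect manifest."""
    rows = []
    counts = (
        truth.cells.groupby(["patient", "cell_type"], sort=True)
        .size()
        .reset_index(name="n")
    )
    for _, r in counts.iterrows():
        rows.append(
            {
                "kind": "cells",
                "patient": r["patient"],
                "detail": r["cell_type"],
                "n": int(r["n"]),
            }
        )
    for seg in truth.config.resolved_cnv_segments():
        rows.append(
            {
                "kind": "cnv_segment",
                "patient": seg.patient,
                "detail": f"chr{seg.chromosome}:{seg.start_gene_index}"
                f"+{seg.n_genes}x{seg.fold_change}",
                "n": seg.n_genes,
            }
        )
    if truth.circuit is not None:
        c = truth.circuit
        rows.append(
            {
                "kind": "circuit",
                "patient": "all",
                "detail": f"{c.ligand}->{c.receptor} "
                f"({c.sender_type}->{c.receiver_type})",
                "n": len(truth.receptor_positive_cells),
            }
        )
    for name, genes in sorted(truth.de_sets.items()):
        rows.append({"kind": "program", "patient": "all", "detail": name, "n": len(genes)})
    return pd.DataFrame(rows, columns=["kind", "patient", "detail", "n"])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _sample_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu * (1 + phi * mu)."""
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_mpe(config: SimConfig | None = None) -> tuple[CountMatrix, GroundTruth]:
    """Simulate an MPE-like cohort; returns the counts and the planted truth."""
    config = config or SimConfig()
    model = _SimModel(config)
    cfg = config
    types = [t for t in CELL_TYPES if cfg.type_proportions.get(t, 0) > 0]
    probs = np.array([cfg.type_proportions[t] for t in types])
    probs = probs / probs.sum()

    cells = []
    for patient in cfg.patients():
        drawn = model.rng_assign.choice(len(types), size=cfg.cells_per_patient, p=probs)
        for j, ti in enumerate(drawn):
            cells.append(
                {
                    "cell_id": f"{patient}_c{j:04d}",
                    "patient": patient,
                    "cell_type": types[int(ti)],
                    "subset": "base",
                    "receptor_positive": False,
                }
            )
    cell_df = pd.DataFrame(cells)
    n_cells = len(cell_df)
    libsize = model.rng_libsize.lognormal(
        mean=cfg.libsize_log_mu, sigma=cfg.libsize_log_sigma, size=n_cells
    )

    # within-type subsets (deterministic stream order: patients then programs)
    for patient in cfg.patients():
        for t in types:
            idx = np.flatnonzero(
                (cell_df["patient"] == patient) & (cell_df["cell_type"] == t)
            )
            subs = [s for s in cfg.subset_programs if s.cell_type == t]
            if not subs or len(idx) == 0:
                continue
            perm = model.rng_assign.permutation(idx)
            start = 0
            for s in subs:
                k = int(round(s.fraction * len(idx)))
                cell_df.loc[perm[start : start + k], "subset"] = s.name
                start += k

    # receptor-positive receiver cells (planted exactly)
    if cfg.lr_circuit is not None:
        c = cfg.lr_circuit
        ridx = np.flatnonzero(cell_df["cell_type"] == c.receiver_type)
        k = int(round(c.receptor_positive_fraction * len(ridx)))
        chosen = model.rng_receptor.permutation(ridx)[:k]
        cell_df.loc[chosen, "receptor_positive"] = True

    g = len(model.symbols)
    counts = np.zeros((g, n_cells), dtype=np.int64)
    receptor_pos_gene = (
        model._gene_pos(cfg.lr_circuit.receptor) if cfg.lr_circuit else None
    )

    for patient in cfg.patients():
        for t in types:
            base_mu = model.baseline * model.type_mult[t]
            if t == "malignant":
                base_mu = base_mu * model.cnv_folds[patient].to_numpy()
            subset_names = sorted(
                {"base"} | {s.name for s in cfg.subset_programs if s.cell_type == t}
            )
            for sub_name in subset_names:
                for rpos in (False, True):
                    mask = (
                        (cell_df["patient"] == patient)
                        & (cell_df["cell_type"] == t)
                        & (cell_df["subset"] == sub_name)
                        & (cell_df["receptor_positive"] == rpos)
                    ).to_numpy()
                    idx = np.flatnonzero(mask)
                    if len(idx) == 0:
                        continue
                    mu_g = base_mu.copy()
                    if sub_name != "base":
                        mu_g = mu_g * model.subset_mult[(t, sub_name)]
                    if rpos:
                        mu_g = mu_g * model.downstream_mult
                    block_mu = np.outer(mu_g, libsize[idx])
                    if receptor_pos_gene is not None and t == cfg.lr_circuit.receiver_type:
                        block_mu[receptor_pos_gene, :] = 0.0
                    block = _sample_counts(
                        model.rng_counts, block_mu, cfg.nb_dispersion
                    )
                    if receptor_pos_gene is not None and rpos:
                        extra = _sample_counts(
                            model.rng_counts,
                            np.full(len(idx), max(cfg.lr_circuit.receptor_mean - 1, 0)),
                            cfg.nb_dispersion,
                        )
                        block[receptor_pos_gene, :] = 1 + extra
                    counts[:, idx] = block

    cell_meta = pd.DataFrame(
        {
            "cell_id": cell_df["cell_id"],
            "patient": cell_df["patient"],
            "sample": cell_df["patient"],
            "enriched": False,
        }
    )
    cm = CountMatrix(
        sp.csr_matrix(counts), model.gene_meta.copy(), cell_meta
    )
    de_sets = {
        f"{t}_program": tuple(genes) for t, (genes, _) in sorted(cfg.de_program.items())
    }
    de_sets["caf"] = CAF_PROGRAM if "mesothelial" in cfg.de_program else tuple()
    de_sets["epithelial"] = (
        EPITHELIAL_PROGRAM if "malignant" in cfg.de_program else tuple()
    )
    if cfg.lr_circuit is not None:
        de_sets["fgf_downstream"] = tuple(cfg.lr_circuit.downstream_genes)
    truth = GroundTruth(
        cells=cell_df,
        cnv_folds=model.cnv_folds.copy(),
        receptor_positive_cells=tuple(
            cell_df.loc[cell_df["receptor_positive"], "cell_id"]
        ),
        de_sets=de_sets,
        circuit=cfg.lr_circuit,
        config=cfg,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Companion fixtures derived from the generative model
# ---------------------------------------------------------------------------

def make_reference_profiles(
    config: SimConfig, n_refs: int = 3, noise_sd: float = 0.2, seed: int = 0
) -> list[ReferenceProfile]:
    """Noisy per-type centroid references for consensus annotation.

    Each reference perturbs the generative expected log-profiles with iid
    Gaussian noise, emulating independent annotation datasets.
    """
    model = _SimModel(config)
    base = pd.DataFrame(
        {t: model.expected_log_profile(t) for t in CELL_TYPES},
        index=model.symbols,
    )
    rng = np.random.default_rng(seed)
    refs = []
    for i in range(n_refs):
        noisy = base + rng.normal(0.0, noise_sd, size=base.shape)
        refs.append(ReferenceProfile(name=f"ref{i + 1}", profiles=noisy))
    return refs


def make_t_reference(config: SimConfig, noise_sd: float = 0.15, seed: int = 0) -> ReferenceProfile:
    """A small T-subtype centroid reference aligned with the planted subsets."""
    model = _SimModel(config)
    t_prof = model.expected_log_profile("T")
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(index=model.symbols)
    boost = np.log2(1 + 1e4 * 2.0**7 * model.baseline) - np.log2(
        1 + 1e4 * model.baseline
    )

    def with_genes(genes: Sequence[str]) -> np.ndarray:
        v = t_prof.copy()
        for sym in genes:
            i = model._gene_pos(sym)
            v[i] = t_prof[i] + boost[i]
        return v + rng.normal(0.0, noise_sd, size=len(v))

    base["CD8 Naïve-like"] = with_genes(("CD8A", "CD8B"))
    base["CD4 Naïve-like"] = with_genes(("CD4",))
    base["Th1"] = with_genes(("CD4", "CD2"))
    return ReferenceProfile(name="t_subtypes", profiles=base)


def make_subtype_centroids(
    genes: Sequence[str] | None = None,
    subtypes: Sequence[str] = ("Basal", "Her2", "LumA", "LumB", "Normal-like"),
    n_genes: int = 600,
    seed: int = 0,
):
    """A toy intrinsic-subtype centroid table (pluggable stand-in).

    Synthetic: random half-normal expression per subtype; this exercises the
    nearest-centroid classification mechanics, not any published rule set.
    """
    from .signatures import CentroidTable

    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"SGENE{i:04d}" for i in range(1, n_genes + 1)]
    table = pd.DataFrame(
        np.abs(rng.normal(0.0, 2.0, size=(len(genes), len(subtypes)))),
        index=pd.Index(genes, name="symbol"),
        columns=list(subtypes),
    )
    return CentroidTable(table=table, vocabulary=tuple(subtypes))


def make_intrinsic_centroids(
    config: SimConfig, noise_sd: float = 0.3, seed: int = 0
):
    """Toy intrinsic-subtype centroids over the simulated gene universe.

    Synthetic stand-in for a published subtype rule set: the four tumour
    subtypes are distinct perturbations of the malignant expected profile and
    'Normal-like' is the mesothelial (fibroblast-like) expected profile, so
    malignant pseudo-bulks classify as tumour subtypes and mesothelial
    pseudo-bulks as Normal-like.
    """
    from .signatures import CentroidTable

    model = _SimModel(config)
    rng = np.random.default_rng(seed)
    mal = model.expected_log_profile("malignant")
    mes = model.expected_log_profile("mesothelial")
    cols = {}
    for name in ("Basal", "Her2", "LumA", "LumB"):
        cols[name] = mal + rng.normal(0.0, noise_sd, size=len(mal))
    cols["Normal-like"] = mes + rng.normal(0.0, noise_sd, size=len(mes))
    table = pd.DataFrame(cols, index=model.symbols)
    vocab = ("Basal", "Her2", "LumA", "LumB", "Normal-like")
    return CentroidTable(table=table[list(vocab)], vocabulary=vocab)


def make_lr_database(
    config: SimConfig, n_pairs: int = 300, seed: int = 0
) -> pd.DataFrame:
    """A ligand-receptor pair table over the simulated gene universe.

    Contains the planted circuit pair plus random background pairs; columns
    are (pair_id, ligand, receptor). Mirroring curated LR resources, the
    pool excludes the most abundant (housekeeping-like) quartile of the
    transcriptome: signalling genes are regulated, not constitutive.
    """
    model = _SimModel(config)
    rng = np.random.default_rng(seed)
    is_bg = np.array([s.startswith("GENE") for s in model.symbols])
    cutoff = np.quantile(model.baseline[is_bg], 0.75)
    background = [
        s for s, b, bg in zip(model.symbols, model.baseline, is_bg)
        if bg and b < cutoff
    ]
    rows = []
    if config.lr_circuit is not None:
        c = config.lr_circuit
        rows.append((f"LR_{c.ligand}_{c.receptor}", c.ligand, c.receptor))
    seen = {(r[1], r[2]) for r in rows}
    while len(rows) < n_pairs:
        lig, rec = rng.choice(background, size=2, replace=False)
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        rows.append((f"LR{len(rows):04d}", lig, rec))
    return pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor"])


def make_gene_set_collection(
    config: SimConfig, n_random_sets: int = 25, seed: int = 0
) -> dict[str, tuple[str, ...]]:
    """A toy gene-set collection: the planted programs plus random sets."""
    model = _SimModel(config)
    rng = np.random.default_rng(seed)
    background = [s for s in model.symbols if s.startswith("GENE")]
    sets: dict[str, tuple[str, ...]] = {
        "CAF_SIGNATURE": CAF_PROGRAM,
        "EPITHELIAL_A": EPITHELIAL_PROGRAM[:10],
        "EPITHELIAL_B": EPITHELIAL_PROGRAM[10:],
        "FGF_DOWNSTREAM": FGF_DOWNSTREAM,
        "PROLIFERATION": PROLIFERATION_PROGRAM,
    }
    for i in range(n_random_sets):
        size = int(rng.integers(10, 50))
        sets[f"RANDOM_{i:02d}"] = tuple(rng.choice(background, size=size, replace=False))
    return sets


def simulate_pseudobulk(
    n_genes: int = 2000,
    n_per_group: int = 4,
    mean_counts: float = 500.0,
    dispersion: float = 0.01,
    planted: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[PseudoBulk, dict[str, float]]:
    """Directly simulate paired pseudo-bulk count profiles for DE testing.

    Two groups ('g1', 'g2') with ``n_per_group`` patient-matched samples each;
    per-gene baseline means are log-normally spread around ``mean_counts`` and
    shared across samples. ``planted`` maps gene symbols to fold-changes
    applied to group 'g1'.
    """
    rng = np.random.default_rng(seed)
    genes = [f"PGENE{i:04d}" for i in range(1, n_genes + 1)]
    base = rng.lognormal(mean=np.log(mean_counts), sigma=1.0, size=n_genes)
    folds = np.ones(n_genes)
    planted = dict(planted or {})
    gene_index = {g: i for i, g in enumerate(genes)}
    for sym, f in planted.items():
        if sym not in gene_index:
            raise ValueError(f"planted gene {sym!r} not in simulated universe")
        folds[gene_index[sym]] = f
    cols = {}
    meta_rows = []
    for group, fold_vec in (("g1", base * folds), ("g2", base)):
        for j in range(n_per_group):
            name = f"P{j + 1}|{group}"
            cols[name] = _sample_counts(rng, fold_vec, dispersion)
            meta_rows.append(
                {"sample": name, "patient": f"P{j + 1}", "group": group, "n_cells": 1}
            )
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="symbol"))
    totals = counts.sum(axis=0).astype(float)
    logcpm = np.log2(1.0 + counts / totals * 1e6)
    pb = PseudoBulk(counts=counts, logcpm=logcpm, sample_meta=pd.DataFrame(meta_rows))
    return pb, planted
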