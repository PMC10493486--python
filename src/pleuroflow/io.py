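"""File formats: GMT gene sets, reference/centroid tables, annotations.

Count matrices travel as MatrixMarket + TSV sidecars (see
:mod:`pleuroflow.matrix`); everything else is plain TSV with headers, plus
the GMT line format for gene-set collections.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .annotation import CellAnnotation, ReferenceProfile
from .matrix import NormMatrix
from .signatures import CentroidTable, GeneSet


# -- GMT --------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:60]!r}")
        sets.append(GeneSet(name=parts[0], genes=tuple(parts[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([gs.name, "pleuroflow"] + list(gs.genes)) for gs in sets
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


# -- reference / centroid tables -------------------------------------------

def read_reference_profile(path: str | Path, name: str | None = None) -> ReferenceProfile:
    """Genes x types TSV with a leading `symbol` column."""
    df = pd.read_csv(path, sep="\t").set_index("symbol")
    return ReferenceProfile(name=name or Path(path).stem, profiles=df)


def write_reference_profile(ref: ReferenceProfile, path: str | Path) -> Path:
    path = Path(path)
    ref.profiles.rename_axis("symbol").to_csv(path, sep="\t")
    return path


def read_centroid_table(path: str | Path) -> CentroidTable:
    df = pd.read_csv(path, sep="\t").set_index("symbol")
    return CentroidTable(table=df, vocabulary=tuple(df.columns))


def write_centroid_table(ct: CentroidTable, path: str | Path) -> Path:
    path = Path(path)
    ct.table.rename_axis("symbol")[list(ct.vocabulary)].to_csv(path, sep="\t")
    return path


# -- annotations ------------------------------------------------------------

def write_annotation(ann: CellAnnotation, path: str | Path) -> Path:
    path = Path(path)
    out = ann.table.reset_index()
    out.columns = ["cell_id"] + list(out.columns[1:])
    out.to_csv(path, sep="\t", index=False)
    return path


def read_annotation(path: str | Path) -> CellAnnotation:
    tab = pd.read_csv(path, sep="\t").set_index("cell_id")
    for col in ("t_subtype", "cd_class"):
        if col in tab.columns:
            tab[col] = tab[col].where(tab[col].notna(), None)
    return CellAnnotation(tab)


# -- normalized matrix ------------------------------------------------------

def write_norm_matrix(n: NormMatrix, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "norm.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    mmwrite(paths["mtx"], n.values.tocoo(), field="real", precision=10)
    n.gene_meta.to_csv(paths["genes"], sep="\t", index=False)
    n.cell_meta.to_csv(paths["barcodes"], sep="\t", index=False)
    return paths


def read_norm_matrix(in_dir: str | Path) -> NormMatrix:
    d = Path(in_dir)
    values = sp.csr_matrix(mmread(d / "norm.mtx"))
    gene_meta = pd.read_csv(d / "genes.tsv", sep="\t", dtype={"chromosome": str})
    cell_meta = pd.read_csv(d / "barcodes.tsv", sep="\t")
    if values.shape != (len(gene_meta), len(cell_meta)):
        raise ValueError("normalized matrix dimensions inconsistent with sidecars")
    return NormMatrix(values, gene_meta, cell_meta)


# -- pseudo-bulk ------------------------------------------------------------

def write_pseudobulk(pb, out_dir: str | Path) -> dict[str, Path]:
    from .matrix import PseudoBulk  # noqa: F401  (type reference)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "pseudobulk_counts.tsv",
        "meta": out / "pseudobulk_meta.tsv",
    }
    pb.counts.rename_axis("symbol").to_csv(paths["counts"], sep="\t")
    pb.sample_meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


def read_pseudobulk(in_dir: str | Path):
    from .matrix import PseudoBulk

    d = Path(in_dir)
    counts = pd.read_csv(d / "pseudobulk_counts.tsv", sep="\t").set_index("symbol")
    meta = pd.read_csv(d / "pseudobulk_meta.tsv", sep="\t")
    totals = counts.sum(axis=0).astype(float)
    logcpm = np.log2(1.0 + counts / totals * 1e6)
    return PseudoBulk(counts=counts, logcpm=logcpm, sample_meta=meta)


# -- ground truth -----------------------------------------------------------

def write_ground_truth(truth, out_dir: str | Path) -> dict[str, Path]:
    """Persist a GroundTruth as TSV tables plus a JSON manifest."""
    from .sim import ground_truth_summary

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out / "truth_cells.tsv",
        "cnv": out / "truth_cnv_folds.tsv",
        "summary": out / "truth_summary.tsv",
        "manifest": out / "truth_manifest.json",
    }
    truth.cells.to_csv(paths["cells"], sep="\t", index=False)
    truth.cnv_folds.rename_axis("symbol").to_csv(paths["cnv"], sep="\t")
    ground_truth_summary(truth).to_csv(paths["summary"], sep="\t", index=False)
    manifest = {
        "n_cells": int(len(truth.cells)),
        "patients": sorted(truth.cells["patient"].unique()),
        "cell_types": sorted(truth.cells["cell_type"].unique()),
        "n_receptor_positive": len(truth.receptor_positive_cells),
        "de_sets": {k: list(v) for k, v in sorted(truth.de_sets.items())},
        "circuit": None
        if truth.circuit is None
        else {
            "ligand": truth.circuit.ligand,
            "receptor": truth.circuit.receptor,
            "sender_type": truth.circuit.sender_type,
            "receiver_type": truth.circuit.receiver_type,
        },
        "seed": int(truth.config.seed),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
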