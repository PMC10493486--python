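"""Config-driven orchestration of the full MPE analysis.

A single YAML/JSON document drives all stages in dependency order:

    simulate/ingest -> qc -> normalize -> annotate/gate -> tcells -> cluster
    -> cnv -> score/subtype -> de/enrich -> lr/stratify

Every stage writes its tables under the output directory as it completes
(partial outputs survive a failing stage), and the run finishes with a
versioned, machine-readable ``report.json`` echoing parameters, per-stage
seeds and row counts. The report contains no timestamps, so identical
configs give byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import annotation as ann_mod
from . import cnv as cnv_mod
from . import de as de_mod
from . import interactions as lr_mod
from . import io as io_mod
from . import matrix as mx
from . import signatures as sig_mod
from . import sim as sim_mod
from ._utils import split_seed

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

STAGES = (
    "qc", "normalize", "annotate", "gate", "tcells", "cluster", "cnv",
    "score", "subtype", "de", "enrich", "lr", "stratify",
)

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "simulate": {
        "n_patients": int,
        "cells_per_patient": int,
        "n_background_genes": int,
        "nb_dispersion": float,
        "libsize_log_mu": float,
        "libsize_log_sigma": float,
        "marker_log2fc": float,
    },
    "inputs": {"mtx": str, "genes": str, "barcodes": str},
    "stages": {s: bool for s in STAGES},
    "qc": {"min_genes_per_cell": int, "max_mito_frac": float},
    "annotate": {
        "n_refs": int,
        "noise_sd": float,
        "min_agreement": float,
        "reference_paths": list,
    },
    "cluster": {
        "n_pcs": int, "k_neighbors": int, "resolution": float, "n_hvgs": int,
    },
    "cnv": {"window": int, "clamp": float, "per_cluster": int, "tau": float},
    "score": {"gmt_path": str},
    "subtype": {"centroids_path": str},
    "de": {"alpha": float, "top_k": int},
    "lr": {
        "db_path": str, "n_pairs": int, "k": int,
        "sender": str, "receiver": str,
        "sender_on": float, "receiver_off": float,
    },
    "stratify": {"receptor": str, "receiver_type": str},
    "prevalence_genes": list,
}

IMMUNE_LABELS = ("T", "NK", "B", "myeloid", "DC")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""


def _validate_keys(config: Mapping[str, Any], schema: Mapping[str, Any], path: str = "") -> None:
    for key, value in config.items():
        if key not in schema:
            raise ValueError(f"unknown config key {path + key!r}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, Mapping):
            _validate_keys(value, sub, path + key + ".")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    _validate_keys(cfg, _SCHEMA)
    return cfg


def _stage_enabled(cfg: Mapping[str, Any], name: str) -> bool:
    return bool(cfg.get("stages", {}).get(name, True))


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        _validate_keys(config, _SCHEMA)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage_seeds = dict(zip(
        ("simulate", "references", "cluster", "cnv_subsample", "assets"),
        split_seed(seed, 5),
    ))
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": json.loads(json.dumps(config, sort_keys=True)),
        "seeds": stage_seeds,
        "tables": {},
        "stages_run": [],
    }
    state: dict[str, Any] = {}

    def run_stage(name: str, fn) -> None:
        if not _stage_enabled(config, name):
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage name + cause contract
            _finalize(report, out)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        report["stages_run"].append(name)

    # -- input ------------------------------------------------------------
    sim_cfg = None
    if "inputs" in config:
        paths = config["inputs"]
        cm = mx.read_count_matrix(paths["mtx"], paths["genes"], paths["barcodes"])
        truth = None
    else:
        sim_over = dict(config.get("simulate", {}))
        sim_cfg = sim_mod.SimConfig(seed=stage_seeds["simulate"], **sim_over)
        cm, truth = sim_mod.simulate_mpe(sim_cfg)
        fixture_dir = out / "fixture"
        mx.write_count_matrix(cm, fixture_dir)
        io_mod.write_ground_truth(truth, fixture_dir)
        report["tables"]["fixture_cells"] = int(cm.n_cells)
    state["cm_raw"] = cm

    # -- qc ---------------------------------------------------------------
    def do_qc() -> None:
        p = config.get("qc", {})
        before = state["cm_raw"].n_cells
        state["cm"] = mx.qc_filter(
            state["cm_raw"],
            min_genes_per_cell=int(p.get("min_genes_per_cell", 200)),
            max_mito_frac=float(p.get("max_mito_frac", 0.2)),
        )
        summary = pd.DataFrame(
            [{"cells_in": before, "cells_out": state["cm"].n_cells,
              "removed": before - state["cm"].n_cells}]
        )
        report["tables"]["qc_summary"] = _write_tsv(summary, out / "qc_summary.tsv")

    run_stage("qc", do_qc)
    state.setdefault("cm", state["cm_raw"])

    def do_normalize() -> None:
        state["norm"] = mx.lognormalize(state["cm"])

    run_stage("normalize", do_normalize)
    downstream = [s for s in STAGES if s not in ("qc", "normalize")]
    if "norm" not in state:
        if any(_stage_enabled(config, s) for s in downstream):
            raise PipelineError("normalize stage is required by all downstream stages")
        _finalize(report, out)
        return report
    norm = state["norm"]
    cm = state["cm"]

    # -- annotation -------------------------------------------------------
    def do_annotate() -> None:
        p = config.get("annotate", {})
        if "reference_paths" in p:
            refs = [io_mod.read_reference_profile(rp) for rp in p["reference_paths"]]
        elif sim_cfg is not None:
            refs = sim_mod.make_reference_profiles(
                sim_cfg,
                n_refs=int(p.get("n_refs", 3)),
                noise_sd=float(p.get("noise_sd", 0.2)),
                seed=stage_seeds["references"],
            )
        else:
            raise ValueError("ingest mode requires annotate.reference_paths")
        votes = [ann_mod.reference_correlation_annotate(norm, r) for r in refs]
        state["ann"] = ann_mod.consensus_annotate(
            votes, cm.cell_meta, min_agreement=float(p.get("min_agreement", 0.5))
        )

    run_stage("annotate", do_annotate)

    def do_gate() -> None:
        state["ann"] = ann_mod.gate_nonimmune_cells(state["ann"], norm)
        report["tables"]["annotation"] = _write_tsv(
            state["ann"].table.reset_index(), out / "annotation.tsv"
        )
        comp = mx.composition_table(state["ann"])
        report["tables"]["composition"] = _write_tsv(comp, out / "composition.tsv")
        genes = config.get(
            "prevalence_genes",
            ["EPCAM", "DES", "MSLN", "CD3D", "KLRF1", "CD79A", "CD14", "KRT8", "MKI67"],
        )
        genes = [g for g in genes if g in set(norm.gene_symbols)]
        prev = mx.expression_prevalence(norm, state["ann"], genes)
        report["tables"]["prevalence"] = _write_tsv(
            prev.rename_axis("cell_type").reset_index(), out / "prevalence.tsv"
        )
        corr, order = mx.celltype_profile_correlation(norm, state["ann"])
        report["tables"]["profile_correlation"] = _write_tsv(
            corr.loc[order, order].rename_axis("group").reset_index(),
            out / "profile_correlation.tsv",
        )

    run_stage("gate", do_gate)
    if "ann" not in state:
        raise PipelineError("annotate/gate stages are required downstream")
    ann = state["ann"]

    def do_tcells() -> None:
        state["ann"] = ann_mod.classify_t_cd4_cd8(norm, state["ann"])
        if sim_cfg is not None:
            t_ref = sim_mod.make_t_reference(sim_cfg, seed=stage_seeds["references"])
            state["ann"] = ann_mod.project_t_subtypes(norm, state["ann"], t_ref)
            state["ann"] = ann_mod.exclude_discordant_t(state["ann"])
        t_tab = state["ann"].table
        t_tab = t_tab[t_tab["label"] == "T"]
        report["tables"]["t_cells"] = _write_tsv(
            t_tab.reset_index(), out / "t_cells.tsv"
        )

    run_stage("tcells", do_tcells)
    ann = state["ann"]

    # -- clustering of gated non-immune cells -----------------------------
    def do_cluster() -> None:
        p = config.get("cluster", {})
        act = ann.active_table()
        nonimmune = act.index[act["label"].isin(["malignant", "mesothelial"])]
        labels = mx.cluster_cells(
            norm,
            cells_subset=list(nonimmune),
            n_pcs=int(p.get("n_pcs", 30)),
            k_neighbors=int(p.get("k_neighbors", 20)),
            resolution=float(p.get("resolution", 0.8)),
            n_hvgs=int(p.get("n_hvgs", 2000)),
            seed=stage_seeds["cluster"],
        )
        state["clusters"] = labels
        df = labels.rename("cluster").rename_axis("cell_id").reset_index()
        df["patient"] = ann.table.loc[df["cell_id"], "patient"].to_numpy()
        report["tables"]["clusters"] = _write_tsv(df, out / "clusters.tsv")

    run_stage("cluster", do_cluster)

    # -- CNV ---------------------------------------------------------------
    def do_cnv() -> None:
        p = config.get("cnv", {})
        act = ann.active_table()
        baseline = list(act.index[act["label"].isin(IMMUNE_LABELS)])
        order = cnv_mod.build_genomic_order(cm.gene_meta)
        targets = act.index[act["label"].isin(["malignant", "mesothelial"])]
        if "clusters" in state:
            groups = pd.Series(
                [
                    (ann.table.loc[c, "patient"], state["clusters"].get(c, "na"))
                    for c in targets
                ],
                index=targets,
            )
        else:
            groups = pd.Series(
                [(ann.table.loc[c, "patient"], ann.table.loc[c, "label"]) for c in targets],
                index=targets,
            )
        subsampled = cnv_mod.subsample_cells_per_cluster(
            groups, int(p.get("per_cluster", 150)), seed=stage_seeds["cnv_subsample"]
        )
        cnvm = cnv_mod.infer_cnv_matrix(
            norm, order, baseline_cells=baseline, cells=subsampled,
            window=int(p.get("window", 101)), clamp=float(p.get("clamp", 1.0)),
        )
        state["cnv"] = cnvm
        frame = cnvm.frame()
        frame.rename_axis("cell_id").to_csv(out / "cnv_matrix.tsv", sep="\t")
        (out / "cnv_matrix.json").write_text(
            json.dumps(
                {
                    "window": cnvm.window,
                    "clamp": cnvm.clamp,
                    "baseline": cnvm.baseline,
                    "n_cells": len(cnvm.cell_ids),
                },
                indent=2, sort_keys=True,
            ) + "\n"
        )
        regions = []
        for chrom in ("8", "17"):
            lo, hi = order.boundaries.get(chrom, (0, 0))
            if hi - lo >= 10:
                regions.append((chrom, 0, hi - lo))
        summary = cnv_mod.summarize_cnv_regions(
            cnvm, ann, regions, tau=float(p.get("tau", 0.15))
        )
        report["tables"]["cnv_summary"] = _write_tsv(summary, out / "cnv_summary.tsv")

    run_stage("cnv", do_cnv)

    # -- signature scoring -------------------------------------------------
    def do_score() -> None:
        p = config.get("score", {})
        if "gmt_path" in p:
            sets = io_mod.read_gmt(p["gmt_path"])
        elif sim_cfg is not None:
            coll = sim_mod.make_gene_set_collection(
                sim_cfg, n_random_sets=0, seed=stage_seeds["assets"]
            )
            sets = [sig_mod.GeneSet(k, v) for k, v in sorted(coll.items()) if len(v) >= 2]
        else:
            raise ValueError("ingest mode requires score.gmt_path")
        act = ann.active_table()
        cells = act.index[act["label"].isin(["malignant", "mesothelial"])]
        pos = norm.cell_positions(cells)
        sub = mx.NormMatrix(
            norm.values[:, pos], norm.gene_meta,
            norm.cell_meta.iloc[pos].reset_index(drop=True),
        )
        scores = sig_mod.score_signatures(sub, sets)
        state["scores"] = scores
        df = scores.rename_axis("cell_id").reset_index()
        df.insert(1, "label", ann.table.loc[scores.index, "label"].to_numpy())
        df.insert(1, "patient", ann.table.loc[scores.index, "patient"].to_numpy())
        report["tables"]["signature_scores"] = _write_tsv(
            df, out / "signature_scores.tsv"
        )

    run_stage("score", do_score)

    # -- pseudo-bulk subtype + MKI67 split ---------------------------------
    def do_subtype() -> None:
        p = config.get("subtype", {})
        act = ann.active_table()
        targets = act.index[act["label"].isin(["malignant", "mesothelial"])]
        if "clusters" in state:
            grouping = pd.Series(
                {
                    c: (ann.table.loc[c, "patient"], f"c{state['clusters'][c]}")
                    for c in targets
                    if c in state["clusters"].index
                }
            )
        else:
            grouping = pd.Series(
                {c: (ann.table.loc[c, "patient"], ann.table.loc[c, "label"]) for c in targets}
            )
        pb = mx.pseudobulk_aggregate(cm, grouping)
        state["pb_clusters"] = pb
        io_mod.write_pseudobulk(pb, out / "pseudobulk_clusters")
        if "centroids_path" in p:
            centroids = io_mod.read_centroid_table(p["centroids_path"])
        elif sim_cfg is not None:
            centroids = sim_mod.make_intrinsic_centroids(
                sim_cfg, seed=stage_seeds["assets"]
            )
        else:
            raise ValueError("ingest mode requires subtype.centroids_path")
        calls = sig_mod.classify_pseudobulk_subtype(pb, centroids)
        report["tables"]["subtype_calls"] = _write_tsv(
            calls.rename_axis("sample").reset_index(), out / "subtype_calls.tsv"
        )
        if "clusters" in state and "MKI67" in set(norm.gene_symbols):
            mal_cells = act.index[act["label"] == "malignant"]
            clus = state["clusters"].loc[
                state["clusters"].index.intersection(mal_cells)
            ]
            if clus.nunique() >= 2:
                assignment, means = sig_mod.split_clusters_by_gene(norm, clus, "MKI67")
                split = pd.DataFrame(
                    {
                        "cluster": list(means.index),
                        "mean_log_expression": means.to_numpy(),
                        "side": [assignment[c] for c in means.index],
                    }
                )
                report["tables"]["mki67_split"] = _write_tsv(
                    split, out / "mki67_split.tsv"
                )

    run_stage("subtype", do_subtype)

    # -- DE and enrichment -------------------------------------------------
    def do_de() -> None:
        p = config.get("de", {})
        act = ann.active_table()
        targets = act.index[act["label"].isin(["malignant", "mesothelial"])]
        grouping = pd.Series(
            {c: (ann.table.loc[c, "patient"], ann.table.loc[c, "label"]) for c in targets}
        )
        pb = mx.pseudobulk_aggregate(cm, grouping)
        meta = pb.sample_meta
        by_patient = meta.pivot_table(
            index="patient", columns="group", values="sample", aggfunc="first"
        )
        both = by_patient.dropna(subset=["malignant", "mesothelial"])
        if len(both) < 2:
            raise ValueError(
                f"need >= 2 patients with both populations, got {len(both)}"
            )
        g_mal = list(both["malignant"])
        g_mes = list(both["mesothelial"])
        res = de_mod.pseudobulk_de(pb, g_mal, g_mes, paired_by_patient=True)
        state["de"] = res
        report["tables"]["de_malignant_vs_mesothelial"] = _write_tsv(
            res, out / "de_malignant_vs_mesothelial.tsv"
        )
        tops = de_mod.top_table(res, k=int(p.get("top_k", 20)), alpha=float(p.get("alpha", 0.05)))
        state["de_top"] = tops
        pd.DataFrame(
            [{"direction": d, "gene": g} for d in ("up", "down") for g in tops[d]]
        ).to_csv(out / "de_top_genes.tsv", sep="\t", index=False)

    run_stage("de", do_de)

    def do_enrich() -> None:
        if "de" not in state:
            raise ValueError("enrich requires the de stage")
        p = config.get("score", {})
        if "gmt_path" in p:
            sets = io_mod.read_gmt(p["gmt_path"])
        elif sim_cfg is not None:
            coll = sim_mod.make_gene_set_collection(
                sim_cfg, n_random_sets=25, seed=stage_seeds["assets"]
            )
            sets = [sig_mod.GeneSet(k, v) for k, v in sorted(coll.items()) if len(v) >= 2]
        else:
            raise ValueError("ingest mode requires score.gmt_path")
        universe = list(state["de"]["gene"])
        rows = []
        for direction in ("up", "down"):
            query = state["de_top"][direction]
            if not query:
                continue
            enr = de_mod.ora_enrich(query, universe, sets)
            tab = enr.table.copy()
            tab.insert(0, "direction", direction)
            rows.append(tab)
        if rows:
            enrich_tab = pd.concat(rows, ignore_index=True)
            report["tables"]["enrichment"] = _write_tsv(
                enrich_tab, out / "enrichment.tsv"
            )

    run_stage("enrich", do_enrich)

    # -- ligand-receptor ---------------------------------------------------
    def do_lr() -> None:
        p = config.get("lr", {})
        sender = p.get("sender", "mesothelial")
        receiver = p.get("receiver", "malignant")
        if "db_path" in p:
            db = pd.read_csv(p["db_path"], sep="\t")
        elif sim_cfg is not None:
            db = sim_mod.make_lr_database(
                sim_cfg, n_pairs=int(p.get("n_pairs", 300)), seed=stage_seeds["assets"]
            )
        else:
            raise ValueError("ingest mode requires lr.db_path")
        genes = sorted(
            (set(db["ligand"]) | set(db["receptor"])) & set(norm.gene_symbols)
        )
        stats = lr_mod.expression_stats_by_type(norm, ann, genes)
        edges = lr_mod.rank_lr_interactions(
            stats, db, sender, receiver, k=int(p.get("k", 100))
        )
        edges = lr_mod.filter_directional_pairs(
            edges, stats,
            sender_on=float(p.get("sender_on", 0.10)),
            receiver_off=float(p.get("receiver_off", 0.05)),
        )
        state["lr_edges"] = edges
        report["tables"]["lr_edges"] = _write_tsv(edges, out / "lr_edges.tsv")

    run_stage("lr", do_lr)

    def do_stratify() -> None:
        p = config.get("stratify", {})
        receptor = p.get("receptor", "FGFR2")
        receiver_type = p.get("receiver_type", "malignant")
        if receptor not in set(norm.gene_symbols):
            raise ValueError(f"receptor {receptor!r} absent from matrix")
        partition = lr_mod.stratify_by_receptor(norm, ann, receptor, receiver_type)
        if "scores" not in state:
            raise ValueError("stratify requires the score stage")
        scores = state["scores"].loc[
            state["scores"].index.intersection(partition.index)
        ]
        partition = partition.loc[scores.index]
        libs = cm.libsizes().loc[scores.index]
        res = lr_mod.test_signalling_activity(
            scores, partition, libs,
            patients=ann.table.loc[scores.index, "patient"],
        )
        rows = [
            {"set": k, "p_positive_greater": v}
            for k, v in sorted(res["set_pvalues"].items())
        ]
        report["tables"]["signalling_tests"] = _write_tsv(
            pd.DataFrame(rows), out / "signalling_tests.tsv"
        )
        if res["per_patient_medians"] is not None:
            _write_tsv(
                res["per_patient_medians"], out / "signalling_per_patient.tsv"
            )
        report["libsize_confound"] = res["libsize_confound"]
        report["receptor_positive_cells"] = int(partition.sum())

    run_stage("stratify", do_stratify)

    _finalize(report, out)
    return report


def _finalize(report: dict, out: Path) -> None:
    import pleuroflow

    report["package_version"] = pleuroflow.__version__
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
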