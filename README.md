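# pleuroflow

Analysis toolkit for single-cell RNA-seq of **malignant pleural effusions
(MPEs)** — the mixed fluid of malignant, mesothelial and immune cells that
accumulates in the pleural cavity of advanced breast-cancer patients. The
central analytical difficulty in such data is that invading carcinoma cells
and resident mesothelial cells are phenotypically similar (shared keratins,
VIM, CD44), so the package combines several lines of evidence to tell them
apart and to characterize how they interact:

- **Consensus cell typing with marker gates.** Cells are labelled by
  nearest-centroid Spearman correlation against several pluggable reference
  profiles, combined by modal vote. Non-immune labels then pass a hard gate:
  malignant cells must express *EPCAM*; mesothelial cells must express *DES*
  (desmin) and not *EPCAM*; a cell negative for its primary gate gene is
  retained only if it expresses at least two markers from the corresponding
  discriminatory panel (epithelial: CLDN4, IMP3, MUC1, CDH1, CEACAM5,
  SCGB2A2, CLDN3, CLDN7; mesothelial: CALB2, WT1, UPK3B, CDH2, COL1A2,
  S100A4, MSLN). T cells get CD4/CD8 calls and nearest-centroid subtype
  projections, with removal of cells whose marker expression contradicts the
  projected subtype.
- **Expression-based CNV inference.** Per cell *c* and gene *g* in genomic
  order, the smoothed baseline-relative log-ratio

  `s_gc = clamp( MA_w( x_gc − mean_baseline(x_g) − median_c ) , ±1 )`

  where `x` is log2(1 + counts-per-10K), the baseline is a set of known
  non-malignant (immune) cells, `median_c` recentres each cell, and `MA_w`
  is a moving average over `w = 101` genes within each chromosome (shrinking
  windows at the ends). Gains appear as positive plateaus, losses as
  negative ones; immune and mesothelial cells stay flat.
- **Rank-based signature scoring.** A singscore-like statistic: the mean
  within-cell expression rank of the set genes, rescaled by its attainable
  extremes to [0, 1]; exactly invariant under monotone transforms of a
  cell's profile.
- **Pseudo-bulk subtyping and differential expression.** Counts are summed
  over (patient, cluster/type) groups; molecular subtype calls are
  nearest-centroid Spearman against a pluggable centroid table (LumA / LumB /
  Her2 / Basal / Normal-like vocabulary); DE uses Welch or patient-paired t
  tests on log2-CPM with Benjamini-Hochberg FDR, and pathway
  over-representation uses the hypergeometric upper tail.
- **Directed ligand-receptor inference.** Candidate pairs are scored by
  `(frac_sender(L)·mean_sender(L)) · (frac_receiver(R)·mean_receiver(R))`,
  the top-k kept, and a directional filter retains pairs whose ligand is
  expressed by the sender (fraction ≥ 0.10) but not the receiver (≤ 0.05).
  Receiver cells are then stratified by receptor positivity and downstream
  pathway activity is compared between strata, with a library-size confound
  check.

Everything is exercised end-to-end against a bundled synthetic-data
generator (`pleuroflow.sim`) that emulates an MPE cohort — 7 patients, six
cell types, patient-level CNV segments, a CAF-like mesothelial program and a
planted FGF2→FGFR2 mesothelial→malignant circuit — with full ground truth,
so every stage is testable without any download.

## Worked example

```python
from pleuroflow import sim, matrix, annotation, cnv

cfg = sim.SimConfig(n_patients=3, cells_per_patient=300, seed=42)
counts, truth = sim.simulate_mpe(cfg)
norm = matrix.lognormalize(matrix.qc_filter(counts))

refs = sim.make_reference_profiles(cfg, n_refs=3, seed=1)
votes = [annotation.reference_correlation_annotate(norm, r) for r in refs]
ann = annotation.consensus_annotate(votes, counts.cell_meta)
ann = annotation.gate_nonimmune_cells(ann, norm)

comp = matrix.composition_table(ann)
print(comp[comp.patient == "P1"].to_string(index=False))

order = cnv.build_genomic_order(counts.gene_meta)
act = ann.active_table()
immune = list(act.index[act.label.isin(["T", "NK", "B", "myeloid"])])
mal = list(act.index[act.label == "malignant"])
profile = cnv.infer_cnv_matrix(norm, order, baseline_cells=immune, cells=mal)
lo, hi = order.boundaries["8"]
print("mean chr8 signal in malignant cells:",
      round(profile.values[:, lo:hi].mean(), 3))
```

prints

```
patient   cell_type  n_cells  fraction
     P1           B       19  0.063333
     P1          NK       30  0.100000
     P1           T       51  0.170000
     P1   malignant      127  0.423333
     P1 mesothelial       28  0.093333
     P1     myeloid       45  0.150000
mean chr8 signal in malignant cells: 0.433
```

The composition table shows the per-patient cell-type mix after gating
(fractions sum to 1 per patient; malignant cells dominate, as configured).
The positive mean chr8 signal reflects the 2.0× copy-number gain the
generator plants on 150 contiguous chr8 genes in malignant cells — immune
baseline cells average near zero on the same region.

## Command line

The `pleuroflow` command exposes each stage as a file-based verb
(`simulate`, `ingest`, `qc`, `normalize`, `annotate`, `gate`, `tcells`,
`cluster`, `cnv`, `pseudobulk`, `score`, `subtype`, `de`, `enrich`, `lr`,
`stratify`) plus a config-driven `run`:

```bash
pleuroflow run --config fixture.yaml --out results/
```

`run` executes simulate/ingest → qc → normalize → annotate/gate → tcells →
cluster → cnv → score/subtype → de/enrich → lr/stratify, writes every stage
table as TSV and finishes with a versioned `report.json`. Runs are
deterministic: the same config produces byte-identical outputs.

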