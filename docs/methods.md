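# Methods

This note records the models, conventions and design choices behind
`pleuroflow`, and what the synthetic-data generator does and does not
emulate.

## Conventions used throughout

- **Normalization.** `log2(1 + 1e4 · count / libsize)` (log counts-per-10K,
  base 2, pseudocount 1). A zero count maps to exactly 0 and the transform
  is invariant to per-cell scaling of raw counts.
- **"Expressed".** Raw count ≥ 1, equivalently a positive normalized value.
  This single convention drives the marker gates, expression prevalence
  tables, ligand/receptor expressing fractions and receptor stratification.
- **Correlation.** Spearman rank correlation everywhere a profile is
  compared to a centroid (annotation, T-subtype projection, subtype calls,
  per-(patient, type) profile similarity); it is insensitive to monotone
  distortions of expression scale.
- **Multiple testing.** Benjamini-Hochberg step-up FDR, used identically for
  gene-level DE, marker curation and set-level enrichment.

## Cell typing

Automated labels come from nearest-centroid Spearman correlation against one
or more reference profiles; several references are combined by modal vote
(a cell is `unassigned` when the modal fraction falls below 0.5, ties break
lexicographically so results are deterministic). The classifier is a
deliberate simplification of reference-based annotation tools: the package's
contribution is the consensus and gating logic, and the references are
pluggable centroid tables.

The non-immune gate encodes the biology of the pleural compartment:
carcinoma cells are EPCAM-positive epithelium, mesothelial cells are
desmin-positive and EPCAM-negative. Because single-cell dropout makes any
single gene unreliable, a cell negative for its primary gate gene can fall
back to expressing at least two markers of the corresponding discriminatory
panel. The gate only retains, falls back or excludes — it never relabels.
Excluded cells keep their label for bookkeeping but are invisible to every
downstream computation (`CellAnnotation.active_table`).

T cells: CD8 call = (CD8A or CD8B) and not CD4; CD4 call = CD4 and neither
CD8 gene; both sides positive = double (retained regardless of projection).
Projection onto a T-subtype reference uses the same nearest-centroid
machinery; cells whose CD4/CD8 call contradicts the projected subtype class
(CD4-positive projected to CD8 Naïve-like / CD8 Early Active / CD8 Effector
Memory, or CD8-positive projected to Th1 / Tfh / CD4 Naïve-like) are
excluded. The operation is idempotent.

Data-driven marker curation is one-vs-rest Wilcoxon rank-sum per gene with
BH-FDR < 0.05 and positive effect, after removing mitochondrial (`MT-`) and
ribosomal (`RPL`/`RPS`) genes; cell types with fewer than 100 cells are not
tested. A gene significant for several types is assigned to the type with
the larger mean-difference effect, and the overlap is reported.

## CNV inference

The estimator is the minimal well-defined variant of expression-derived CNV
profiling: baseline subtraction (per-gene mean over known non-malignant
cells, immune labels by default) → per-cell median centring → per-chromosome
moving average along genomic gene order → clamping.

- `window = 101` genes (odd; shrinking asymmetric windows at chromosome
  ends rather than padding, so every value is a true mean of observed
  genes). `clamp = 1.0` log2 units.
- Median centring makes the signal exactly invariant to adding a constant
  to all of a cell's values.
- No HMM segmentation, subclone inference or allele-specific analysis; the
  output is the smoothed per-cell profile plus (patient, type) × region
  summaries (mean signal, fraction of cells with |region mean| > τ = 0.15).
- For display-scale outputs the pipeline subsamples up to 150 cells per
  (patient, cluster), uniformly without replacement under a fixed seed.

## Signature scoring and subtyping

The per-cell score of a gene set of size *s* in a universe of *G* genes is
`(mean rank of set genes − (s+1)/2) / (G − (s−1)/2 − (s+1)/2)`, with average
ranks on ties so all zero-count genes share the lowest ranks. The score is
bounded in [0, 1] and exactly invariant under strictly monotone transforms
of a cell's expression vector. Genes missing from the matrix are dropped
(logged), never zero-imputed; a set with no present gene is an error.

Molecular subtype calls are nearest-centroid Spearman against a centroid
table with a fixed vocabulary (ties break by vocabulary order). No published
rule set is bundled: the shipped fixtures are synthetic stand-ins
(`sim.make_subtype_centroids`, `sim.make_intrinsic_centroids`) that exercise
the mechanics; real centroid tables drop in as TSV. MKI67-style
stratification assigns a cluster "high" iff its mean log-expression strictly
exceeds the mean of cluster means.

## Pseudo-bulk DE and enrichment

Counts are aggregated (summed) per group before any testing, so duplicating
a cell inside a group or permuting cells cannot change results. Per gene the
test is Welch's two-sample t on log2(CPM+1) profiles, or the paired t across
patient-matched samples; genes with zero counts in every selected sample are
dropped. Genes whose variance vanishes on both sides get p = 1 when the
means agree and p = 0 otherwise. A t-on-pseudo-bulk engine was chosen over a
negative-binomial GLM because it is simple, defensible at these replicate
counts, and fully checkable against oracles; an NB engine is a natural
extension point. Enrichment is over-representation (hypergeometric upper
tail) of GMT sets intersected with the tested universe — not ranked GSEA —
because set lists with p-values are the required output and the statistic is
exactly enumerable.

## Ligand-receptor inference

Edges are scored with exactly the two per-node statistics such networks
display — expressing fraction and mean log-expression —
`score = (f_send(L)·m_send(L)) · (f_recv(R)·m_recv(R))`; ties break by pair
id so the ranking is deterministic and invariant to database row order. The
directional filter (ligand fraction ≥ 0.10 in the sender, ≤ 0.05 in the
receiver) operationalizes "expressed by the sender but not the receiver";
both thresholds are configuration. Receptor positivity is count ≥ 1. The
downstream activity test is a one-sided Wilcoxon rank-sum
(positive > negative) per scored set, accompanied by a two-sided rank-sum on
total counts between strata: a significant library-size difference flags the
comparison as potentially confounded rather than blocking it.

## The synthetic cohort

`sim.simulate_mpe` draws counts from a gamma-Poisson (negative-binomial)
model: `mean_gc = libsize_c · baseline_g · type_effect · cnv_fold ·
circuit_effect`, with log-normal library sizes and one global seed split
into per-stage substreams (genome, assignment, library sizes, receptor
choice, counts), so identical (config, seed) pairs are bit-identical.

Scaling choices, made once for the whole package:

- **Compressed gene universe.** ~2,100 genes over 22 chromosomes with
  procedurally generated 1-based positions. Each simulated gene stands for a
  block of real genes; accordingly the per-cell depth (median ≈ 49,000
  counts) concentrates on fewer genes than real data and the NB dispersion
  (0.03) is lower than single-gene estimates, because block-level averaging
  removes most gene-level biological noise. This keeps per-window CNV noise
  in the estimator's operating range at window 101 — the regime a full-size
  transcriptome provides via more genes per window.
- **Default composition** (per patient): malignant 0.40, T 0.20,
  mesothelial 0.12, myeloid 0.12, NK 0.10, B 0.06 — an MPE-like mix where
  malignant cells dominate and B cells are rare. Cell types are drawn iid
  per cell, so realized proportions are multinomial.
- **Planted biology.** Marker panels (about 6–12 genes per type, 2^7-fold
  in-type induction on a low baseline so off-type expressing fractions stay
  ~3%); an epithelial/luminal program in malignant cells and a CAF-like
  program (collagens, growth factors, matrix remodelling) in mesothelial
  cells (2^2-fold); patient-level CNV segments, by default a 2.0× gain over
  150 contiguous chr8 genes and a 0.5× loss over 120 chr17 genes in every
  patient's malignant cells (named genes are kept off chromosomes 8 and 17
  so segments contain only background genes); a proliferative MKI67-high
  malignant subset (30%); CD4/CD8 T-cell subsets; and an FGF2→FGFR2
  mesothelial→malignant circuit in which a planted 30% of malignant cells
  are receptor-positive (their FGFR2 count is forced ≥ 1 and the remainder
  to 0, so the stratification truth is exact) and carry a 4× induction of a
  15-gene downstream program.
- **Companion fixtures** derive from the same generative model: noisy
  expected-profile centroids as annotation references, a T-subtype
  reference, toy intrinsic-subtype centroids, a gene-set collection, and a
  ligand-receptor database of the planted pair plus random background pairs
  drawn from the sub-75th-percentile abundance pool (signalling genes are
  regulated, not housekeeping; an abundance-weighted pool would make the
  score ranking a readout of housekeeping expression).
- **Pseudo-bulk DE fixtures** (`sim.simulate_pseudobulk`) simulate the
  aggregated samples directly: per-gene means ~500 counts, NB dispersion
  0.01 across replicates — replicate variability is aggregation/sampling
  dominated, i.e. the replicates behave like technical aggregates of one
  population rather than heterogeneous patients.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: ambient RNA and doublets, batch effects
across library chemistries, patient-to-patient biological variability in
expression programs (programs are shared across patients; only CNV segments
are patient-keyed in configuration), realistic dropout depth (the compressed
universe is much denser than real matrices), sub-clonal CNV structure, and
any empirical fit to a real accession. Results on real data additionally
depend on the quality of the supplied reference profiles, centroid tables
and ligand-receptor database, all of which are user inputs.

## Numerical and determinism notes

- Windowed means use per-chromosome cumulative sums (float64); agreement
  with a brute-force windowed mean is at the 1e-12 level used in tests.
- Spearman correlations are computed by ranking with average ties and
  z-scored dot products; constant vectors correlate 0 rather than NaN.
- Clustering (scanpy: scaled top-2,000-variance genes → PCA (arpack) → kNN
  graph → Leiden via igraph, k = 20, 30 PCs, resolution 0.8) is
  deterministic under a fixed seed; an all-identical input short-circuits to
  a single cluster.
- Every random stage consumes an explicit seed; the pipeline derives
  per-stage seeds from the single config seed and echoes them in
  `report.json`, which contains no timestamps — two runs of the same config
  are byte-identical.
- Problem sizes used by the shipped checks: the reference cohort is 7
  patients × 700 cells (~2,100 genes); DE calibration uses 20 null
  simulations of 2,000 genes at 4 vs 4 samples; the ligand-receptor null
  specificity uses 100 cohorts of 2 patients × 400 cells without a planted
  circuit.

## Known limitations

- The annotation consensus assumes references share the cell-type
  vocabulary; no label harmonization is attempted.
- The CNV baseline must be supplied (immune labels by default); a
  contaminated baseline biases all profiles, and no external normal
  reference is bundled.
- Welch t at very low replicate counts cannot produce p-values small enough
  to survive FDR when between-replicate dispersion is large; with few
  patients and high heterogeneity an NB GLM engine would be preferable.
- The ligand-receptor score double-counts the receptor's expressing
  fraction (once directly, once inside the over-all-cells mean); this is the
  stated design — the score uses exactly the two published per-node
  statistics — but it penalizes receptors expressed in a cell subset.
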