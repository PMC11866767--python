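# Methods

## Scope and data model

The package analyses gene × cell integer count matrices carried as
`AnnData` (cells × genes, CSR sparse) with `library` and `condition`
(`control` / `tumor`) in `obs`. On-disk interchange is the 10x-style MTX
triplet (one `matrix.mtx` + `features.tsv` + `barcodes.tsv` per library)
plus one metadata TSV — plain text throughout.

## Synthetic data generator

The generator emulates the sorted-stroma study design rather than a whole
transcriptome:

* **Design.** Five libraries — three control, two tumor-engrafted — of
  `n_cells_per_library` cells each (default 2,000; the study's scale of
  ~50,000 cells is reachable but not required). Each library draws its
  cells' population identities from its condition's composition vector;
  defaults are the published per-condition proportions of the seven
  stromal populations (control ≈ 16.9% MSC … 0.4% chondrocyte; tumor
  ≈ 24.4% MSC … 1.2% chondrocyte).
* **Counts.** Negative binomial via gamma–Poisson with a single global
  dispersion θ (variance μ + μ²/θ, default θ = 5, a moderate overdispersion
  typical of UMI data; θ = ∞ gives the Poisson limit). Per-gene θ is a
  config extension point, not implemented.
* **Profiles.** Filler ("housekeeping") genes sit at a steady mean of 3.0,
  so their log-normalized variance is detection noise only. Marker genes
  have base mean 1.0 and are elevated `marker_fold`× (default 8) in their
  population, making them bimodal across populations — the property HVG
  selection keys on. Each population additionally elevates a deterministic
  block of ~6% of filler genes 3-fold (its "program"): real populations
  differ across dozens of genes, and a 3-gene signature alone would drown
  in NB noise at the log scale. Genes used by detection gates (Cdh5,
  Pecam1, Prrx1, Col1a1, Ighg2b) are near-silent (mean 0.005) outside the
  populations that express them (mean 4.0–6.0), so count ≥ 1 is an
  informative positivity rule.
* **Mitochondria.** A `mt-`-prefixed gene block is scaled so the expected
  mitochondrial fraction equals `mito_mean_fraction` (default 2%); per-cell
  variation comes from sampling noise.
* **Batch effect.** One log-normal size factor per library
  (`library_effect_sd`, default 0.15 on the log scale) multiplying all
  means — the simplest effect that exercises the integration substitute.
* **Tumor cells.** An Ighg2b+ plasma-cell profile spiked only into tumor
  libraries (default 2% of their cells).
* **Gradients.** `simulate_gradient` places cells uniformly on a latent
  axis in [0, 1] and interpolates expected expression piecewise-linearly
  between successive population profiles — the fixture for trajectory
  validation.
* **Determinism.** One seed; per-library child streams spawned in fixed
  order; identical config + seed gives bit-identical counts.

What the generator does **not** model: ambient RNA, doublets, UMI
saturation, per-gene dispersion, library-size variation within a library,
and correlated gene programs beyond block elevation. Passing tests
therefore demonstrate the pipeline's correctness and its behavior under
the stated noise model, not robustness to every artifact of real data.

## QC

Four predicates, all evaluated on pre-filter statistics over the combined
dataset, remove a cell when any holds: < 500 detected genes; > 5%
mitochondrial counts (`mt-` prefix, case-insensitive); detected genes above
the top-2% quantile; total counts above the top-5% quantile. Quantiles are
linearly interpolated empirical quantiles and removal is strictly-greater,
so fully tied data lose nothing. The filter is applied exactly once —
cutoffs shift after removal, so it is deliberately not idempotent.
Per-library quantiles are available behind a flag (default off: the
thresholds are stated once for all cells). The gene floor is read as
*unique genes* (the quantile rules already police transcript totals).

## Normalization, HVGs, embedding, clustering

* `value = ln(1 + 10,000 · count / cell_total)` (scale factor 10,000).
* HVGs: variance of normalized expression per library, averaged across
  libraries, top n (default 2,000), ties broken lexicographically — a
  deterministic vst-like criterion instead of a loess mean–variance fit.
  The synthetic gene universes (≤ 1,000 genes) are smaller than the
  default cut, so in-package analyses effectively standardize all genes;
  the selector's ranking contract is tested separately on planted
  high-variance genes.
* Embedding: HVGs standardized to mean 0 / variance 1 — per library by
  default, then pooled — followed by exact-SVD PCA (30 components for the
  integrated analysis, 50 per-library, both configurable). Component signs
  are fixed (largest-|loading| gene positive). Per-library standardization
  replaces anchor-based integration: the generator's batch model is a
  global size factor, which per-cell normalization plus per-library
  standardization removes exactly; the contract downstream stages rely on
  is that library identity is not linearly separable in the leading PCs.
* Clustering: Euclidean kNN graph in PC space (k = 20) and Leiden with the
  RB-configuration objective at resolution 0.2 by default, seeded; clusters
  relabeled by decreasing size. Leiden under a fixed seed is not formally
  invariant to vertex relabeling; on partition-stable (well-separated)
  data the partition is order-invariant, which is what the property test
  asserts.
* `subcluster` reruns normalize → HVG → embed on a subset and scans
  resolutions 0.05–2.0 (step 0.05), returning the smallest resolution whose
  cluster count hits `target_k`, else the closest count with a mismatch
  flag. The kNN graph is built once per subset; only the Leiden stage is
  re-run across the grid.

## Annotation and gates

Cluster score for a label = mean over its markers of the standardized mean
difference (cluster vs rest, pooled SD); argmax labels the cluster, ties
go lexicographically, and a winning margin < 0.1 flags ambiguity. AEC/SEC
calls compare standardized means of (Ly6a, Cxcl12) vs (Flt4, Il6st), with
exact ties falling to AEC by fixed precedence. Gates use raw-count
detection (count ≥ 1), the least parameterized positivity rule: tumor =
Ighg2b detected; EndoMT = (Cdh5 or Pecam1) and (Prrx1 or Col1a1), i.e.
panel-level co-expression — with EndoMT abundance reported relative to the
Cdh5+ cells of each condition at the same detection threshold.

## Differential abundance

Within each condition, B = 100 resamples of the condition's cells with
replacement; per-iteration RA per type; Welch t-test (Welch–Satterthwaite
df) comparing the B tumor vs B control RAs, with the Welch 95% CI on the
difference of means. Resampling n labeled cells and tabulating frequencies
is distributionally a multinomial draw over type counts, which is how the
replicates are generated (and why per-iteration counts conserve the
condition total exactly). The replicate t-test is anti-conservative by
construction — replicates are not independent observations — so p-values
like 1e-180 are a property of the procedure; they are computed in log
space, printed as 0 below the smallest positive normal double
(2.225074e-308), and accompanied by a plug-in two-proportion z-test column
marked as an extension. Sub-lineage analyses (MSC-lineage, BMEC) resample
within the lineage subset only.

## DE and preranked GSEA

Per-gene two-sided Wilcoxon rank-sum with tie-corrected normal
approximation on log-normalized values; logFC = difference of mean
log-normalized expression; BH correction. Ranking metric:
sign(logFC) · (−log10 p), p floored at 1e-300, ties by |logFC| then gene
id (a strict total order); pure-logFC ranking is available by flag.

Enrichment score: the weighted-KS running sum (hit increment
|score|^w / Σ_hits |score|^w with w = 1, miss decrement 1/(N − N_hits));
ES is the maximum |deviation|, taken at the earliest extremum in the walk
(an epsilon-guarded rule that settles exact ± ties deterministically).
Degenerate sets covering the whole universe define ES = 1 with a warning.
The null draws same-size random gene subsets per set and permutation
(preranked convention — no phenotype labels exist); NES divides ES by the
mean |null ES| of matching sign; nominal p is the matching-sign null tail
(with add-one smoothing); FDR q is ratio-of-tails over the pooled
normalized null, followed by a step-up monotonicity pass (from weakest
|NES| upward, cumulative minimum within each sign) so q never borrows
significance from stronger sets. Gene-set collections are read from GMT;
the bundled collections are synthetic stand-ins (curated hallmark
collections are external resources and are not redistributed).

## Trajectory

Complete Euclidean graph over cluster centroids in PC space → minimum
spanning tree → orthogonal projection of each cell onto its nearest tree
edge → pseudotime = geodesic tree distance from the root centroid to the
projection, shifted so the root cluster's minimum is 0 (projections
landing before the earliest root cell clip at 0). The root is a
user-specified cluster (the multipotent MSC-0 cluster for the MSC lineage;
AEC cluster 1 for the endothelial lineage). This is a deterministic
substitute for a learned principal graph; a learned graph in a nonlinear
embedding would differ metrically, so only ordinal claims (direction of
differentiation, branch ordering) are asserted or supported.

## Ligand activity

Sender-expressed ligands (detected in ≥ 10% of sender cells) are scored by
Pearson correlation between the ligand's prior target-potential row and
the receiver's 0/1 response over the stated universe; the default response
is the BH q < 0.05 condition-DE indicator within the receiver population.
AUROC is available behind a flag. Scores within 1e-12 of ±1 snap to ±1 so
a potential vector identical to the response scores exactly 1. Constant
responses are rejected (correlation undefined). Real ligand–target priors
are external; the bundled generator plants one causal ligand whose
potential concentrates on the response genes, giving the inference a
ground-truth benchmark.

## Numerical and testing choices

* All stochastic stages take explicit seeds; the pipeline manifest records
  file hashes so reruns are verifiable.
* Problem sizes in tests and the acceptance script are chosen to make the
  statistical assertions decisive at 4-SE tolerances: 45,000 cells for the
  seven-population recovery run (the rarest population, chondrocytes at
  0.4–1.2%, then exceeds 300 cells), 2,000–3,000 cells for gradient and
  gate checks, 100-seed repeats for calibration rates, with a reduced
  400-gene universe where the full one adds nothing.
* Known limitations: no doublet/ambient modeling; QC retention rates on
  synthetic data are not comparable to real-tissue attrition; Leiden
  order-invariance holds only on stable partitions; the bootstrap t-test
  inherits the stated anti-conservativeness; subcluster's resolution scan
  can fail to reach `target_k` on data whose community structure does not
  admit it (reported via the mismatch flag, never silently).
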