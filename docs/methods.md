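# Methods

This note documents the models, procedures and numerical choices behind
chickclock, and what the synthetic-data tests do and do not establish about
real WGBS data.

## Methylation calls and coordinates

A methylation track stores strand-resolved per-cytosine counts
(`meth_count`, `total_count`) in methratio-style layout: 1-based cytosine
positions, `+`/`-` strand, CG context. Ratios are always recomputed as
`meth_count / total_count` and are undefined (NaN) at zero coverage; values
in input files are never trusted. Genomic intervals use the BED convention
(0-based, half-open). These two conventions match the source formats
bit-exactly; the converters in `io.py` are the only crossing point. A CpG
dyad consists of the plus-strand cytosine at position p and the minus-strand
cytosine at p+1; `aggregate_strands` folds the dyad onto p by summing
counts. The standard coverage floor for using a ratio at all is three reads.

Per-interval methylation is the **unweighted mean of per-CpG ratios** over
CpGs passing the coverage rule (not a pooled-count ratio), so deeply covered
CpGs do not dominate an LMR's value. Per-strand records each count as one
observation; the per-strand coverage thresholds of the clock filters are
applied *before* any strand aggregation, taking "strand-specific coverage"
literally. Sliding-window summaries default to a non-overlapping 2-kb tiling
(step = window), the resolution at which genome-wide methylation
distributions are usually drawn; the step is configurable.

## LMR segmentation

Low-methylated regions are called per sample in four steps:

1. **Smoothing** — a centred running mean over `smooth_k` (default 3)
   neighbouring CpGs within a chromosome, truncated at the ends. Three CpGs
   damp single-CpG sampling noise without blurring region edges at typical
   LMR CpG densities.
2. **Run segmentation** — maximal runs of consecutive CpGs with smoothed
   methylation strictly below the cutoff `m` (default 0.5). Ties at the
   cutoff count as "not low"; strictness makes the rule deterministic.
   Runs with fewer than `min_cpgs_segment` (default 4) CpGs are dropped. A
   segment spans first to last CpG of its run (half-open), records its CpG
   count and the mean of the *unsmoothed* ratios.
3. **Classification** — segments with at least `umr_cpg_threshold`
   (default 30) CpGs are classed UMR (long CpG-island-like unmethylated
   regions), the rest LMR (short regulatory-element-like regions).
4. **FDR calibration (optional)** — for each cutoff on a 0.1–0.9 grid the
   false-discovery proportion is estimated as (mean segment count over
   `null_shuffles` position-preserving within-chromosome permutations of the
   ratios) / (observed segment count). Shuffling destroys the spatial
   clustering of methylation while preserving CpG spacing, so it nulls
   exactly the feature segmentation exploits. The estimated FDR grows with
   the cutoff, and the calibrator returns the **largest** cutoff whose FDR is
   at or below `fdr_target` (default 0.05) — the most sensitive setting that
   still controls false discoveries. If no cutoff qualifies (e.g. a
   methylome with no spatial coherence) or the track is degenerate, the
   default cutoff is returned with a warning flag.

No partially-methylated-domain pre-segmentation is attempted; PMDs are out
of scope for this genome. LMR sets from several samples are pooled by union
with merging of overlapping and book-ended intervals; pooled segments carry
no per-sample statistics until a feature matrix is built.

## Clock construction

**Site filters.** CpGs on sex chromosomes (Z/W — methylation there tracks
sex, not age) and CpGs at known SNP positions (apparent methylation change
may be genotype) are removed. Remaining CpGs must exceed a per-strand
coverage threshold in *every* sample: strictly greater than 10 for CpG-level
clocks, strictly greater than 5 for CpGs inside LMRs ("greater than" is
taken literally as a strict inequality).

**Feature matrix.** LMR features are per-sample interval means over the
filtered CpGs; CpG features are per-site ratios. Features not covered in
every sample are dropped, so the matrix has no missing entries.

**Tissue-offset normalization.** Tissues mature at different rates, so raw
feature values carry a per-tissue offset that confounds a multi-tissue age
axis. The offset estimate is the per-tissue per-feature mean over training
samples; normalized values are raw minus offset, making every
(tissue, feature) training mean exactly zero. Offsets are stored on the
model and re-used at prediction time; a tissue never seen in training falls
back to the global per-feature training mean, with a warning.

**Elastic net.** Age in days is regressed on normalized feature values by
minimizing

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢβ)² + λ[(1−α)/2 ‖β‖₂² + α ‖β‖₁]

with an unpenalized intercept. The solver is cyclic coordinate descent with
glmnet-style active-set iteration (full sweeps alternate with sweeps over
the nonzero set), warm-started along a descending λ path; the inner kernel
is numba-compiled. Convergence is declared when the largest coefficient
update in a sweep falls below `tol` (default 1e-8 for final fits, 1e-6
inside cross-validation). Features are *not* variance-standardized by
default — methylation values already share the [0,1] scale — but a
`standardize` flag exists. Mixing defaults are α = 0.9 for LMR clocks and
α = 0.7 for CpG clocks: strongly selective, giving a manageable marker set
at near-best fit.

**λ selection.** k-fold cross-validated RMSE over a geometric grid from
λ_max (smallest all-zero λ) down 3 decades; the minimizer wins and exact
ties go to the larger λ (sparser model). A `one_se` flag instead takes the
largest λ within one standard error of the minimum — with n = 36 the SE of
the CV curve is large, so the rule yields markedly sparser clocks and is off
by default.

**Cross-validation.** Folds are stratified by (tissue, age group) — age
groups are the distinct `age_days` values — seeded, and invariant to sample
order (stratum members are sorted by sample id before the seeded shuffle).
By default both the tissue offsets and λ are re-estimated inside each
training split, so nothing leaks from held-out samples; a
`refit_normalization=False` mode reproduces the simpler normalize-once
protocol, whose RMSE is optimistic because held-out samples contribute to
the offsets they are later corrected with; fold-internal re-estimation is
therefore the default. Prediction is ŷ = β₀ + Σⱼ βⱼ(xⱼ −
offset(tissue, j)), unclamped.

**Serialization.** Models round-trip through JSON with floats encoded as
decimal strings (`repr`), so weights, offsets and predictions are bit-exact
across the round trip. A schema version guards against stale files.

## Cohort analyses

*Differential LMRs* compare per-group means of raw (unnormalized) interval
methylation; a feature is hyper-/hypomethylated in B when the difference
exceeds 0.1 strictly (a difference of exactly 0.1 is not a call). Group
means are computed per-sample-then-averaged. *Age acceleration* is predicted
minus chronological age; groups are compared to a reference group with
Welch's two-sample t-test, two-sided by default (a one-sided flag covers the
directional hypothesis of acceleration). *Marker enrichment* in a genomic
feature class is (fraction of markers in the class) / (fraction of the
genome in the class); interval markers are assigned by midpoint (an
any-overlap mode exists behind a flag), and promoters, when derived, are the
1 kb upstream of the TSS. *PCA* is column-centered SVD with per-component
Pearson correlation against age. *Tissue contrasts* use the two-sided
Wilcoxon rank-sum test — exact null distribution for small tie-free samples,
tie-corrected normal approximation otherwise.

## Synthetic methylomes

The generator emulates the structure the pipeline assumes. CpG dyads are
placed with exponential spacing: mean 100 bp in the background (a realistic
genome-wide CpG density) and 35 bp inside planted regions, because
LMRs/regulatory elements are CpG-enriched and a 500-bp region at background
spacing would often fall below the minimum segment size. Planted regions
(default 500 of 300–600 bp) are placed disjointly on autosomes; the sex
chromosome carries background CpGs only and exists to exercise the filter. A
fraction (default 0.1) of regions drift with age, linearly on the logit
scale so trajectories stay inside (0,1): slope magnitudes U(0.05, 0.15)
logit/day, positive with probability 0.55; descending regions start high so
they end near the low baseline at day 35. Per-(tissue, region) offsets are
N(0, 0.5) logit units and exist only inside regions — tissue separation in
real methylomes is carried by regulatory-element methylation, not bulk
background. Treatment is modeled as a pure shift of effective age
(acceleration in days), the minimal mechanism consistent with inflammation
speeding the clock.

Counts are simulated per strand: coverage ~ Poisson(coverage_mean/2) per
strand (default total 40x, a realistic WGBS depth), methylated reads
beta-binomial with intraclass correlation `dispersion` (default 0.02; plain
binomial at 0). All randomness flows from one master seed;
per-sample seeds are spawned deterministically, and the full truth (region
coordinates, slopes, offsets, per-sample acceleration) is returned.

The **reference noise setting** used by the acceptance checks is coverage
40x, dispersion 0.02, and per-(sample, region) noise sd 0.25 logit — chosen
so that a single region predicts age only to ~2.5 days while the ensemble of
age-responsive regions supports day-level accuracy, the regime in which a
multi-locus clock is the right tool.

What the simulator does **not** capture: sequence-context effects and real
CpG clustering, bisulfite conversion failure, mapping artifacts, correlated
biological noise across loci (each region's noise is independent), nonlinear
or tissue-specific aging trajectories, and cell-composition effects. Passing
recovery tests therefore demonstrate the correctness and statistical
behaviour of the algorithms under the stated model, not performance on real
methylomes.

## Problem sizes and known limitations

The test and acceptance workloads use a 5-Mb autosome with 500 planted
regions (36-sample default cohort), 2-Mb genomes with 100 regions for
segmentation recovery, and 40–100 simulation replicates for power and
type-I checks; matrix-level quantities simulate only the CpGs inside feature
regions, which leaves the feature matrix unchanged in distribution.

A structural limitation worth stating: with n samples, an L1-dominant
elastic net (α = 0.9) selects at most ~n features — the response vector
lives in an (n−1)-dimensional centered space, so no more than that many
features carry non-redundant signal. On a 36-sample cohort the
cross-validated clock therefore keeps ~30 markers no matter how many truly
age-responsive regions exist; when 50 regions are planted, about 60% appear
among the nonzero weights and the remainder are absorbed by correlated
selected markers. Completeness of marker recovery at fixed small n requires
a ridge-dominant mixing (recall reaches 1.0 at α = 0.2), at the cost of a
much larger marker panel. Interpret clock weight sets as a sufficient
predictive panel, not as an exhaustive catalogue of age-responsive loci.
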