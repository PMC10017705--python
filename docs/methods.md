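# Methods

This note documents the models, parameter choices and numerical conventions
behind `watlas`, and what the synthetic-data generators do and do not
emulate.

## Synthetic data model

**Multi-study counts.** Counts are gamma-Poisson (negative binomial with
Var = μ + φμ², dispersion φ = 0.3 by default): gene base means are drawn
log-normally (σ = 1) around `base_mean` (0.5 counts per cell), each of the
`n_celltypes` planted types elevates its disjoint block of `markers_per_type`
marker genes by `marker_log2fc` = 2 (4-fold) in every study, and each study
multiplies every gene by an independent log-normal factor with log-scale sd
`batch_shift_sd` (0.3).  Cells are assigned to types uniformly at random;
depot (sc/om/pv) and method (scSeq/snSeq/STx) labels rotate round-robin over
studies.  The defaults (2 studies × 2000 cells × 2000 genes, 8 types × 30
markers) are sized so the planted markers dominate one-vs-rest fold-change
rankings without being trivial — detection still has to survive NB noise and
multiplicative batch effects.  The spec's configuration field list did not
include the gene-universe size, so `n_genes` is an explicit `SimConfig`
field (default 2000).

**Embeddings.** Each batch level gets a unit-variance Gaussian blob; blob
centres sit on a circle of radius `separation` = 8 and are displaced toward
the origin by the factor (1 − mixing).  At `mixing = 1` every blob collapses
onto the origin, so labels are exactly independent of position; at
`mixing = 0` blobs are ≥ 8σ apart and neighbourhoods are pure.

**Bulk cohorts.** Sample compositions are symmetric Dirichlet(1); bulk
expression is the convex signature mixture under multiplicative log-normal
noise (log-sd 0.2 by default).  A trait with planted effect (type t, slope
s) is s · z(p_t) + N(0,1), i.e. the slope is an effect size in SD units; a
slope of 1 corresponds to a population correlation of about 0.7.

**Spots.** Per-spot, per-type abundances are independent Gamma(2,1) draws —
cell-type loads, deliberately *not* a composition: simplex normalisation
would force a −1/(K−1) baseline correlation between all pairs (≈ −0.14 at
K = 8) and blur the null.  A planted colocalized pair shares an additive
Gamma(1, `coloc_strength` = 1) latent term, giving the pair a population
correlation of s²/(2+s²) ≈ 0.33 at the default — moderate, but far above
the zero null at 500 spots.  Ground truth additionally records normalised
per-spot shares.

**Time courses.** Marker genes of a cluster are multiplied by
`peak_fold` = 3 at the cluster's assigned timepoint only; "flat" clusters
stay constant; per-(gene, timepoint) log-normal noise (log-sd 0.05) keeps
flat-cluster fold-changes within a few percent of 1 when averaged over 30
markers.

**Platform profiles.** Discordant genes are planted in opposite-sign form
(+c on one platform, −c on the other, c ∈ [4.2, 5.0]) on a shared standard
normal background.  An additive one-sided shift would not survive the
z-score standardisation the concordance scorer applies — 20 shifted genes in
500 inflate the profile's sd enough to pull a 6-unit shift below the
5-unit detection threshold — whereas the symmetric construction inflates
both platforms equally, and the realised post-standardisation separation
2c/σ stays ≥ 6 z-units.  The realised Δz per planted gene is recorded in
the ground truth.

**What the generators do not emulate:** ambient RNA, doublets, zero-inflation
beyond NB sampling, gene–gene correlation within a cell type, per-cell
quality covariates, spatial autocorrelation of spots, and non-linear
trait–composition relationships.  Passing recovery tests therefore
demonstrates the pipeline's correctness and calibration under its stated
noise model, not robustness to every artefact of real tissue data.

## Marker detection

Counts are normalised to counts-per-10k and log2(x+1)-transformed.  The
per-gene test is the two-sided Wilcoxon rank-sum with tie-corrected normal
approximation; when both sides have ≤ 10 observations and no ties, the exact
distribution is used.  Fold-change is log2((mean_in + ε)/(mean_out + ε)) on
de-logged normalised values with ε = 1e-9 — stable when the background mean
is zero.  BH correction is applied per cluster across all genes tested,
matching per-cluster marker lists.  Selection thresholds are strict
(log2FC > 0.5, p_adj < 0.05), and sets are ordered by decreasing fold-change
with gene id as a deterministic tie-break.

## Cluster network

Overlap fractions are directed (|A∩B|/|A|, |A∩B|/|B|); the candidate rule —
max > 0.15 and min > 0.05, strict — and the top-5-by-Jaccard rule are
applied per node, with the final edge set the union over nodes: an edge
survives if either endpoint ranks it in its top five.  The union keeps the
graph symmetric and prevents small clusters from being orphaned by hubs; a
global top-k variant is available (`top_k_scope="global"`).  Jaccard ties at
the top-k boundary break by larger minimum overlap fraction, then
lexicographic node id.  Within-study edges are allowed but flagged.
Consensus classes are connected components, labelled in decreasing order of
total within-study size fraction.

## Integration metrics

*ARI* is computed directly from the contingency table; two degenerate
partitions (both single-cluster) give 1 by convention, with a warning.

*LISI* calibrates a per-point Gaussian bandwidth over the ⌈3·perplexity⌉
nearest neighbours (self excluded) by bisection until the weight
distribution's Shannon perplexity equals the target (default 30); the score
is the inverse Simpson index of the weighted covariate frequencies, in
[1, B].  With ~90 neighbours weighted to an effective sample of ~30, the
fully mixed two-batch mean sits near 1.91–1.97 rather than exactly 2 —
finite-sample variance of the weighted frequencies, not an implementation
artefact.

*kBET* samples `n_tests` anchors (without replacement when possible),
compares each anchor's k-nearest-neighbour batch composition to the global
frequencies with a Pearson χ² test (B − 1 dof, asymptotic p), and reports
1 − rejection rate.  Default k = ⌊0.1·n⌋ clamped to [10, 500]; k is always
recorded in the report.  Levels with expected neighbourhood count below 1
are pooled into "other".  At k = 50 with two equal batches the discreteness
of the count makes the exact null rejection ≈ 0.062 rather than α = 0.05
(the rejection region is |o − 25| ≥ 7), so acceptance under perfect mixing
is ≈ 0.94.

*Capping.* Each group level at or below the cap (default 1500) is kept
whole; larger levels contribute a uniform sample of exactly the cap, drawn
without replacement, deterministic under the seed.

## Deconvolution

For each cell type the samples × markers submatrix (log2(x+1), constant
rows dropped) is gene-centred; the score is the first left singular vector
scaled by its singular value — the first principal axis of marker
co-variation — sign-aligned to correlate positively with the mean centred
marker expression (ties resolve toward a positive loading sum).  Scores are
relative: comparable across samples within a type, arbitrary in scale, no
simplex constraint — the downstream uses are correlations and group
comparisons, not compositions.  A mean marker z-score alternative
(`method="mean_z"`) is provided.  Types with fewer than `min_genes` = 6
measured markers are skipped and flagged, never scored.

## Colocalization

Per-subject matrices are spot-wise Pearson correlations; zero-variance types
give NaN entries (flagged, never zero-filled).  Pooling across subjects is
an entry-wise Fisher-z average weighted by n_spots − 3 (unweighted and
concatenate-spots modes available; the pooling rule for a combined heatmap
is a design choice, not forced by the per-subject definition).  Grouping is
average-linkage on distance 1 − r, cut into `n_groups` = 3 by default; both
linkage inputs and the cut are configurable.

## Time-course and concordance scoring

The time-course score for cluster c at timepoint t is the mean over c's top
30 measured markers of expr(g,t) divided by that gene's mean across all
timepoints.  This background makes the score unit-free and centred at 1 and
leaves it invariant to global rescaling; a per-timepoint all-gene background
is available behind `background="timepoint_all_genes"` since the choice of
background is genuinely open.  ε = 1e-9 stabilises all ratios.  Enrichment
screens use strict > `min_fold` on ε-stabilised target/compendium-mean
ratios.  Platform discordance z-scores each platform over the gene set
(population sd), takes Δz for the named pair, and flags |Δz| > threshold
(default 5) strictly.

## Meta-analysis

Cohort correlations are Spearman ρ with midrank ties on pairwise-complete
observations; combinations with fewer than 4 complete pairs or constant
vectors are flagged out.  Pooling uses Fisher z = atanh(ρ) with variance
1/(n − 3) (the common-model convention; the Spearman-specific 1.06/(n − 3)
is available via `var_scale`), inverse-variance common effect, and
DerSimonian–Laird τ² with weights 1/(var + τ²) for the random-effects
model; Q and I² are reported; |ρ| = 1 is clipped to 0.9999 before atanh,
with a warning.  CIs are 95% two-sided on the z scale, back-transformed.
Association-profile clustering is average-linkage on Euclidean distance over
pooled-ρ vectors; groups are lettered A, B, C… in decreasing order of mean
signed association with the chosen ordering traits (insulin-resistance-like
by default), so the lettering is algorithmic rather than cosmetic.  Group
comparisons delegate to the standard tests (Mann–Whitney U, Wilcoxon
signed-rank with zeros dropped, paired t); all-zero paired differences give
p = 1 by convention, and exactly constant non-zero differences are reported
as a below-machine-precision p with a degeneracy flag rather than a NaN.

## Problem sizes and determinism

The test suite and the acceptance script run the recovery analyses at
2 studies × 2000 cells × 2000 genes (network), 100 samples × 8 types
(deconvolution), 500 spots × 100 replicates (colocalization), 8 cohorts ×
200 replicates (meta-analysis coverage), and n = 2000 embeddings with
k = 50, 500 anchor tests (kBET) — sizes at which every planted structure is
comfortably identifiable yet the full run completes in well under a minute.
Every generator and every stochastic stage (kBET anchor sampling, capping)
is a pure function of its parameters and an explicit integer seed;
identical inputs give bit-identical outputs.

## Known limitations

- The marker test ignores donor structure (no pseudobulk aggregation);
  p-values on real multi-subject data would be anti-conservative.
- kBET uses the asymptotic χ² null; at small k with many batch levels the
  finite-sample discreteness moves the null rejection rate off α.
- The first-principal-axis deconvolution score assumes the dominant axis of
  marker co-variation is the abundance signal; strongly correlated noise
  across a type's markers (e.g. batch effects within a bulk cohort) can
  hijack the axis.
- The colocalization grouping and association-profile clustering are
  descriptive: cluster counts are user choices, validated here only on
  planted block structure.
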