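# watlas

Cross-study comparison toolkit for single-cell and bulk transcriptomics of
white adipose tissue (WAT) — and, structurally, for any tissue atlas built by
re-analysing many independent studies.

Single-cell and single-nucleus studies of the same tissue rarely agree on a
cluster nomenclature: each study reports its own clusters, at its own
resolution, under its own batch structure.  `watlas` implements the
computational core of a multi-study harmonisation workflow:

- **Marker detection** (`watlas.markers`): one-vs-rest two-sided Wilcoxon
  rank-sum per cluster on library-size-normalised counts, fold-changes on
  de-logged means, Benjamini–Hochberg FDR per cluster, and marker-set
  selection at log₂FC > 0.5 ∧ p_adj < 0.05.
- **Cluster-correspondence network** (`watlas.atlas_graph`): nodes are
  (study, cluster) pairs; candidate edges require marker-set overlap
  fractions |A∩B|/|A| and |A∩B|/|B| to exceed 15% in one direction and 5% in
  both; each node keeps its five highest-Jaccard candidates; connected
  components of the retained graph are the consensus cell classes.
- **Integration metrics** (`watlas.integration_metrics`): adjusted Rand
  index, local inverse Simpson index (LISI, perplexity-calibrated Gaussian
  neighbourhoods), and kBET acceptance (1 − χ² rejection rate of local vs
  global batch composition), per covariate, plus a per-group object-capping
  subsampler (cap 1500).
- **Marker-gene deconvolution** (`watlas.deconv`): relative cell-type
  abundance scores for bulk or spot expression as the sign-aligned first
  principal axis of each type's gene-centred marker submatrix; types with
  fewer than six measured markers are skipped.
- **Spatial colocalization** (`watlas.spatial_coloc`): spot-wise Pearson
  correlation between cell-type abundances per subject, Fisher-z pooling
  across subjects, average-linkage grouping on 1 − r.
- **Signature scoring** (`watlas.signature_scoring`): cluster fold-change
  trajectories along bulk differentiation time courses (top-30 markers over
  their across-time mean), >50-fold enrichment screens, and cross-platform
  discordance (per-platform z-scoring over a gene set, |Δz| > 5).
- **Clinical meta-analysis** (`watlas.clinical_meta`): Spearman correlations
  of abundance scores with clinical traits per cohort, Fisher-z pooling with
  common (inverse-variance) and random-effects (DerSimonian–Laird τ²)
  models, association-profile clustering, and Mann–Whitney / Wilcoxon
  signed-rank / paired-t group comparisons.
- **Synthetic data** (`watlas.synthio`): gamma-Poisson multi-study count
  simulations with planted cell types and batch effects, embeddings with a
  tunable mixing parameter, bulk cohorts whose composition covaries with
  traits, spatial spots with planted colocalization, time courses with
  transient signatures, and platform profiles with planted discordant genes
  — every generator records its ground truth, so each pipeline stage is
  testable end to end.

## Worked example

Four synthetic bulk cohorts share a planted effect: the true proportion of
cell type `T4` drives an insulin-resistance-like trait.  Deconvolve each
cohort with the marker scorer, correlate scores with the trait, and pool:

```python
import watlas as w
from watlas.deconv import MarkerReference, score_samples
from watlas.clinical_meta import cohort_correlations, pool_correlations

sig, markers = w.make_signatures(n_celltypes=8, markers_per_type=30, seed=3)
per_cohort = []
for c in range(4):
    expr, traits, truth = w.simulate_bulk_cohort(
        sig, 100, {"homa_ir": ("T4", 1.0)}, noise_sd=0.2, seed=100 + c)
    scores = score_samples(expr, MarkerReference(markers=markers))
    tab = cohort_correlations(scores.scores, traits)
    row = tab[(tab.celltype == "T4") & (tab.trait == "homa_ir")].iloc[0]
    per_cohort.append((row.rho, row.n))
    print(f"cohort {c}: rho = {row.rho:.3f} (n = {row.n})")
mc = pool_correlations(per_cohort)
print(f"pooled (common effect): rho = {mc.fixed[0]:.3f} "
      f"[{mc.fixed[1]:.3f}, {mc.fixed[2]:.3f}], tau2 = {mc.tau2:.4f}")
```

Output:

```
cohort 0: rho = 0.690 (n = 100)
cohort 1: rho = 0.682 (n = 100)
cohort 2: rho = 0.596 (n = 100)
cohort 3: rho = 0.453 (n = 100)
pooled (common effect): rho = 0.613 [0.547, 0.671], tau2 = 0.0176
```

Each cohort recovers a strong positive rank correlation between the score of
the planted type and the trait it drives; the common-effect pool sharpens
the estimate (the 95% CI excludes zero by a wide margin) and the small τ²
reflects the mild between-cohort variability the simulation injects through
independent mixing proportions and noise draws.

The numbered scripts under `analysis/` run the full workflow in order —
simulation, marker network, integration benchmarking, deconvolution,
colocalization, time-course/concordance scoring, and the clinical
meta-analysis — writing tables to `results/` and large intermediates to
`scratch/`.  A `watlas` command-line interface exposes the same stages
(`watlas simulate`, `markers`, `network`, `metrics`, `deconvolve`, `coloc`,
`score-timecourse`, `concordance`, `meta`).

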