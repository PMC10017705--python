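"""Meta-analysis across eight synthetic bulk cohorts: deconvolution scores
are correlated with clinical traits per cohort (Spearman), pooled with
common and random effects models, and cell types grouped by association
profile.  One cell type (T4) carries a planted positive effect on an
insulin-resistance-like trait."""

import pandas as pd

import watlas as w
from watlas.clinical_meta import (association_matrix,
                                  cluster_association_profiles,
                                  cohort_correlations, meta_analyze)
from watlas.deconv import MarkerReference, score_samples

sig, mk = w.make_signatures(seed=3)
ref = MarkerReference(markers=mk)
EFFECTS = {"homa_ir": ("T4", 1.0), "hdl": ("T4", -0.8),
           "age": ("T0", 0.0)}

tables = []
for c in range(8):
    expr, traits, truth = w.simulate_bulk_cohort(
        sig, 80 + 10 * (c % 3), EFFECTS, noise_sd=0.2, seed=100 + c)
    scores = score_samples(expr, ref)
    tables.append(cohort_correlations(scores.scores, traits))

meta = meta_analyze(tables)
meta.round(4).to_csv("results/07_meta_correlations.csv", index=False)
assoc = association_matrix(meta).dropna()
groups = cluster_association_profiles(assoc, n_groups=3,
                                      order_by=["homa_ir"])
groups.to_csv("results/07_association_groups.csv")

focus = meta[meta.celltype == "T4"].set_index("trait")
print(meta.round(3).to_string(index=False))
print(f"\nT4 (planted): pooled rho with homa_ir = "
      f"{focus.loc['homa_ir', 'rho_fixed']:.2f} "
      f"[{focus.loc['homa_ir', 'fixed_lo']:.2f}, "
      f"{focus.loc['homa_ir', 'fixed_hi']:.2f}], with hdl = "
      f"{focus.loc['hdl', 'rho_fixed']:.2f}; association group "
      f"{groups['T4']!r} (group A = most positively associated with "
      "homa_ir). Age, with a zero planted slope, associates with nothing.")
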