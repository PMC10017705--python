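"""Score batch mixing with ARI, mean LISI and kBET acceptance on embeddings
with known mixing (0 = separated study blobs, 1 = labels independent of
position), per covariate, mirroring how integration methods are benchmarked
across sequencing methods, depots and cohorts.
"""

from pathlib import Path

import pandas as pd

import watlas as w
from watlas import io

ann = io.read_annotation(Path("scratch/atlas/annotation.csv"))
rows = []
for mixing in (0.0, 0.5, 1.0):
    emb = w.simulate_embedding(ann, mixing=mixing, seed=11,
                               covariate="study")
    report = w.integration_report(emb, covariates=["study", "method",
                                                   "depot"], seed=12)
    for _, r in report.to_frame().iterrows():
        rows.append({"mixing": mixing, **r})

table = pd.DataFrame(rows)
table.to_csv("results/03_integration_metrics.csv", index=False)
study = table[table.covariate == "study"]
print(table.round(3).to_string(index=False))
print("\nkBET acceptance across study rises from "
      f"{study.kbet_acceptance.iloc[0]:.2f} (separated) to "
      f"{study.kbet_acceptance.iloc[-1]:.2f} (fully mixed); LISI moves from "
      f"{study.mean_lisi.iloc[0]:.2f} toward the 2-batch limit "
      f"{study.mean_lisi.iloc[-1]:.2f}.")
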