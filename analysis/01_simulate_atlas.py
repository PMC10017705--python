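"""Simulate the multi-study single-cell collection used by the downstream
analyses: two studies sharing 8 planted cell types (30 markers each) under
study-specific batch effects, written as MTX + annotation + ground truth.

Large matrices go to scratch/; only the run summary lands in results/.
"""

import json
from pathlib import Path

import watlas as w
from watlas import io

SEED = 7
OUT = Path("scratch/atlas")

cfg = w.SimConfig(n_studies=2, n_celltypes=8, markers_per_type=30,
                  n_cells_per_study=2000, seed=SEED)
expr, ann, truth = w.simulate_multistudy_sc(cfg)
io.write_mtx(expr, OUT / "expression")
io.write_annotation(ann, OUT / "annotation.csv")
io.write_json(io.truth_to_json(truth), OUT / "truth.json")

summary = {
    "n_genes": expr.shape[0], "n_cells": expr.shape[1],
    "n_studies": cfg.n_studies, "n_celltypes": cfg.n_celltypes,
    "markers_per_type": cfg.markers_per_type, "seed": SEED,
}
Path("results").mkdir(exist_ok=True)
Path("results/01_simulation_summary.json").write_text(
    json.dumps(summary, indent=2))
print(f"simulated {expr.shape[1]} cells x {expr.shape[0]} genes across "
      f"{cfg.n_studies} studies -> {OUT}")
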