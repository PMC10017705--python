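import numpy as np
import pandas as pd
import pytest

import watlas as w


@pytest.fixture(scope="session")
def atlas_sim():
    """Two-study simulation with 8 shared planted types, plus per-study
    marker detection and selection.  Session-scoped: the marker testing on
    2 x 2000 cells is the most expensive step in the suite."""
    cfg = w.SimConfig(n_studies=2, n_celltypes=8, markers_per_type=30,
                      n_cells_per_study=2000, seed=7)
    expr, ann, truth = w.simulate_multistudy_sc(cfg)
    node_sets, sizes = {}, {}
    for study, sub_ann in ann.groupby("study"):
        tab = w.find_markers(expr[sub_ann.index], sub_ann["cluster"])
        for cl, ms in w.select_markers(tab, top_n=50).items():
            node_sets[(study, cl)] = ms
            sizes[(study, cl)] = float((sub_ann["cluster"] == cl).mean())
    return {"config": cfg, "expr": expr, "annotation": ann, "truth": truth,
            "node_sets": node_sets, "size_fractions": sizes}


@pytest.fixture(scope="session")
def signatures():
    sig, markers = w.make_signatures(n_genes=1000, n_celltypes=8,
                                     markers_per_type=30, seed=3)
    return sig, markers


@pytest.fixture()
def two_batch_annotation():
    n = 2000
    return pd.DataFrame(
        {"study": ["a"] * (n // 2) + ["b"] * (n // 2),
         "cluster": ["c0", "c1"] * (n // 2)},
        index=[f"obs{i:04d}" for i in range(n)])


def spearman_oracle(x, y):
    """Rank-then-Pearson Spearman, independent of scipy.spearmanr."""
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() /
                 np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def ari_oracle(a, b):
    """Direct contingency-table evaluation of the adjusted Rand formula."""
    from math import comb
    a, b = list(a), list(b)
    la, lb = sorted(set(a)), sorted(set(b))
    nij = np.zeros((len(la), len(lb)), dtype=int)
    for x, y in zip(a, b):
        nij[la.index(x), lb.index(y)] += 1
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sa = sum(comb(int(v), 2) for v in nij.sum(axis=1))
    sb = sum(comb(int(v), 2) for v in nij.sum(axis=0))
    exp = sa * sb / comb(len(a), 2)
    denom = 0.5 * (sa + sb) - exp
    return 1.0 if denom == 0 else (sum_ij - exp) / denom


def mannwhitney_u_oracle(x, y):
    """U statistic by direct pair counting (ties count one half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u
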