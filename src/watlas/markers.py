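"""One-vs-rest marker-gene detection and threshold-based marker selection.

Counts are library-size normalized internally (counts per 10k, log2(x+1));
each cluster is tested one-vs-rest per gene with a two-sided Wilcoxon
rank-sum test (tie-corrected normal approximation, exact when both sides have
<= 10 observations and no ties), fold-changes are computed on the de-logged
normalized means with a small pseudocount, and Benjamini-Hochberg correction
is applied per cluster across all genes tested.

Marker sets are selected with strict thresholds (log2 fold-change > 0.5 and
adjusted p < 0.05 by default), ordered by decreasing fold-change, optionally
truncated to the top N genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MARKER_TABLE_COLUMNS = ["cluster", "gene", "log2fc", "p", "p_adj",
                        "pct_in", "pct_out"]
EPS = 1e-9


@dataclass
class MarkerSet:
    """Ordered marker genes for one cluster plus the selection rule used."""

    cluster: str
    genes: list[str]
    selection_rule: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log2(counts / column-sum * scale + 1); zero-sum columns left at zero."""
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    totals[totals == 0] = 1.0
    norm = counts.to_numpy(dtype=float) / totals * scale
    return pd.DataFrame(np.log2(norm + 1.0), index=counts.index,
                        columns=counts.columns)


def _ranksum_pvalues(x: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (rows), vectorized.

    Normal approximation with tie correction; genes with zero rank variance
    (all values tied) get p = 1.
    """
    n1 = int(in_mask.sum())
    n2 = x.shape[1] - n1
    ranks = stats.rankdata(x, axis=1)
    r1 = ranks[:, in_mask].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction: sum over tie groups of (t^3 - t), per gene
    xs = np.sort(x, axis=1)
    tie_term = np.empty(x.shape[0])
    for g in range(x.shape[0]):
        breaks = np.flatnonzero(np.diff(xs[g]) != 0)
        t = np.diff(np.concatenate([[-1], breaks, [n - 1]])).astype(float)
        tie_term[g] = (t ** 3 - t).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(x.shape[0])
    ok = var > 0
    z = (u1[ok] - mu) / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z))
    return np.minimum(p, 1.0)


def _ranksum_exact(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Exact two-sided rank-sum p for one gene (small n, no ties)."""
    res = stats.mannwhitneyu(x_in, x_out, alternative="two-sided",
                             method="exact")
    return float(res.pvalue)


def find_markers(counts: pd.DataFrame, labels: pd.Series,
                 min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest differential expression for every cluster.

    Parameters
    ----------
    counts : genes x observations count matrix.
    labels : cluster assignment per observation (aligned to columns).

    Returns a MarkerTable data frame with one row per (cluster, gene):
    ``cluster, gene, log2fc, p, p_adj, pct_in, pct_out``.  log2fc is
    log2((mean_in + eps) / (mean_out + eps)) on de-logged (normalized)
    values; p_adj is Benjamini-Hochberg within cluster.  Clusters with fewer
    than ``min_cells`` observations are skipped with a warning.
    """
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some observations")
    clusters = labels.value_counts()
    usable = clusters[clusters >= min_cells].index
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest testing")
    for cl in clusters.index.difference(usable):
        warnings.warn(f"cluster {cl!r} has < {min_cells} observations; "
                      "skipped", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable clusters after size filter")

    logx = lognormalize(counts).to_numpy()
    norm = (2.0 ** logx) - 1.0      # de-logged normalized values
    detected = counts.to_numpy() > 0
    genes = counts.index.to_numpy()
    lab = labels.to_numpy()

    out_frames = []
    for cl in sorted(map(str, usable)):
        in_mask = lab.astype(str) == cl
        n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
        if n1 <= 10 and n2 <= 10:
            p = np.empty(len(genes))
            for g in range(len(genes)):
                xi, xo = logx[g, in_mask], logx[g, ~in_mask]
                if np.unique(np.concatenate([xi, xo])).size == xi.size + xo.size:
                    p[g] = _ranksum_exact(xi, xo)
                else:
                    p[g] = _ranksum_pvalues(logx[g:g + 1], in_mask)[0]
        else:
            p = _ranksum_pvalues(logx, in_mask)
        mean_in = norm[:, in_mask].mean(axis=1)
        mean_out = norm[:, ~in_mask].mean(axis=1)
        log2fc = np.log2((mean_in + EPS) / (mean_out + EPS))
        p_adj = multipletests(p, method="fdr_bh")[1]
        out_frames.append(pd.DataFrame({
            "cluster": cl,
            "gene": genes,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "pct_in": detected[:, in_mask].mean(axis=1),
            "pct_out": detected[:, ~in_mask].mean(axis=1),
        }))
    return pd.concat(out_frames, ignore_index=True)[MARKER_TABLE_COLUMNS]


def select_markers(table: pd.DataFrame, min_log2fc: float = 0.5,
                   max_padj: float = 0.05,
                   top_n: int | None = None) -> dict[str, MarkerSet]:
    """Threshold-based marker selection per cluster.

    Keeps rows with log2fc strictly above ``min_log2fc`` AND adjusted p
    strictly below ``max_padj``, sorts by decreasing log2fc (gene id breaks
    ties, for determinism) and truncates to ``top_n`` if given.  Clusters
    with no passing genes yield empty sets (with a warning).
    """
    if table.empty:
        raise ValueError("marker table is empty")
    rule = {"min_log2fc": min_log2fc, "max_padj": max_padj, "top_n": top_n}
    sets: dict[str, MarkerSet] = {}
    for cl, sub in table.groupby("cluster", sort=True):
        passing = sub[(sub["log2fc"] > min_log2fc)
                      & (sub["p_adj"] < max_padj)]
        passing = passing.sort_values(["log2fc", "gene"],
                                      ascending=[False, True])
        genes = passing["gene"].tolist()
        if top_n is not None:
            genes = genes[:top_n]
        if not genes:
            warnings.warn(f"cluster {cl!r}: no genes pass the marker "
                          "thresholds", stacklevel=2)
        sets[str(cl)] = MarkerSet(cluster=str(cl), genes=genes,
                                  selection_rule=dict(rule))
    return sets
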