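"""Within-spot cell-type colocalization from abundance estimates.

Per subject, colocalization is the spot-wise Pearson correlation between every
pair of cell-type abundance vectors.  Per-subject matrices are pooled by a
Fisher-z average weighted by (n_spots - 3) and back-transformed (an unweighted
mean and a concatenate-spots mode are available), and cell types are grouped
by average-linkage hierarchical clustering on distance 1 - r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

_ATANH_CLIP = 0.999999  # keeps Fisher z finite for r == +-1


@dataclass
class ColocalizationMatrix:
    """Symmetric cell-type correlation matrix for one subject (or pooled)."""

    subject: str
    r: pd.DataFrame
    n_spots: int


def colocalization_matrix(abundance: pd.DataFrame,
                          subject: str = "subject") -> ColocalizationMatrix:
    """Spot-wise Pearson correlations between cell-type abundances.

    ``abundance`` is spots x cell types, nonnegative.  Requires >= 3 spots;
    zero-variance types yield NaN rows/columns (flagged with a warning, never
    zero-filled).  The diagonal is 1 for types with positive variance.
    """
    if abundance.shape[0] < 3:
        raise ValueError(f"need >= 3 spots for spot-wise correlation, got "
                         f"{abundance.shape[0]}")
    if abundance.isna().to_numpy().any():
        raise ValueError("abundance matrix contains missing entries")
    constant = abundance.columns[abundance.std(axis=0) == 0].tolist()
    if constant:
        warnings.warn(f"zero-variance cell types give undefined "
                      f"correlations: {constant}", stacklevel=2)
    r = abundance.corr(method="pearson")  # pandas leaves NaN for constants
    return ColocalizationMatrix(subject=subject, r=r,
                                n_spots=int(abundance.shape[0]))


def pool_matrices(matrices: list[ColocalizationMatrix],
                  weighted: bool = True) -> pd.DataFrame:
    """Pool per-subject correlation matrices on the Fisher-z scale.

    Entry-wise atanh-average across subjects, weighted by (n_spots - 3) when
    ``weighted`` (unit weights otherwise), back-transformed by tanh.  The
    diagonal stays exactly 1; pooling is invariant to subject order.
    """
    if not matrices:
        raise ValueError("need at least one subject matrix")
    types = matrices[0].r.index
    for m in matrices[1:]:
        if not m.r.index.equals(types):
            raise ValueError("subject matrices disagree on cell types")
    zs, ws = [], []
    for m in matrices:
        r = m.r.to_numpy(dtype=float)
        z = np.arctanh(np.clip(r, -_ATANH_CLIP, _ATANH_CLIP))
        zs.append(z)
        ws.append(max(m.n_spots - 3, 1) if weighted else 1.0)
    zs = np.stack(zs)
    ws = np.asarray(ws, dtype=float)[:, None, None]
    valid = ~np.isnan(zs)
    wsum = (ws * valid).sum(axis=0)
    with np.errstate(invalid="ignore"):
        zbar = np.nansum(ws * np.where(valid, zs, 0.0), axis=0) / wsum
    pooled = np.tanh(zbar)
    np.fill_diagonal(pooled, 1.0)
    return pd.DataFrame(pooled, index=types, columns=types)


def concatenated_matrix(abundances: list[pd.DataFrame]) -> pd.DataFrame:
    """Alternative pooling: correlate after concatenating all subjects' spots."""
    stacked = pd.concat(abundances, axis=0)
    return colocalization_matrix(stacked, subject="concatenated").r


def pool_and_cluster(matrices: list[ColocalizationMatrix],
                     n_groups: int = 3, weighted: bool = True):
    """Pooled matrix plus cell-type groups by colocalization pattern.

    Average-linkage hierarchical clustering on distance 1 - pooled r, cut
    into ``n_groups``.  Cell types with any undefined pooled correlation are
    excluded from clustering with a warning.  Returns (pooled matrix, groups
    as a Series indexed by cell type with labels ``group_1..group_k``).
    """
    pooled = pool_matrices(matrices, weighted=weighted)
    usable = pooled.index[~pooled.isna().any(axis=1)]
    dropped = pooled.index.difference(usable)
    if len(dropped):
        warnings.warn(f"cell types excluded from clustering (undefined "
                      f"correlations): {list(dropped)}", stacklevel=2)
    sub = pooled.loc[usable, usable]
    if len(usable) < n_groups:
        raise ValueError(f"cannot cut {len(usable)} cell types into "
                         f"{n_groups} groups")
    dist = 1.0 - sub.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=n_groups, criterion="maxclust")
    # relabel deterministically by first appearance in cell-type order
    seen: dict[int, int] = {}
    labels = []
    for c in raw:
        seen.setdefault(c, len(seen) + 1)
        labels.append(f"group_{seen[c]}")
    groups = pd.Series(labels, index=usable, name="group")
    return pooled, groups
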