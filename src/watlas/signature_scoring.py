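"""Cluster-signature scoring along bulk time courses and platform concordance.

Time-course scoring: for each cluster, the fold-change of its top marker
genes at each timepoint over those genes' mean across all timepoints (a
unit-free score centered at 1; an all-gene per-timepoint background is
available behind a flag).  Used to place transient cluster signatures along
an in-vitro differentiation time course.

Platform concordance: select genes strongly enriched in a target profile
versus a compendium (>50-fold by default), z-score each platform's profile
over the gene set, and flag genes whose between-platform z-difference exceeds
a threshold (|dz| > 5 by default) as discordant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .markers import EPS, MarkerSet


def timecourse_scores(bulk: pd.DataFrame,
                      marker_sets: dict[str, MarkerSet],
                      top_n: int = 30,
                      background: str = "marker_mean",
                      min_measured: int = 5) -> pd.DataFrame:
    """Cluster x timepoint fold-change scores.

    ``bulk`` is genes x timepoints on a linear scale.  With the default
    ``background="marker_mean"``, FC(c, t) is the mean over c's top
    ``top_n`` measured markers of expr(g, t) / mean over timepoints of
    expr(g, .); markers constant over time give FC = 1 at every timepoint,
    and the score is invariant to rescaling the whole matrix.  With
    ``background="timepoint_all_genes"`` the denominator is instead the
    all-gene mean at each timepoint.  Clusters with fewer than
    ``min_measured`` measured markers are flagged with a warning (and still
    scored on what is measured, when nonempty).
    """
    if bulk.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    if background not in ("marker_mean", "timepoint_all_genes"):
        raise ValueError("unknown background mode")
    x = bulk.to_numpy(dtype=float)
    rows = {}
    counts = {}
    for cl, mset in sorted(marker_sets.items()):
        measured = [g for g in mset.genes if g in bulk.index][:top_n]
        counts[cl] = len(measured)
        if len(measured) < min_measured:
            warnings.warn(f"cluster {cl!r}: only {len(measured)} markers "
                          "measured in the bulk", stacklevel=2)
        if not measured:
            rows[cl] = np.full(bulk.shape[1], np.nan)
            continue
        sub = bulk.loc[measured].to_numpy(dtype=float)
        if background == "marker_mean":
            bg = sub.mean(axis=1, keepdims=True)
            if (bg <= 0).any():
                warnings.warn(f"cluster {cl!r}: zero background stabilized "
                              "with epsilon", stacklevel=2)
            rows[cl] = ((sub + EPS) / (bg + EPS)).mean(axis=0)
        else:
            bg = x.mean(axis=0)
            if (bg <= 0).any():
                warnings.warn("zero all-gene background stabilized with "
                              "epsilon", stacklevel=2)
            rows[cl] = (sub.mean(axis=0) + EPS) / (bg + EPS)
    fc = pd.DataFrame(rows, index=bulk.columns).T
    fc.index.name = "cluster"
    fc.attrs["marker_count"] = counts
    return fc


def enriched_genes(target: pd.Series, compendium: pd.DataFrame,
                   min_fold: float = 50.0) -> list[str]:
    """Genes enriched > ``min_fold`` in ``target`` over the compendium mean.

    Linear-scale, nonnegative profiles on a shared gene universe; the ratio
    is epsilon-stabilized.  The threshold is strict, as printed.
    """
    if compendium.shape[1] == 0:
        raise ValueError("compendium is empty")
    common = target.index.intersection(compendium.index)
    t = target.loc[common].to_numpy(dtype=float)
    ref = compendium.loc[common].to_numpy(dtype=float).mean(axis=1)
    ratio = (t + EPS) / (ref + EPS)
    return [g for g, r in zip(common, ratio) if r > min_fold]


def platform_discordance(profiles: pd.DataFrame,
                         pair: tuple[str, str],
                         threshold: float = 5.0,
                         reference: pd.Series | None = None) -> pd.DataFrame:
    """Between-platform z-score discordance over a gene set.

    ``profiles`` is genes x platforms over the (enriched) gene set.  Each
    platform column is z-scored across the genes (so columns end with mean 0,
    sd 1); ``delta_z = z_A - z_B`` for the named ``pair``; a gene is
    discordant iff |delta_z| strictly exceeds ``threshold``.  An optional
    ``reference`` profile is z-scored and carried through for context.
    """
    if profiles.shape[0] < 3:
        raise ValueError("need a gene set of size >= 3")
    for p in pair:
        if p not in profiles.columns:
            raise KeyError(f"platform {p!r} not in profiles")
    z = {}
    cols = list(profiles.columns)
    table = pd.DataFrame(index=profiles.index)
    frames = {c: profiles[c] for c in cols}
    if reference is not None:
        frames["reference"] = reference.reindex(profiles.index)
    for name, col in frames.items():
        v = col.to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"platform {name!r} has zero variance over "
                             "the gene set")
        z[name] = (v - v.mean()) / sd
        table[f"z_{name}"] = z[name]
    table["delta_z"] = z[pair[0]] - z[pair[1]]
    table["discordant"] = table["delta_z"].abs() > threshold
    table.attrs["pair"] = pair
    table.attrs["threshold"] = threshold
    return table
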