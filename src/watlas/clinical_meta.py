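"""Cell-type / clinical-trait correlations pooled across cohorts.

Per cohort, the association between a cell type's deconvolution score and a
clinical trait is a Spearman rank correlation on pairwise-complete samples.
Per (cell type, trait), cohort correlations are pooled on the Fisher-z scale
(variance 1/(n-3); the 1.06/(n-3) alternative is a flag) with both a common
(fixed-effect, inverse-variance) and a random-effects model (DerSimonian-
Laird tau^2), 95% CIs back-transformed by tanh, and Q / I^2 heterogeneity
statistics.  Cell types are grouped by average-linkage clustering of their
pooled association profiles, and standard paired/unpaired group comparisons
(Mann-Whitney U, Wilcoxon signed-rank, paired t) are provided for
intervention designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

_Z_CLIP = np.arctanh(0.9999)
_CI_Z = stats.norm.ppf(0.975)  # 95% two-sided


@dataclass
class MetaCorrelation:
    """Pooled estimates for one (cell type, trait) combination."""

    celltype: str
    trait: str
    per_cohort: list[tuple[float, int]]          # (rho_i, n_i)
    fixed: tuple[float, float, float]            # rho_hat, lo, hi
    random: tuple[float, float, float]
    tau2: float
    q: float
    i2: float
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.k = len(self.per_cohort)


def cohort_correlations(scores: pd.DataFrame, traits: pd.DataFrame,
                        min_n: int = 4) -> pd.DataFrame:
    """Spearman rho per (cell type, trait) for one cohort.

    Pairwise-complete observations with midrank ties; combinations with
    fewer than ``min_n`` complete pairs, or a constant vector, are flagged
    out (rho = NaN, flag column explains).  Returns a long data frame with
    columns ``celltype, trait, rho, n, flag``.
    """
    common = scores.index.intersection(traits.index)
    if len(common) == 0:
        raise ValueError("scores and traits share no sample ids")
    rows = []
    for ct in scores.columns:
        s = scores.loc[common, ct]
        for tr in traits.columns:
            t = traits.loc[common, tr]
            ok = s.notna() & t.notna()
            n = int(ok.sum())
            if n < min_n:
                rows.append((ct, tr, np.nan, n, f"n<{min_n}"))
                continue
            sv, tv = s[ok].to_numpy(), t[ok].to_numpy()
            if np.ptp(sv) == 0 or np.ptp(tv) == 0:
                rows.append((ct, tr, np.nan, n, "constant"))
                continue
            rho = stats.spearmanr(sv, tv).statistic
            rows.append((ct, tr, float(rho), n, "ok"))
    return pd.DataFrame(rows, columns=["celltype", "trait", "rho", "n",
                                       "flag"])


def pool_correlations(per_cohort: list[tuple[float, int]],
                      celltype: str = "", trait: str = "",
                      var_scale: float = 1.0) -> MetaCorrelation:
    """Common- and random-effects pooling of cohort correlations.

    z_i = atanh(rho_i), Var(z_i) = var_scale/(n_i - 3) (``var_scale=1.06``
    selects the Spearman-specific variance convention).  Fixed effect:
    inverse-variance weighted mean.  Random effects: DerSimonian-Laird
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)), weights
    1/(var_i + tau^2).  CIs computed on the z scale and back-transformed.
    |rho| = 1 is clipped to 0.9999 before atanh, with a warning.
    """
    if not per_cohort:
        raise ValueError("need at least one cohort")
    for rho, n in per_cohort:
        if n < 4:
            raise ValueError(f"cohort with n={n} < 4 cannot be pooled")
    rhos = np.array([r for r, _ in per_cohort], dtype=float)
    ns = np.array([n for _, n in per_cohort], dtype=float)
    if (np.abs(rhos) >= 1).any():
        warnings.warn("|rho| = 1 clipped before Fisher transform",
                      stacklevel=2)
    z = np.clip(np.arctanh(np.clip(rhos, -0.9999, 0.9999)),
                -_Z_CLIP, _Z_CLIP)
    var = var_scale / (ns - 3.0)
    w = 1.0 / var
    z_fixed = float((w * z).sum() / w.sum())
    se_fixed = float(np.sqrt(1.0 / w.sum()))
    k = len(rhos)
    q = float((w * (z - z_fixed) ** 2).sum())
    if k > 1:
        denom = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    else:
        tau2, i2 = 0.0, 0.0
    w_r = 1.0 / (var + tau2)
    z_rand = float((w_r * z).sum() / w_r.sum())
    se_rand = float(np.sqrt(1.0 / w_r.sum()))
    fixed = (float(np.tanh(z_fixed)),
             float(np.tanh(z_fixed - _CI_Z * se_fixed)),
             float(np.tanh(z_fixed + _CI_Z * se_fixed)))
    rand = (float(np.tanh(z_rand)),
            float(np.tanh(z_rand - _CI_Z * se_rand)),
            float(np.tanh(z_rand + _CI_Z * se_rand)))
    return MetaCorrelation(celltype=celltype, trait=trait,
                           per_cohort=[(float(r), int(n))
                                       for r, n in per_cohort],
                           fixed=fixed, random=rand, tau2=tau2, q=q, i2=i2)


def meta_analyze(cohort_tables: list[pd.DataFrame],
                 var_scale: float = 1.0) -> pd.DataFrame:
    """Pool every (cell type, trait) combination across cohort tables.

    Each table comes from :func:`cohort_correlations`.  Combinations flagged
    out in a cohort simply drop that cohort.  Returns a wide data frame with
    pooled estimates, CIs and heterogeneity per combination.
    """
    if not cohort_tables:
        raise ValueError("no cohorts supplied")
    stacked = pd.concat(cohort_tables, keys=range(len(cohort_tables)),
                        names=["cohort"]).reset_index(level=0)
    rows = []
    for (ct, tr), sub in stacked.groupby(["celltype", "trait"], sort=True):
        usable = sub[(sub["flag"] == "ok") & sub["rho"].notna()]
        if usable.empty:
            rows.append({"celltype": ct, "trait": tr, "k": 0,
                         "rho_fixed": np.nan, "fixed_lo": np.nan,
                         "fixed_hi": np.nan, "rho_random": np.nan,
                         "random_lo": np.nan, "random_hi": np.nan,
                         "tau2": np.nan, "Q": np.nan, "I2": np.nan})
            continue
        mc = pool_correlations(list(zip(usable["rho"], usable["n"])),
                               celltype=str(ct), trait=str(tr),
                               var_scale=var_scale)
        rows.append({"celltype": ct, "trait": tr, "k": mc.k,
                     "rho_fixed": mc.fixed[0], "fixed_lo": mc.fixed[1],
                     "fixed_hi": mc.fixed[2], "rho_random": mc.random[0],
                     "random_lo": mc.random[1], "random_hi": mc.random[2],
                     "tau2": mc.tau2, "Q": mc.q, "I2": mc.i2})
    return pd.DataFrame(rows)


def association_matrix(meta: pd.DataFrame,
                       estimate: str = "rho_random") -> pd.DataFrame:
    """Pivot a meta-analysis table into a cell-type x trait pooled-rho matrix."""
    return meta.pivot(index="celltype", columns="trait", values=estimate)


def cluster_association_profiles(assoc: pd.DataFrame, n_groups: int = 3,
                                 order_by: list[str] | None = None):
    """Group cell types by their pooled trait-association profiles.

    Average-linkage hierarchical clustering on Euclidean distance over the
    pooled-rho trait vectors, cut into ``n_groups``; rows with missing pooled
    values are excluded with a warning.  Groups are labelled A, B, C, ... in
    decreasing order of mean signed association with the ``order_by`` traits
    (all traits when None) — so group A is the most positively associated.
    An all-zero matrix is flagged degenerate (single group).
    """
    usable = assoc.index[~assoc.isna().any(axis=1)]
    dropped = assoc.index.difference(usable)
    if len(dropped):
        warnings.warn(f"cell types with missing pooled values excluded: "
                      f"{list(dropped)}", stacklevel=2)
    sub = assoc.loc[usable]
    if (sub.to_numpy() == 0).all():
        warnings.warn("all-zero association matrix: grouping degenerate",
                      stacklevel=2)
        return pd.Series("A", index=usable, name="group")
    if len(usable) < n_groups:
        raise ValueError(f"cannot cut {len(usable)} cell types into "
                         f"{n_groups} groups")
    z = linkage(pdist(sub.to_numpy(), metric="euclidean"), method="average")
    raw = fcluster(z, t=n_groups, criterion="maxclust")
    cols = order_by if order_by is not None else list(sub.columns)
    means = {c: sub.loc[raw == c, cols].to_numpy().mean()
             for c in np.unique(raw)}
    order = sorted(means, key=lambda c: -means[c])
    letters = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    return pd.Series([letters[c] for c in raw], index=usable, name="group")


def group_comparisons(scores: pd.DataFrame, design: str,
                      group: pd.Series | None = None,
                      pair_ids: pd.Series | None = None,
                      condition: pd.Series | None = None) -> pd.DataFrame:
    """Per-cell-type two-group tests.

    ``design="unpaired"``: two-sided Mann-Whitney U between the two levels of
    ``group`` (tie-corrected).  ``design="paired"``: two-sided Wilcoxon
    signed-rank over samples matched by ``pair_ids`` across the two levels of
    ``condition`` (zero differences dropped; all-zero differences are
    degenerate, p = 1 by convention).  ``design="longitudinal"``: paired t
    test on the same matching (all differences equal and nonzero is an exact-
    constant degeneracy: p reported as the smallest positive float, flagged).
    Returns columns ``celltype, statistic, p, n, flag``.
    """
    if design not in ("unpaired", "paired", "longitudinal"):
        raise ValueError("design must be unpaired, paired or longitudinal")
    rows = []
    if design == "unpaired":
        if group is None:
            raise ValueError("unpaired design needs a group series")
        levels = sorted(group.dropna().unique())
        if len(levels) != 2:
            raise ValueError("unpaired design needs exactly 2 groups")
        g1 = group[group == levels[0]].index
        g2 = group[group == levels[1]].index
        for ct in scores.columns:
            a = scores.loc[scores.index.intersection(g1), ct].dropna()
            b = scores.loc[scores.index.intersection(g2), ct].dropna()
            if len(a) < 3 or len(b) < 3:
                rows.append((ct, np.nan, np.nan, len(a) + len(b), "n<3"))
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append((ct, float(res.statistic), float(res.pvalue),
                         len(a) + len(b), "ok"))
    else:
        if pair_ids is None or condition is None:
            raise ValueError("paired designs need pair_ids and condition")
        levels = sorted(condition.dropna().unique())
        if len(levels) != 2:
            raise ValueError("paired design needs exactly 2 conditions")
        s0 = pair_ids[condition == levels[0]]
        s1 = pair_ids[condition == levels[1]]
        if s0.duplicated().any() or s1.duplicated().any():
            raise ValueError("duplicate pair ids within a condition")
        map0 = pd.Series(s0.index, index=s0.to_numpy())
        map1 = pd.Series(s1.index, index=s1.to_numpy())
        pairs = map0.index.intersection(map1.index)
        if len(pairs) != len(map0) or len(pairs) != len(map1):
            raise ValueError("unmatched pair ids between conditions")
        idx1 = map0.loc[pairs].to_numpy()
        idx2 = map1.loc[pairs].to_numpy()
        for ct in scores.columns:
            a = scores.loc[idx1, ct].to_numpy(dtype=float)
            b = scores.loc[idx2, ct].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            a, b = a[ok], b[ok]
            n = int(ok.sum())
            if n < 3:
                rows.append((ct, np.nan, np.nan, n, "n<3"))
                continue
            d = a - b
            if design == "paired":
                if np.all(d == 0):
                    rows.append((ct, 0.0, 1.0, n, "degenerate: all zeros"))
                    continue
                res = stats.wilcoxon(a, b, zero_method="wilcox",
                                     alternative="two-sided")
                rows.append((ct, float(res.statistic), float(res.pvalue),
                             n, "ok"))
            else:
                if np.ptp(d) == 0:
                    if d[0] == 0:
                        rows.append((ct, 0.0, 1.0, n,
                                     "degenerate: all zeros"))
                    else:
                        rows.append((ct, np.inf, float(np.finfo(float).tiny),
                                     n, "degenerate: constant difference"))
                    continue
                res = stats.ttest_rel(a, b)
                rows.append((ct, float(res.statistic), float(res.pvalue),
                             n, "ok"))
    return pd.DataFrame(rows, columns=["celltype", "statistic", "p", "n",
                                       "flag"])
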