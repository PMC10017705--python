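"""Batch-integration quality metrics on labeled embeddings.

Scores how well observations from different batches (sequencing method, fat
depot, cohort) mix in a low-dimensional embedding, using three complementary
metrics:

* ARI — chance-corrected agreement between the cluster partition and a batch
  covariate (low ARI against batch = good mixing);
* LISI — effective number of batch levels in each point's Gaussian-weighted
  neighborhood (inverse Simpson index; higher = better mixed);
* kBET acceptance — 1 minus the rate at which local neighborhoods' batch
  composition is rejected against the global composition by a chi-square test.

The metrics operate on the embedding as provided (typically 2-D UMAP
coordinates); no internal dimensionality reduction is performed.  A capping
subsampler equalizes object counts across groups before metric computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb
from sklearn.neighbors import NearestNeighbors


@dataclass
class Embedding:
    """Observation coordinates plus per-observation covariate labels."""

    coordinates: pd.DataFrame          # observations x d
    labels: pd.DataFrame               # observations x covariates
    cluster: pd.Series | None = None   # cluster assignment, if any

    def __post_init__(self) -> None:
        if self.coordinates.isna().to_numpy().any():
            raise ValueError("embedding coordinates contain missing values")
        if not self.coordinates.index.equals(self.labels.index):
            self.labels = self.labels.loc[self.coordinates.index]


@dataclass
class IntegrationReport:
    """ARI / mean LISI / kBET acceptance for one embedding, per covariate."""

    ari: dict[str, float]
    mean_lisi: dict[str, float]
    kbet_acceptance: dict[str, float]
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        covs = sorted(set(self.ari) | set(self.mean_lisi)
                      | set(self.kbet_acceptance))
        return pd.DataFrame({
            "covariate": covs,
            "ari": [self.ari.get(c, np.nan) for c in covs],
            "mean_lisi": [self.mean_lisi.get(c, np.nan) for c in covs],
            "kbet_acceptance": [self.kbet_acceptance.get(c, np.nan)
                                for c in covs],
        })


def adjusted_rand_index(labels1, labels2) -> float:
    """Adjusted Rand index between two partitions of the same observations.

    Computed from the contingency table: (sum_ij C(n_ij,2) - E) /
    (0.5*(sum_i C(a_i,2) + sum_j C(b_j,2)) - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2).  Both partitions trivial
    (a single cluster each, or all singletons) gives 1 by convention.
    """
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    if l1.shape != l2.shape:
        raise ValueError("label vectors differ in length")
    n = l1.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    ct = pd.crosstab(pd.Series(l1), pd.Series(l2)).to_numpy()
    sum_ij = comb(ct, 2).sum()
    a = comb(ct.sum(axis=1), 2).sum()
    b = comb(ct.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    denom = 0.5 * (a + b) - expected
    if denom == 0:
        # both partitions degenerate (all-one-cluster or all-singletons)
        warnings.warn("degenerate partitions: ARI set to 1 by convention",
                      stacklevel=2)
        return 1.0
    return float((sum_ij - expected) / denom)


def _knn(coords: np.ndarray, k: int):
    """k nearest neighbors excluding self; returns (distances, indices)."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, coords.shape[0]))
    nn.fit(coords)
    dist, idx = nn.kneighbors(coords)
    return dist[:, 1:], idx[:, 1:]


def lisi(embedding: Embedding, covariate: str,
         perplexity: float = 30.0) -> pd.Series:
    """Local inverse Simpson index per observation for one covariate.

    For each point, a Gaussian kernel over its ceil(3*perplexity) nearest
    neighbors is calibrated (per-point bandwidth, binary search) so the weight
    distribution's perplexity equals ``perplexity``; the score is the inverse
    Simpson index of the weighted covariate-level frequencies.  Scores lie in
    [1, B] for B levels: 1 = locally pure, B = perfectly mixed.
    """
    coords = embedding.coordinates.to_numpy(dtype=float)
    levels, codes = np.unique(
        embedding.labels[covariate].astype(str).to_numpy(),
        return_inverse=True)
    n, n_levels = coords.shape[0], len(levels)
    if n_levels == 1:
        return pd.Series(1.0, index=embedding.coordinates.index)
    k = int(np.ceil(3 * perplexity))
    if n - 1 < 2:
        raise ValueError("need at least 3 observations for LISI")
    dist, idx = _knn(coords, min(k, n - 1))
    d2 = dist.astype(float) ** 2
    d2[d2 == 0] = 1e-12  # coincident points: epsilon jitter
    log_perp = np.log(perplexity)
    scores = np.empty(n)
    target_levels = np.arange(n_levels)
    for i in range(n):
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        di = d2[i] - d2[i].min()
        for _ in range(64):
            w = np.exp(-beta * di)
            sw = w.sum()
            p = w / sw
            h = -(p * np.log(np.clip(p, 1e-300, None))).sum()
            if abs(h - log_perp) < 1e-5:
                break
            if h > log_perp:   # too flat -> sharpen
                beta_lo = beta
                beta = beta * 2 if np.isinf(beta_hi) else (beta + beta_hi) / 2
            else:
                beta_hi = beta
                beta = beta / 2 if beta_lo == 0 else (beta + beta_lo) / 2
        freq = np.bincount(codes[idx[i]], weights=p, minlength=n_levels)
        freq = freq[target_levels] / freq.sum()
        scores[i] = 1.0 / np.square(freq).sum()
    return pd.Series(scores, index=embedding.coordinates.index)


def kbet(embedding: Embedding, covariate: str, k: int | None = None,
         n_tests: int = 500, alpha: float = 0.05,
         seed: int = 0) -> tuple[float, dict]:
    """kBET acceptance rate (1 - rejection rate) for one covariate.

    Samples ``n_tests`` anchor observations; for each, compares the batch
    composition of its k nearest neighbors against the global level
    frequencies with a Pearson chi-square test (B-1 dof).  Default k is
    floor(0.1*n) clamped to [10, 500].  Levels whose expected neighborhood
    count k*f_b falls below 1 are pooled into "other" with a warning.
    """
    coords = embedding.coordinates.to_numpy(dtype=float)
    lab = embedding.labels[covariate].astype(str).to_numpy()
    n = coords.shape[0]
    levels, codes = np.unique(lab, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("kBET undefined for one batch")
    if k is None:
        k = int(np.clip(n // 10, 10, 500))
    if k >= n:
        raise ValueError(f"k={k} must be < number of observations {n}")
    freq = np.bincount(codes) / n
    if (k * freq < 1).any():
        warnings.warn("levels with expected neighborhood count < 1 pooled "
                      "into 'other'", stacklevel=2)
        rare = k * freq < 1
        pooled = np.where(rare[codes], len(levels), codes)
        levels_keep = np.unique(pooled)
        codes = np.searchsorted(levels_keep, pooled)
        freq = np.bincount(codes) / n
    n_levels = freq.size
    if n_levels < 2:
        raise ValueError("fewer than 2 usable batch levels after pooling")
    rng = np.random.default_rng(seed)
    anchors = (rng.choice(n, size=n_tests, replace=False) if n_tests <= n
               else rng.integers(0, n, size=n_tests))
    _, idx = _knn(coords, k)
    observed = np.stack([np.bincount(codes[idx[a]], minlength=n_levels)
                         for a in anchors])
    expected = k * freq
    chi2 = ((observed - expected) ** 2 / expected).sum(axis=1)
    pvals = stats.chi2.sf(chi2, df=n_levels - 1)
    rejection = float(np.mean(pvals < alpha))
    info = {"k": int(k), "n_tests": int(n_tests), "alpha": alpha,
            "seed": seed, "n_levels": int(n_levels)}
    return 1.0 - rejection, info


def cap_objects(annotation: pd.DataFrame, cap: int, group_by: str,
                seed: int = 0) -> pd.Index:
    """Subsample each level of ``group_by`` to at most ``cap`` observations.

    Levels at or below the cap are kept whole; larger levels contribute a
    uniform random sample of exactly ``cap`` without replacement.  Returns the
    retained index in the original order; deterministic under ``seed``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(annotation), dtype=bool)
    groups = annotation[group_by].to_numpy()
    for level in pd.unique(groups):
        pos = np.flatnonzero(groups == level)
        if pos.size <= cap:
            keep[pos] = True
        else:
            keep[rng.choice(pos, size=cap, replace=False)] = True
    return annotation.index[keep]


def integration_report(embedding: Embedding, covariates: list[str],
                       perplexity: float = 30.0, k: int | None = None,
                       n_tests: int = 500, alpha: float = 0.05,
                       seed: int = 0) -> IntegrationReport:
    """Full ARI / LISI / kBET report for one labeled embedding."""
    if embedding.cluster is None:
        raise ValueError("integration report requires a cluster assignment")
    ari, mlisi, acc = {}, {}, {}
    params: dict = {"perplexity": perplexity, "alpha": alpha,
                    "n_tests": n_tests, "seed": seed}
    for cov in covariates:
        ari[cov] = adjusted_rand_index(embedding.cluster.to_numpy(),
                                       embedding.labels[cov].to_numpy())
        mlisi[cov] = float(lisi(embedding, cov, perplexity=perplexity).mean())
        acc[cov], info = kbet(embedding, cov, k=k, n_tests=n_tests,
                              alpha=alpha, seed=seed)
        params["k"] = info["k"]
    return IntegrationReport(ari=ari, mean_lisi=mlisi, kbet_acceptance=acc,
                             parameters=params)
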