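"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (marker detection, cluster-graph
construction, integration metrics, deconvolution, colocalization, time-course
and platform-concordance scoring, clinical meta-analysis) is exercised on the
outputs of this module.  The generators emulate the *structure* of multi-study
adipose-tissue transcriptomics collections — several studies sharing planted
cell types under study-specific batch effects, bulk cohorts whose composition
covaries with clinical traits, spatial spots with planted colocalization, and
differentiation time courses with transient cluster signatures — while keeping
every planted feature recoverable and recorded in a :class:`GroundTruth`.

All generators are pure functions of their parameters and a seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integration_metrics import Embedding

DEPOTS = ("sc", "om", "pv")
METHODS = ("scSeq", "snSeq", "STx")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the multi-study single-cell count simulation.

    The count model is gamma-Poisson (negative binomial): gene base means are
    drawn log-normally around ``base_mean``, each cell type elevates its
    planted marker genes by ``marker_log2fc`` (log2 units) in every study, and
    each study applies an independent multiplicative per-gene effect with
    log-scale standard deviation ``batch_shift_sd``.
    """

    n_studies: int = 2
    n_celltypes: int = 8
    markers_per_type: int = 30
    n_cells_per_study: int = 1000
    batch_shift_sd: float = 0.3
    base_mean: float = 0.5
    dispersion: float = 0.3
    n_genes: int = 2000
    marker_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_studies", "n_celltypes", "markers_per_type",
                     "n_cells_per_study", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if self.markers_per_type * self.n_celltypes > self.n_genes:
            raise ValueError(
                "markers_per_type * n_celltypes exceeds n_genes: "
                f"{self.markers_per_type} * {self.n_celltypes} > {self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulation, for downstream recovery checks."""

    celltype_of_observation: pd.Series | None = None
    marker_genes_of_type: dict[str, list[str]] = field(default_factory=dict)
    true_proportions: pd.DataFrame | None = None
    planted_colocalized_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_discordant_genes: dict[str, float] = field(default_factory=dict)
    planted_peak_timepoint: dict[str, str] = field(default_factory=dict)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_multistudy_sc(config: SimConfig):
    """Simulate a multi-study single-cell count collection.

    Returns
    -------
    expr : pd.DataFrame
        genes x observations integer counts.
    annotation : pd.DataFrame
        per-observation ``study``, ``depot``, ``method``, ``subject``,
        ``cluster`` labels (cluster == planted cell type, named identically
        across studies so (study, cluster) nodes have known correspondences).
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:04d}" for i in range(config.n_genes)])
    types = [f"T{k}" for k in range(config.n_celltypes)]

    base = config.base_mean * rng.lognormal(mean=0.0, sigma=1.0,
                                            size=config.n_genes)
    # planted marker blocks: disjoint gene slices, one per type
    marker_idx = {
        t: np.arange(k * config.markers_per_type,
                     (k + 1) * config.markers_per_type)
        for k, t in enumerate(types)
    }
    boost = 2.0 ** config.marker_log2fc

    blocks, ann_rows = [], []
    for s in range(config.n_studies):
        study = f"study{s}"
        batch = np.exp(rng.normal(0.0, config.batch_shift_sd,
                                  size=config.n_genes))
        ct = rng.integers(0, config.n_celltypes,
                          size=config.n_cells_per_study)
        mean = np.tile((base * batch)[:, None],
                       (1, config.n_cells_per_study))
        for k, t in enumerate(types):
            cols = np.flatnonzero(ct == k)
            if cols.size:
                mean[np.ix_(marker_idx[t], cols)] *= boost
        counts = _nb_counts(rng, mean, config.dispersion)
        obs = [f"{study}_cell{i:05d}" for i in range(config.n_cells_per_study)]
        blocks.append(pd.DataFrame(counts, index=genes, columns=obs))
        ann_rows.append(pd.DataFrame({
            "study": study,
            "depot": DEPOTS[s % len(DEPOTS)],
            "method": METHODS[s % len(METHODS)],
            "subject": [f"{study}_subj{i % 4}" for i in
                        range(config.n_cells_per_study)],
            "cluster": [types[k] for k in ct],
        }, index=obs))

    expr = pd.concat(blocks, axis=1)
    annotation = pd.concat(ann_rows, axis=0)
    truth = GroundTruth(
        celltype_of_observation=annotation["cluster"].copy(),
        marker_genes_of_type={t: list(genes[idx])
                              for t, idx in marker_idx.items()},
    )
    return expr, annotation, truth


def simulate_embedding(annotation: pd.DataFrame, mixing: float, seed: int,
                       covariate: str = "study",
                       separation: float = 8.0) -> Embedding:
    """2-D embedding whose batch mixing is tunable.

    ``mixing=0`` places each level of ``covariate`` in its own Gaussian blob
    (unit variance, centers ``separation`` apart on a circle); ``mixing=1``
    collapses all centers so labels are independent of position; intermediate
    values interpolate the center displacement linearly.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError(f"mixing must be in [0, 1], got {mixing}")
    levels = annotation[covariate].astype(str)
    uniq = sorted(levels.unique())
    if len(uniq) < 2:
        raise ValueError("need >= 2 batch labels to simulate an embedding")
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(len(uniq)) / len(uniq)
    centers = separation * np.column_stack([np.cos(angles), np.sin(angles)])
    centers = {lv: c for lv, c in zip(uniq, centers)}
    offset = np.array([centers[lv] for lv in levels]) * (1.0 - mixing)
    coords = rng.normal(size=(len(levels), 2)) + offset
    coords = pd.DataFrame(coords, index=annotation.index, columns=["x", "y"])
    return Embedding(coordinates=coords, labels=annotation.copy(),
                     cluster=annotation["cluster"].astype(str)
                     if "cluster" in annotation else None)


def make_signatures(n_genes: int = 1000, n_celltypes: int = 8,
                    markers_per_type: int = 30, marker_fold: float = 8.0,
                    base_mean: float = 2.0, seed: int = 0):
    """Type-mean expression signatures with disjoint planted marker blocks.

    Returns (signatures genes x types, marker_genes_of_type dict).  Shared
    helper for the bulk, spot and time-course generators.
    """
    if markers_per_type * n_celltypes > n_genes:
        raise ValueError("marker blocks exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    types = [f"T{k}" for k in range(n_celltypes)]
    base = base_mean * rng.lognormal(0.0, 0.7, size=n_genes)
    sig = np.tile(base[:, None], (1, n_celltypes))
    markers = {}
    for k, t in enumerate(types):
        idx = np.arange(k * markers_per_type, (k + 1) * markers_per_type)
        sig[idx, k] *= marker_fold
        markers[t] = [genes[i] for i in idx]
    return pd.DataFrame(sig, index=genes, columns=types), markers


def simulate_bulk_cohort(signatures: pd.DataFrame, n_samples: int,
                         trait_effects: dict[str, tuple[str, float]],
                         noise_sd: float, seed: int,
                         dirichlet_alpha: float = 1.0):
    """Bulk cohort as convex mixtures of cell-type signatures.

    Each sample's composition is Dirichlet; expression is the mixture of
    signature columns under multiplicative log-normal noise with log-scale sd
    ``noise_sd``.  Each trait is a linear function (slope in SD units) of the
    z-scored true proportion of its target cell type plus unit Gaussian noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    types = list(signatures.columns)
    for trait, (ct, _) in trait_effects.items():
        if ct not in types:
            raise KeyError(f"trait {trait!r} targets unknown cell type {ct!r}")
    props = rng.dirichlet([dirichlet_alpha] * len(types), size=n_samples)
    samples = [f"sample{i:03d}" for i in range(n_samples)]
    bulk = signatures.to_numpy() @ props.T
    if noise_sd > 0:
        bulk = bulk * rng.lognormal(0.0, noise_sd, size=bulk.shape)
    expr = pd.DataFrame(bulk, index=signatures.index, columns=samples)
    prop_df = pd.DataFrame(props, index=samples, columns=types)
    traits = {}
    for trait, (ct, slope) in trait_effects.items():
        p = prop_df[ct].to_numpy()
        z = (p - p.mean()) / p.std() if p.std() > 0 else np.zeros_like(p)
        traits[trait] = slope * z + rng.normal(0.0, 1.0, size=n_samples)
    trait_table = pd.DataFrame(traits, index=samples)
    truth = GroundTruth(true_proportions=prop_df)
    return expr, trait_table, truth


def simulate_spots(signatures: pd.DataFrame, n_spots: int,
                   coloc_pairs: list[tuple[str, str]], seed: int,
                   coloc_strength: float = 1.0, noise_sd: float = 0.1,
                   gamma_shape: float = 2.0):
    """Spatial spots with planted cell-type colocalization.

    Per-spot, per-type abundances are independent gamma draws (spot-level
    cell-type loads, not a composition — no simplex constraint, so the null
    cross-type correlation is zero rather than the -1/(K-1) a Dirichlet
    would force).  Each planted pair shares an additive per-spot gamma
    latent factor (mean ``coloc_strength``) so its two types' abundances
    rise and fall together across spots.  Expression is the
    abundance-weighted signature mixture with multiplicative noise; the
    ground truth also records per-spot normalized shares.
    """
    types = list(signatures.columns)
    for a, b in coloc_pairs:
        if a == b:
            raise ValueError(f"colocalization pair must name two distinct "
                             f"cell types, got ({a!r}, {b!r})")
        for t in (a, b):
            if t not in types:
                raise KeyError(f"unknown cell type in coloc pair: {t!r}")
    if n_spots < 3:
        warnings.warn("fewer than 3 spots: spot-wise correlations are "
                      "undefined downstream", stacklevel=2)
    rng = np.random.default_rng(seed)
    gam = rng.gamma(gamma_shape, 1.0, size=(n_spots, len(types)))
    for a, b in coloc_pairs:
        latent = rng.gamma(1.0, coloc_strength, size=n_spots)
        gam[:, types.index(a)] += latent
        gam[:, types.index(b)] += latent
    spots = [f"spot{i:04d}" for i in range(n_spots)]
    abundance = pd.DataFrame(gam, index=spots, columns=types)
    shares = gam / gam.sum(axis=1, keepdims=True)
    expr = signatures.to_numpy() @ gam.T
    if noise_sd > 0:
        expr = expr * rng.lognormal(0.0, noise_sd, size=expr.shape)
    expr = pd.DataFrame(expr, index=signatures.index, columns=spots)
    truth = GroundTruth(
        true_proportions=pd.DataFrame(shares, index=spots, columns=types),
        planted_colocalized_pairs=list(coloc_pairs))
    return abundance, expr, truth


def simulate_timecourse(marker_sets: dict[str, list[str]],
                        timepoints: list[str],
                        peak_assignment: dict[str, str], seed: int,
                        peak_fold: float = 3.0, base_mean: float = 5.0,
                        noise_sd: float = 0.05,
                        n_background_genes: int = 200) -> pd.DataFrame:
    """Bulk differentiation time course with transient cluster signatures.

    A cluster's markers are elevated ``peak_fold``-fold only at its assigned
    timepoint; clusters assigned ``"flat"`` stay constant.  Log-normal noise
    with log-scale sd ``noise_sd`` is applied per (gene, timepoint).
    """
    for cl, tp in peak_assignment.items():
        if tp != "flat" and tp not in timepoints:
            raise KeyError(f"cluster {cl!r} assigned unknown timepoint {tp!r}")
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for gs in marker_sets.values():
        genes.extend(g for g in gs if g not in genes)
    genes += [f"BG{i:04d}" for i in range(n_background_genes)]
    base = base_mean * rng.lognormal(0.0, 0.5, size=len(genes))
    expr = np.tile(base[:, None], (1, len(timepoints)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for cl, tp in peak_assignment.items():
        if tp == "flat":
            continue
        rows = [gene_pos[g] for g in marker_sets[cl]]
        expr[rows, timepoints.index(tp)] *= peak_fold
    if noise_sd > 0:
        expr = expr * rng.lognormal(0.0, noise_sd, size=expr.shape)
    return pd.DataFrame(expr, index=genes, columns=timepoints)


def simulate_platform_profiles(n_genes: int = 500, n_discordant: int = 20,
                               seed: int = 0,
                               magnitude: tuple[float, float] = (4.2, 5.0),
                               platforms: tuple[str, str] = ("snSeq", "STx")):
    """Two platform pseudobulk profiles with planted discordant genes.

    Planted genes take opposite-sign values (+c on platform A, -c on B, with
    c drawn from ``magnitude``) on a shared standard-normal background.  The
    opposite-sign construction keeps the two profiles' spreads equal, so the
    z-score standardization the concordance scorer applies shrinks both sides
    by the same factor and the planted post-standardization separation
    2c / sd stays above 6 z-units for the default magnitudes; an additive
    one-sided shift would be attenuated below the detection threshold instead.
    Returns (profiles genes x 2 platforms, truth with planted z-shifts).
    """
    if n_discordant >= n_genes:
        raise ValueError("n_discordant must be < n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    background = rng.normal(0.0, 1.0, size=n_genes)
    a = background.copy()
    b = background.copy()
    planted_idx = rng.choice(n_genes, size=n_discordant, replace=False)
    mags = rng.uniform(*magnitude, size=n_discordant)
    signs = rng.choice([-1.0, 1.0], size=n_discordant)
    a[planted_idx] = signs * mags
    b[planted_idx] = -signs * mags
    profiles = pd.DataFrame({platforms[0]: a, platforms[1]: b}, index=genes)
    # realized shift on the standardized scale
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    truth = GroundTruth(planted_discordant_genes={
        genes[i]: float(za[i] - zb[i]) for i in planted_idx})
    return profiles, truth
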