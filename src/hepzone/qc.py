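"""Nucleus-level quality control, normalization, marker scoring, clustering.

QC keeps nuclei with at least ``min_genes`` detected genes and a mitochondrial
read fraction strictly below ``max_mito`` (nuclei at or above the cutoff are
discarded). Normalization is log1p of library-size-scaled counts. Each nucleus
is scored for pericentral and periportal marker expression as the mean of
per-gene z-scores, and nuclei are clustered by PCA -> kNN graph -> Louvain
community detection.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .io import MarkerSets

__all__ = [
    "ClusterConfig",
    "detected_genes",
    "mito_fraction",
    "filter_nuclei",
    "normalize_log",
    "score_markers",
    "cluster_nuclei",
    "exclude_outlier_clusters",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def detected_genes(adata: ad.AnnData) -> np.ndarray:
    """Number of genes with a nonzero count per nucleus (nFeatures)."""
    return (_dense(adata.X) > 0).sum(axis=1)


def mito_fraction(adata: ad.AnnData) -> np.ndarray:
    """Fraction of each nucleus's counts mapping to mitochondrial genes."""
    if "mito" not in adata.var:
        raise ValueError("count matrix has no per-gene 'mito' flag")
    X = _dense(adata.X)
    total = X.sum(axis=1)
    mito = X[:, adata.var["mito"].values.astype(bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def filter_nuclei(adata: ad.AnnData, min_genes: int = 500,
                  max_mito: float = 0.02) -> ad.AnnData:
    """Remove nuclei with < ``min_genes`` detected genes or a mitochondrial
    fraction of at least ``max_mito`` (the cutoff itself is discarded)."""
    keep = (detected_genes(adata) >= min_genes) & (mito_fraction(adata) < max_mito)
    if not keep.any():
        raise ValueError("QC filter removed every nucleus")
    out = adata[keep].copy()
    out.obs["n_features"] = detected_genes(out)
    out.obs["mito_frac"] = mito_fraction(out)
    return out


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log1p(count * scale / nucleus total); zero counts stay exactly zero."""
    X = _dense(adata.X).astype(float)
    total = X.sum(axis=1)
    if np.any(total == 0):
        bad = adata.obs_names[np.flatnonzero(total == 0)[0]]
        raise ValueError(f"nucleus {bad!r} has zero total counts; cannot normalize")
    out = adata.copy()
    out.X = np.log1p(X * scale / total[:, None])
    out.uns["normalized"] = {"scale": scale}
    return out


def score_markers(norm: ad.AnnData, markers: MarkerSets) -> pd.DataFrame:
    """Per-nucleus pericentral and periportal scores.

    Each marker gene's normalized expression is z-scored across nuclei
    (zero-variance genes contribute 0) and the score is the mean over the
    marker set. Markers missing from the panel are dropped with a warning.
    """
    scores = {}
    for name, genes in (("pericentral_score", markers.pericentral),
                        ("periportal_score", markers.periportal)):
        present = [g for g in genes if g in norm.var_names]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(f"{name}: markers not in panel, dropped: {missing}")
        if not present:
            raise ValueError(f"no {name} markers found in the gene panel")
        X = _dense(norm[:, present].X)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        # zero-variance guard with a relative tolerance against rounding
        ok = sd > 1e-10 * np.maximum(1.0, np.abs(mu))
        z = np.where(ok, (X - mu) / np.where(ok, sd, 1.0), 0.0)
        scores[name] = z.mean(axis=1)
    return pd.DataFrame(scores, index=norm.obs_names)


@dataclass
class ClusterConfig:
    n_pcs: int = 12
    resolution: float = 0.12
    k_neighbors: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


def cluster_nuclei(norm: ad.AnnData, config: ClusterConfig | None = None) -> np.ndarray:
    """PCA -> kNN graph -> Louvain modularity clustering.

    Deterministic given ``config.seed``; cluster labels are renumbered in
    order of first appearance so ties are broken by lowest nucleus index.
    """
    config = config or ClusterConfig()
    X = _dense(norm.X).astype(float)
    n, p = X.shape
    if n < config.k_neighbors:
        raise ValueError("fewer nuclei than k_neighbors")
    if config.n_pcs > min(n - 1, p):
        raise ValueError(f"n_pcs={config.n_pcs} exceeds the matrix rank bound "
                         f"min(n-1, p) = {min(n - 1, p)}")
    if np.allclose(X.var(axis=0), 0.0):
        return np.zeros(n, dtype=int)  # degenerate geometry: one cluster
    pcs = PCA(n_components=config.n_pcs, svd_solver="full").fit_transform(X)
    knn = kneighbors_graph(pcs, n_neighbors=min(config.k_neighbors, n - 1),
                           mode="connectivity", include_self=False)
    adj = knn.maximum(knn.T).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(adj.row.tolist(), adj.col.tolist())),
                     directed=False).simplify()
    igraph.set_random_number_generator(random.Random(config.seed))
    part = g.community_multilevel(resolution=config.resolution)
    labels = np.asarray(part.membership)
    # renumber in order of first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    return np.array([remap[lab] for lab in labels], dtype=int)


def exclude_outlier_clusters(norm: ad.AnnData, labels: np.ndarray,
                             n_pcs: int = 30, threshold: float = 3.0) -> np.ndarray:
    """Flag nuclei in clusters far from the main body of the data.

    A cluster is excluded when its PC-space centroid lies more than
    ``threshold`` median absolute deviations (over clusters) from the grand
    centroid. Returns a boolean keep-mask; intended as an optional cleanup
    before trajectory analysis and off by default in the pipeline.
    """
    labels = np.asarray(labels)
    X = _dense(norm.X).astype(float)
    n_pcs = min(n_pcs, min(X.shape[0] - 1, X.shape[1]))
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    uniq = np.unique(labels)
    centroids = np.vstack([pcs[labels == c].mean(axis=0) for c in uniq])
    grand = pcs.mean(axis=0)
    dist = np.linalg.norm(centroids - grand, axis=1)
    mad = np.median(np.abs(dist - np.median(dist)))
    if mad == 0:
        return np.ones(len(labels), dtype=bool)
    bad = uniq[dist > np.median(dist) + threshold * mad]
    return ~np.isin(labels, bad)
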