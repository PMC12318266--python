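"""Diffusion pseudodistance (DPD): the pipeline's 1-D lobular coordinate.

The normalized expression matrix is reduced by PCA, a Gaussian diffusion
kernel with Coifman–Lafon density normalization is built on PC space, and the
spectrum of the Markov transition matrix gives diffusion components. Diffusion
pseudotime (DPT) is the Euclidean distance from a root nucleus in
eigenvalue-rescaled diffusion-component space (components weighted by
lambda/(1-lambda)). DPT is min–max rescaled to [0, 1] and oriented with the
pericentral marker score so that 0 is the pericentral end of the lobule and 1
the periportal end; the rescaled, oriented quantity is the diffusion
pseudodistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse.linalg
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .io import MarkerSets
from .qc import _dense, score_markers

__all__ = [
    "PseudodistanceConfig",
    "DiffusionResult",
    "DPD",
    "density_normalized_kernel",
    "markov_matrix",
    "diffusion_map",
    "diffusion_pseudotime",
    "rescale_orient",
    "compute_dpd",
]


@dataclass
class PseudodistanceConfig:
    n_pcs: int = 30
    n_evecs: int = 15
    bandwidth_k: int = 15      # kernel bandwidth = median distance to k-th NN
    alpha: float = 1.0         # density-normalization exponent
    root_rule: str = "max_periportal_score"

    def __post_init__(self) -> None:
        if self.n_evecs < 2:
            raise ValueError("n_evecs must be >= 2")


@dataclass
class DiffusionResult:
    """Non-trivial eigenpairs of the diffusion operator."""

    eigenvalues: np.ndarray        # descending, trivial pair removed
    components: np.ndarray         # nuclei x n_evecs
    ids: pd.Index

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues > 1 + 1e-8) or np.any(self.eigenvalues <= -1):
            raise ValueError("diffusion eigenvalues must lie in (-1, 1]")


@dataclass
class DPD:
    """Per-nucleus diffusion pseudodistance in [0, 1] (0 = pericentral)."""

    values: pd.Series
    flipped: bool
    orientation: str = "oriented"   # 'oriented' | 'ambiguous'


def density_normalized_kernel(pcs: np.ndarray,
                              config: PseudodistanceConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel on PC space with Coifman–Lafon density normalization.

    The bandwidth is the median distance to the ``bandwidth_k``-th nearest
    neighbor. Returns the normalized kernel W and its row sums d; the Markov
    transition matrix is W / d[:, None].
    """
    n = pcs.shape[0]
    D = squareform(pdist(pcs))
    k = min(config.bandwidth_k, n - 1)
    kth = np.partition(D, k, axis=1)[:, k]
    sigma = float(np.median(kth))
    if sigma == 0:
        sigma = max(float(np.mean(kth)), 1e-12)
    W = np.exp(-(D ** 2) / (2.0 * sigma * sigma))
    if config.alpha != 0:
        q = W.sum(axis=1)
        W = W / np.outer(q, q) ** config.alpha
    off = W.sum(axis=1) - np.diag(W)
    if np.any(off < 1e-12):
        raise ValueError("kernel graph is disconnected for some nuclei; "
                         "increase the bandwidth (bandwidth_k)")
    return W, W.sum(axis=1)


def markov_matrix(pcs: np.ndarray,
                  config: PseudodistanceConfig | None = None) -> np.ndarray:
    """Row-stochastic diffusion transition matrix on PC coordinates."""
    config = config or PseudodistanceConfig()
    W, d = density_normalized_kernel(np.asarray(pcs, float), config)
    return W / d[:, None]


def diffusion_map(norm: ad.AnnData | np.ndarray,
                  config: PseudodistanceConfig | None = None) -> DiffusionResult:
    """Diffusion-map embedding of the normalized expression matrix."""
    config = config or PseudodistanceConfig()
    if isinstance(norm, ad.AnnData):
        X, ids = _dense(norm.X).astype(float), norm.obs_names
    else:
        X = np.asarray(norm, float)
        ids = pd.Index([str(i) for i in range(X.shape[0])])
    n = X.shape[0]
    if n <= config.n_pcs:
        raise ValueError("need more nuclei than n_pcs")

    n_pcs = min(config.n_pcs, X.shape[1], n - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)

    W, d = density_normalized_kernel(pcs, config)
    # symmetric conjugate of the Markov matrix for a stable eigendecomposition
    S = W / np.sqrt(np.outer(d, d))
    k_eig = min(config.n_evecs + 1, n - 1)
    evals, evecs = scipy.sparse.linalg.eigsh(S, k=k_eig, which="LA")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(d)[:, None]
    # drop the trivial (constant) eigenpair and clip rounding above 1
    evals = np.minimum(evals[1:], 1.0)
    psi = psi[:, 1:]
    # deterministic sign: largest-magnitude entry of each component positive
    for j in range(psi.shape[1]):
        i = np.argmax(np.abs(psi[:, j]))
        if psi[i, j] < 0:
            psi[:, j] = -psi[:, j]
    return DiffusionResult(eigenvalues=evals, components=psi, ids=pd.Index(ids))


def diffusion_pseudotime(dmap: DiffusionResult, root) -> pd.Series:
    """DPT(i) = || (psi_i - psi_root) * lambda/(1-lambda) ||."""
    if isinstance(root, str):
        if root not in dmap.ids:
            raise ValueError(f"root nucleus {root!r} not among retained nuclei")
        root_idx = dmap.ids.get_loc(root)
    else:
        root_idx = int(root)
        if not 0 <= root_idx < len(dmap.ids):
            raise ValueError("root index out of range")
    lam = dmap.eigenvalues
    if np.any(lam >= 1 - 1e-12):
        raise ValueError("non-trivial eigenvalue equal to 1: kernel graph is "
                         "disconnected")
    w = lam / (1.0 - lam)
    diff = (dmap.components - dmap.components[root_idx]) * w
    return pd.Series(np.linalg.norm(diff, axis=1), index=dmap.ids, name="dpt")


def rescale_orient(dpt: pd.Series, pc_scores: pd.Series,
                   pp_scores: pd.Series | None = None) -> DPD:
    """Min–max rescale DPT to [0, 1] and orient it pericentral -> periportal.

    If the pericentral score increases with the rescaled coordinate, the axis
    is flipped so that DPD = 0 sits at the pericentral end. A constant
    pericentral score leaves the orientation unchanged and flags it ambiguous.
    """
    vals = np.asarray(dpt, float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("DPT contains non-finite values")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("DPT is constant; cannot rescale")
    scaled = (vals - lo) / (hi - lo)
    pc = np.asarray(pc_scores.reindex(dpt.index) if isinstance(pc_scores, pd.Series)
                    else pc_scores, float)
    rho = spearmanr(scaled, pc).statistic
    if not np.isfinite(rho):
        return DPD(pd.Series(scaled, index=dpt.index, name="dpd"),
                   flipped=False, orientation="ambiguous")
    flipped = rho > 0
    if flipped:
        scaled = 1.0 - scaled
    return DPD(pd.Series(scaled, index=dpt.index, name="dpd"),
               flipped=bool(flipped), orientation="oriented")


def compute_dpd(norm: ad.AnnData, markers: MarkerSets,
                config: PseudodistanceConfig | None = None) -> DPD:
    """End-to-end DPD: marker scores -> diffusion map -> DPT from the
    highest-periportal-score nucleus -> rescale and orient."""
    config = config or PseudodistanceConfig()
    scores = score_markers(norm, markers)
    dmap = diffusion_map(norm, config)
    root = scores["periportal_score"].idxmax()
    dpt = diffusion_pseudotime(dmap, root)
    return rescale_orient(dpt, scores["pericentral_score"],
                          scores["periportal_score"])
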