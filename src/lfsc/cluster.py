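"""Cluster-number estimation and final K-means labeling.

Cells are labeled by K-means on the cell rows of the spectral embedding F.
When k is not supplied, a cluster-tree stability surrogate estimates it:
K-means solutions across a grid of k are linked level-to-level by shared
cells, and the estimate is the resolution past which clusters stop splitting
into substantial children.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import ClusterResult, ExpressionMatrix, SpectralEmbedding

__all__ = ["estimate_k", "kmeans_labels"]


def _level_instability(labels_k: np.ndarray, labels_k1: np.ndarray, child_frac: float) -> float:
    """Fraction of cells whose cluster at level k splits substantially at k+1.

    A cluster "splits" when >= 2 of its children at the next level each
    receive at least ``child_frac`` of its cells.
    """
    n = labels_k.size
    unstable_cells = 0
    for c in np.unique(labels_k):
        members = labels_k1[labels_k == c]
        sizes = np.bincount(members)
        big_children = np.count_nonzero(sizes >= child_frac * members.size)
        if big_children >= 2:
            unstable_cells += members.size
    return unstable_cells / n


def estimate_k(
    x: ExpressionMatrix,
    k_grid: range | list[int] = range(2, 16),
    seed: int = 0,
    n_pcs: int = 20,
    child_frac: float = 0.20,
    instability_budget: float = 0.05,
) -> int:
    """Estimate the number of clusters from cluster-tree stability.

    Seeded K-means is run on the top principal components for every k in the
    grid (plus one extra level); consecutive levels are linked by shared
    cells, and per-level instability is the fraction of cells whose cluster
    splits into >= 2 children each holding >= ``child_frac`` of it. The
    estimate is the smallest grid k from which every higher level stays
    within ``instability_budget`` — i.e. the resolution beyond which further
    splitting is noise. Falls back to the largest grid value if no level is
    stable.
    """
    ks = sorted(set(int(k) for k in k_grid))
    if not ks:
        raise ValueError("empty k grid")
    n = x.n_cells
    if max(ks) >= n:
        ks = [k for k in ks if k < n]
        warnings.warn("k grid truncated to fewer clusters than cells", stacklevel=2)
        if not ks:
            raise ValueError("no feasible k in grid")

    feats = x.values.T
    n_comp = min(n_pcs, feats.shape[0] - 1, feats.shape[1])
    if n_comp >= 1 and n_comp < feats.shape[1]:
        feats = PCA(n_components=n_comp, random_state=seed).fit_transform(feats)

    levels = ks + [ks[-1] + 1]
    labelings = {
        k: KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(feats)
        for k in levels
        if k <= n
    }
    instab = {}
    for k in ks:
        nxt = k + 1
        if nxt not in labelings:
            instab[k] = 0.0
            continue
        instab[k] = _level_instability(labelings[k], labelings[nxt], child_frac)

    for k in ks:
        if all(instab[j] <= instability_budget for j in ks if j >= k):
            return k
    return ks[-1]


def kmeans_labels(
    emb: SpectralEmbedding, k: int, seed: int = 0, restarts: int = 10
) -> ClusterResult:
    """K-means (k-means++ seeding, best of ``restarts`` inits) on cell rows of F."""
    cells = emb.cell_rows
    if k > cells.shape[0]:
        raise ValueError("more clusters than cells")
    if k != emb.k:
        warnings.warn(
            f"clustering into k={k} groups on a k={emb.k}-dimensional embedding",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(cells)
    return ClusterResult(labels=labels, k=k)
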