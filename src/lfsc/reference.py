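"""Building the reference panel (anchor dictionary) R'.

Three routes, matching how anchors can be sourced in practice:

* ``select_bulk_references`` — keep the bulk samples that win the per-cell
  best-Pearson-correlation vote (each cell nominates its most correlated bulk
  sample; a sample survives iff nominated at least once);
* ``build_sc_references`` — average labeled cells per cell type, optionally
  downsampling each type first (weak supervision from labeled scRNA-seq);
* ``kmeans_anchors`` — unsupervised K-means centroids (ablation mode; no
  labels, so no annotation downstream).
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.cluster import KMeans

from .containers import BulkPanel, ExpressionMatrix, ReferencePanel

__all__ = [
    "select_bulk_references",
    "build_sc_references",
    "kmeans_anchors",
    "pearson_matrix",
]


def pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations between two feature-aligned matrices.

    Returns an (x columns) x (y columns) matrix. Correlations involving a
    zero-variance column are defined as 0.
    """
    xc = x - x.mean(axis=0, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(xc, axis=0)
    yn = np.linalg.norm(yc, axis=0)
    num = xc.T @ yc
    denom = np.outer(xn, yn)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(corr, -1.0, 1.0)


def select_bulk_references(x: ExpressionMatrix, r: BulkPanel) -> ReferencePanel:
    """Retain the bulk samples that best explain at least one cell.

    For each cell, compute Pearson correlation against every bulk sample over
    the shared genes and record the argmax (ties broken by lowest sample
    index). Samples nominated by no cell are dropped; the survivors keep the
    panel's original order. A cell whose correlations are all zero (e.g. a
    zero-variance profile) casts no vote.
    """
    if x.layer != "normalized":
        raise ValueError("bulk reference selection expects normalized cells")
    if x.gene_ids != r.gene_ids:
        raise ValueError("gene spaces must be aligned (run intersect_genes first)")
    corr = pearson_matrix(x.values, r.values)  # cells x samples
    if np.all(corr == 0):
        raise ValueError("all correlations undefined: zero variance everywhere")
    best = np.argmax(corr, axis=1)
    voted = corr[np.arange(corr.shape[0]), best] != 0
    winners = np.unique(best[voted])
    keep = np.sort(winners)
    return ReferencePanel(
        values=r.values[:, keep],
        gene_ids=list(r.gene_ids),
        sample_ids=[r.sample_ids[j] for j in keep],
        cell_type_labels=[r.cell_type_labels[j] for j in keep],
        provenance="bulk-selected",
    )


def build_sc_references(
    x: ExpressionMatrix,
    labels: list[str],
    ratio: float = 1.0,
    seed: int = 0,
) -> ReferencePanel:
    """One reference sample per cell type: the mean profile of a labeled subset.

    For each type, ``ceil(ratio * n_type)`` cells are drawn without
    replacement (seeded) and averaged. ``ratio=1`` reproduces the exact class
    means regardless of seed. Types appear in order of first occurrence.
    """
    if not (0 < ratio <= 1):
        raise ValueError("ratio must lie in (0, 1]")
    if len(labels) != x.n_cells:
        raise ValueError("one label per cell required")
    labels = [str(lab) for lab in labels]
    types = list(dict.fromkeys(labels))
    rng = np.random.default_rng(seed)
    cols = []
    for t in types:
        members = np.flatnonzero(np.asarray(labels, dtype=object) == t)
        n_draw = math.ceil(ratio * members.size)
        chosen = members if n_draw >= members.size else np.sort(
            rng.choice(members, size=n_draw, replace=False)
        )
        cols.append(x.values[:, chosen].mean(axis=1))
    return ReferencePanel(
        values=np.column_stack(cols),
        gene_ids=list(x.gene_ids),
        sample_ids=[f"ref_{t}" for t in types],
        cell_type_labels=types,
        provenance="sc-averaged",
    )


def kmeans_anchors(x: ExpressionMatrix, d_prime: int, seed: int = 0) -> ReferencePanel:
    """Unsupervised anchors: K-means centroids of the cell profiles."""
    if not (1 <= d_prime <= x.n_cells):
        raise ValueError("d_prime must lie in [1, n_cells]")
    km = KMeans(n_clusters=d_prime, n_init=10, random_state=seed)
    km.fit(x.values.T)
    return ReferencePanel(
        values=km.cluster_centers_.T,
        gene_ids=list(x.gene_ids),
        sample_ids=[f"anchor_{j}" for j in range(d_prime)],
        cell_type_labels=None,
        provenance="kmeans",
    )
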