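"""Reference-based cell-type annotation of clusters.

Each cluster's mean expression profile is correlated (Pearson, over the
shared highly variable genes) with every labeled reference sample. A cluster
adopts the cell type of its best-correlated reference only when that
correlation strictly exceeds the threshold (default 0.6); otherwise it is
reported as "Unknown type" — the mechanism by which novel populations absent
from the reference panel surface.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    AnnotationResult,
    BulkPanel,
    ClusterResult,
    ExpressionMatrix,
    ReferencePanel,
)
from .reference import pearson_matrix

__all__ = ["annotate_clusters", "UNKNOWN_TYPE"]

UNKNOWN_TYPE = "Unknown type"


def annotate_clusters(
    x: ExpressionMatrix,
    clusters: ClusterResult,
    ref: ReferencePanel | BulkPanel,
    threshold: float = 0.6,
) -> AnnotationResult:
    """Assign one cell type per cluster from its best-correlated reference.

    Ties at the maximum correlation break to the lowest reference index. A
    zero-variance cluster mean correlates 0 with everything and is therefore
    Unknown. Cells inherit the type of their cluster.
    """
    labels = getattr(ref, "cell_type_labels", None)
    if labels is None:
        raise ValueError("reference panel carries no cell-type labels (kmeans anchors?)")
    if x.gene_ids != ref.gene_ids:
        raise ValueError("gene spaces of cells and references are not aligned")
    if clusters.n_cells != x.n_cells:
        raise ValueError("cluster labels do not match cell count")

    means = np.column_stack(
        [x.values[:, clusters.labels == c].mean(axis=1) for c in range(clusters.k)]
    )
    corr = pearson_matrix(means, ref.values)  # clusters x references
    best = np.argmax(corr, axis=1)  # argmax takes the first (lowest) index on ties
    best_corr = corr[np.arange(clusters.k), best]

    cluster_types = [
        labels[j] if c > threshold else UNKNOWN_TYPE for j, c in zip(best, best_corr)
    ]
    sample_ids = ref.sample_ids
    return AnnotationResult(
        cluster_types=cluster_types,
        best_correlations=best_corr,
        best_references=[sample_ids[j] for j in best],
        cell_types=[cluster_types[c] for c in clusters.labels],
    )
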