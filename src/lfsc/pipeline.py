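"""End-to-end orchestration: preprocessing -> anchors -> fit -> labels -> types.

`run_pipeline` is the single entry point the CLI, the examples and the
acceptance checks all share. It accepts raw counts plus one anchor source
(a bulk panel, per-cell labels for averaging, or a K-means anchor count) and
returns every intermediate the caller might want to inspect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .annotation import annotate_clusters
from .anchor_graph import fit_lfsc
from .cluster import estimate_k, kmeans_labels
from .containers import (
    AnchorGraph,
    AnnotationResult,
    BulkPanel,
    ClusterResult,
    ExpressionMatrix,
    FitState,
    ReferencePanel,
    SpectralEmbedding,
)
from .preprocessing import (
    intersect_genes,
    log1p_bulk,
    lognormalize,
    qc_filter_genes,
    select_hvgs,
)
from .reference import build_sc_references, kmeans_anchors, select_bulk_references

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    normalized: ExpressionMatrix
    reference: ReferencePanel
    anchor_graph: AnchorGraph
    embedding: SpectralEmbedding
    fit_state: FitState
    clusters: ClusterResult
    annotation: AnnotationResult | None
    k: int


def run_pipeline(
    counts: ExpressionMatrix,
    bulk: BulkPanel | None = None,
    ref_labels: list[str] | None = None,
    kmeans_d_prime: int | None = None,
    k: int | None = None,
    n_hvg: int = 2000,
    do_qc: bool = True,
    do_hvg: bool = True,
    log_transform_bulk: bool = True,
    downsample_ratio: float = 1.0,
    delta: float = 1.0,
    beta0: float = 0.01,
    max_iter: int = 30,
    tol: float = 1e-6,
    annotation_threshold: float = 0.6,
    seed: int = 0,
) -> PipelineResult:
    """Run the full method on raw counts.

    Exactly one anchor source must be given: ``bulk`` (reference selection by
    per-cell best correlation), ``ref_labels`` (per-type averaging with
    optional ``downsample_ratio``), or ``kmeans_d_prime`` (unsupervised
    centroids; no annotation). ``k=None`` triggers the cluster-tree
    estimator. ``log_transform_bulk`` applies ln(v+1) to bulk values; pass
    False when the panel is already on a log scale.
    """
    sources = [bulk is not None, ref_labels is not None, kmeans_d_prime is not None]
    if sum(sources) != 1:
        raise ValueError("give exactly one of bulk, ref_labels, kmeans_d_prime")

    x = qc_filter_genes(counts) if do_qc else counts
    selection = select_hvgs(x, n_hvg=n_hvg) if do_hvg else None
    normed = lognormalize(x)

    if bulk is not None:
        if log_transform_bulk:
            bulk = log1p_bulk(bulk)
        normed, bulk = intersect_genes(normed, bulk, selection)
        reference = select_bulk_references(normed, bulk)
    else:
        if selection is not None:
            pos = {g: i for i, g in enumerate(normed.gene_ids)}
            normed = normed.subset_genes([pos[g] for g in selection.kept_gene_ids])
        if ref_labels is not None:
            reference = build_sc_references(
                normed, ref_labels, ratio=downsample_ratio, seed=seed
            )
        else:
            reference = kmeans_anchors(normed, int(kmeans_d_prime), seed=seed)

    if k is None:
        k = estimate_k(normed, seed=seed)
    if int(k) > reference.n_samples:
        warnings.warn(
            f"k={k} exceeds the {reference.n_samples} reference samples; "
            f"clamping to {reference.n_samples}",
            stacklevel=2,
        )
    k = min(int(k), reference.n_samples)

    graph, emb, state = fit_lfsc(
        normed,
        reference,
        k=k,
        delta=delta,
        beta0=beta0,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
    )
    clusters = kmeans_labels(emb, k=k, seed=seed)

    annotation = None
    if reference.cell_type_labels is not None:
        annotation = annotate_clusters(
            normed, clusters, reference, threshold=annotation_threshold
        )
    return PipelineResult(
        normalized=normed,
        reference=reference,
        anchor_graph=graph,
        embedding=emb,
        fit_state=state,
        clusters=clusters,
        annotation=annotation,
        k=k,
    )
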