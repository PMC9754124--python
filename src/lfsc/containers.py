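"""In-memory containers shared across the pipeline.

All expression containers are genes-in-rows, cells/samples-in-columns, stored
as dense ``numpy`` arrays (the workloads this package targets are anchored by a
small reference panel, so the matrices that matter are m x n and d' x n, never
n x n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "BulkPanel",
    "GeneSelection",
    "ReferencePanel",
    "AnchorGraph",
    "SpectralEmbedding",
    "FitState",
    "ClusterResult",
    "AnnotationResult",
    "MetricReport",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix.

    Parameters
    ----------
    values
        Nonnegative reals, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Row / column identifiers. Gene ids must be unique.
    layer
        ``"raw"`` for counts, ``"normalized"`` after log-normalization.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.layer not in ("raw", "normalized"):
            raise ValueError(f"unknown layer tag {self.layer!r}")
        if self.layer == "raw":
            if not np.all(np.isfinite(self.values)):
                raise ValueError("raw layer contains non-finite values")
            if np.any(self.values < 0):
                raise ValueError("negative expression value")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene row indices."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=self.cell_ids,
            layer=self.layer,
        )


@dataclass
class BulkPanel:
    """A genes x samples bulk (or pseudo-bulk) panel with per-sample labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    cell_type_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.cell_type_labels = list(self.cell_type_labels)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("bulk panel shape inconsistent with ids")
        if len(self.cell_type_labels) != len(self.sample_ids):
            raise ValueError("missing label for a sample")
        if any(not str(lab) for lab in self.cell_type_labels):
            raise ValueError("empty cell-type label")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "BulkPanel":
        idx = np.asarray(idx, dtype=int)
        return BulkPanel(
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=self.sample_ids,
            cell_type_labels=self.cell_type_labels,
        )


@dataclass
class GeneSelection:
    """Ordered list of retained genes with their variability scores."""

    kept_gene_ids: list[str]
    dispersion_scores: np.ndarray

    def __post_init__(self) -> None:
        self.dispersion_scores = np.asarray(self.dispersion_scores, dtype=float)
        if len(self.kept_gene_ids) != self.dispersion_scores.size:
            raise ValueError("one score per kept gene required")
        if not np.all(np.isfinite(self.dispersion_scores)):
            raise ValueError("non-finite dispersion score")


@dataclass
class ReferencePanel:
    """The dictionary matrix R' (genes x d' reference samples).

    ``provenance`` records how the anchors were built: ``bulk-selected`` via
    per-cell best-correlation voting, ``sc-averaged`` from labeled cells, or
    ``kmeans`` centroids (unlabeled ablation mode).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    cell_type_labels: list[str] | None
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("reference panel shape inconsistent with ids")
        if self.n_samples < 1:
            raise ValueError("reference panel needs at least one sample")
        if self.provenance not in ("bulk-selected", "sc-averaged", "kmeans"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.cell_type_labels is not None and len(self.cell_type_labels) != self.n_samples:
            raise ValueError("one cell-type label per reference sample required")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


COLUMN_SUM_TOL = 1e-8


@dataclass
class AnchorGraph:
    """The learned anchor graph A (d' anchors x n cells).

    Every column is a point on the probability simplex: nonnegative and
    summing to one (each cell's reconstruction coefficients over anchors).
    """

    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be 2-D")
        if np.any(self.A < -COLUMN_SUM_TOL):
            raise ValueError("anchor graph has negative entries")
        colsums = self.A.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=COLUMN_SUM_TOL):
            raise ValueError("anchor-graph columns must sum to one")

    @property
    def d_prime(self) -> int:
        return self.A.shape[0]

    @property
    def n_cells(self) -> int:
        return self.A.shape[1]


@dataclass
class BipartiteLaplacian:
    """Degrees of the bipartite graph B = [[0, A], [A^T, 0]].

    The normalized Laplacian L = I - D^{-1/2} B D^{-1/2} is kept implicit:
    anchor degrees are row sums of A, cell degrees are column sums (exactly 1
    for a valid anchor graph).
    """

    degree_vector: np.ndarray
    d_prime: int

    @property
    def anchor_degrees(self) -> np.ndarray:
        return self.degree_vector[: self.d_prime]

    @property
    def cell_degrees(self) -> np.ndarray:
        return self.degree_vector[self.d_prime:]


@dataclass
class SpectralEmbedding:
    """Eigenvectors of the k smallest eigenvalues of the normalized Laplacian.

    ``F`` stacks anchor rows first, then cell rows; columns are orthonormal.
    """

    F: np.ndarray
    eigenvalues: np.ndarray
    d_prime: int

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.F.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvalue per embedding column required")

    @property
    def k(self) -> int:
        return self.F.shape[1]

    @property
    def anchor_rows(self) -> np.ndarray:
        return self.F[: self.d_prime, :]

    @property
    def cell_rows(self) -> np.ndarray:
        return self.F[self.d_prime:, :]


@dataclass
class FitState:
    """Hyperparameters and convergence trace of one anchor-graph fit."""

    delta: float
    beta: float
    k: int
    objective_trace: list[float] = field(default_factory=list)
    t: int = 0
    converged: bool = False
    component_count: int = 0


@dataclass
class ClusterResult:
    """Cluster labels in [0, k) for each cell."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")

    @property
    def n_cells(self) -> int:
        return self.labels.size


@dataclass
class AnnotationResult:
    """Per-cluster cell types (with the best correlation backing each call)."""

    cluster_types: list[str]
    best_correlations: np.ndarray
    best_references: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.best_correlations = np.asarray(self.best_correlations, dtype=float)
        if len(self.cluster_types) != self.best_correlations.size:
            raise ValueError("one correlation per cluster required")
        if np.any(np.abs(self.best_correlations) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class MetricReport:
    """External clustering agreement metrics (plus optional silhouette)."""

    ari: float
    nmi: float
    acc: float
    purity: float
    silhouette: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"ari": self.ari, "nmi": self.nmi, "acc": self.acc, "purity": self.purity}
        if self.silhouette is not None:
            out["silhouette"] = self.silhouette
        return out
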