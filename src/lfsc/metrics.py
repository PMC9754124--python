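"""External clustering agreement metrics: ARI, NMI, ACC, purity, silhouette.

ARI, NMI and silhouette delegate to scikit-learn (NMI with arithmetic-mean
normalization). ACC is the accuracy of the best one-to-one cluster-to-class
matching, found by optimal assignment on the (zero-padded) confusion matrix;
purity assigns each cluster its majority class.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .containers import MetricReport

__all__ = ["ari", "nmi", "acc", "purity", "silhouette", "evaluate"]


def _check_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1-D and equally long")
    return pred, truth


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1), dtype=int)
    np.add.at(table, (pi, ti), 1)
    return table


def ari(pred, truth) -> float:
    """Adjusted Rand index (Hubert–Arabie chance correction)."""
    pred, truth = _check_pair(pred, truth)
    if pred.size < 2:
        raise ValueError("need at least two points")
    return float(adjusted_rand_score(truth, pred))


def nmi(pred, truth) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    pred, truth = _check_pair(pred, truth)
    return float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


def acc(pred, truth) -> float:
    """Best one-to-one cluster-class matching accuracy (optimal assignment)."""
    pred, truth = _check_pair(pred, truth)
    table = _contingency(pred, truth)
    size = max(table.shape)
    padded = np.zeros((size, size), dtype=int)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum() / pred.size)


def purity(pred, truth) -> float:
    """Fraction of cells belonging to their cluster's majority class."""
    pred, truth = _check_pair(pred, truth)
    table = _contingency(pred, truth)
    return float(table.max(axis=1).sum() / pred.size)


def silhouette(points: np.ndarray, labels) -> float:
    """Mean silhouette coefficient (Euclidean); singletons score 0.

    Degenerate geometry where every within- and between-distance is 0
    (coincident points) scores 0 by convention.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least two clusters")
    if np.allclose(points, points[0]):
        return 0.0
    return float(silhouette_score(points, labels, metric="euclidean"))


def evaluate(pred, truth, points: np.ndarray | None = None) -> MetricReport:
    """All agreement metrics at once; silhouette only if an embedding is given."""
    sil = None
    if points is not None:
        sil = silhouette(points, pred)
    return MetricReport(
        ari=ari(pred, truth),
        nmi=nmi(pred, truth),
        acc=acc(pred, truth),
        purity=purity(pred, truth),
        silhouette=sil,
    )
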