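"""Synthetic clustered scRNA-seq counts with a matched bulk panel.

The generator emulates the minimal structure the pipeline exploits: k cell
populations that differ by disjoint blocks of marker genes elevated on the
log scale, negative-binomial counts with library-size variation, and
independent dropout zeroing. A matched bulk panel is derived from the truth
(per-cluster mean of log-normalized counts, plus optional noise and decoy
samples), so reference selection, fitting and annotation are all exercisable
without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BulkPanel, ExpressionMatrix
from .preprocessing import lognormalize

__all__ = ["SyntheticDataset", "make_clusters", "make_bulk_from_truth"]


@dataclass
class SyntheticDataset:
    """Counts with generating labels; regeneration from params is bit-identical."""

    counts: ExpressionMatrix
    true_labels: list[str]
    params: dict


def make_clusters(
    n_cells: int,
    n_genes: int,
    k: int,
    separation: float,
    dropout_rate: float,
    seed: int,
    marker_frac: float = 0.1,
    dispersion: float = 0.3,
    lib_log_mean: float = 9.2,
    lib_log_sd: float = 0.3,
) -> SyntheticDataset:
    """Simulate k populations distinguished by disjoint marker blocks.

    Each cluster elevates its own block of ``round(marker_frac * n_genes)``
    genes by ``separation`` on the natural-log scale of relative expression.
    Counts are negative-binomial (variance mu + dispersion * mu^2) around the
    cell's library size times the cluster's expression proportions, then
    zeroed independently with probability ``dropout_rate``. Cluster sizes are
    balanced up to remainder; cell order is shuffled.
    """
    if not (1 <= k <= n_cells):
        raise ValueError("require 1 <= k <= n_cells")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must lie in [0, 1)")
    block = int(round(marker_frac * n_genes))
    if block < 1 or block * k > n_genes:
        raise ValueError("marker blocks do not fit: adjust marker_frac / n_genes / k")

    rng = np.random.default_rng(seed)
    base_log = rng.normal(0.0, 0.5, size=n_genes)
    log_means = np.tile(base_log, (k, 1))
    for c in range(k):
        log_means[c, c * block : (c + 1) * block] += separation

    sizes = np.full(k, n_cells // k)
    sizes[: n_cells % k] += 1
    labels_int = rng.permutation(np.repeat(np.arange(k), sizes))

    props = np.exp(log_means)
    props /= props.sum(axis=1, keepdims=True)
    lib = np.exp(rng.normal(lib_log_mean, lib_log_sd, size=n_cells))
    mu = props[labels_int, :] * lib[:, None]  # cells x genes

    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    if dropout_rate > 0:
        counts[rng.random(counts.shape) < dropout_rate] = 0.0
    # guard degenerate cells (possible only at toy sizes): one count somewhere
    empty = np.flatnonzero(counts.sum(axis=1) == 0)
    for i in empty:
        counts[i, rng.integers(n_genes)] = 1.0

    x = ExpressionMatrix(
        values=counts.T,
        gene_ids=[f"gene_{g}" for g in range(n_genes)],
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
        layer="raw",
    )
    return SyntheticDataset(
        counts=x,
        true_labels=[f"type_{c}" for c in labels_int],
        params=dict(
            n_cells=n_cells,
            n_genes=n_genes,
            k=k,
            separation=separation,
            dropout_rate=dropout_rate,
            seed=seed,
            marker_frac=marker_frac,
            dispersion=dispersion,
            lib_log_mean=lib_log_mean,
            lib_log_sd=lib_log_sd,
        ),
    )


def make_bulk_from_truth(
    d: SyntheticDataset, n_decoys: int = 0, noise_sd: float = 0.0, seed: int = 0
) -> BulkPanel:
    """Bulk panel from the generating truth: one sample per cluster plus decoys.

    Cluster samples are the per-type means of the log-normalized counts
    (optionally with Gaussian noise); decoys are gene-wise Gaussian profiles
    unrelated to any population, labeled ``decoy_i``.
    """
    rng = np.random.default_rng(seed)
    normed = lognormalize(d.counts)
    types = sorted(set(d.true_labels))
    labels_arr = np.asarray(d.true_labels, dtype=object)
    cols, sample_ids, ctypes = [], [], []
    for t in types:
        profile = normed.values[:, labels_arr == t].mean(axis=1)
        if noise_sd > 0:
            profile = profile + rng.normal(0.0, noise_sd, size=profile.size)
        cols.append(np.clip(profile, 0.0, None))
        sample_ids.append(f"bulk_{t}")
        ctypes.append(t)
    grand_mean = float(normed.values.mean())
    grand_sd = float(normed.values.std())
    for j in range(n_decoys):
        decoy = np.clip(
            rng.normal(grand_mean, 2.0 * max(grand_sd, 1e-3), size=normed.n_genes),
            0.0,
            None,
        )
        cols.append(decoy)
        sample_ids.append(f"decoy_{j}")
        ctypes.append(f"decoy_{j}")
    return BulkPanel(
        values=np.column_stack(cols),
        gene_ids=list(normed.gene_ids),
        sample_ids=sample_ids,
        cell_type_labels=ctypes,
    )
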