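"""Quality control, log-normalization and highly-variable-gene selection.

The preprocessing order is: gene-level QC on raw counts, HVG ranking on the
raw counts of the QC-passed genes, log-normalization, then intersection with
the bulk panel's gene set. Downstream stages consume the normalized values of
the selected, shared genes.
"""

from __future__ import annotations

import numpy as np

from .containers import BulkPanel, ExpressionMatrix, GeneSelection

__all__ = [
    "qc_filter_genes",
    "lognormalize",
    "select_hvgs",
    "intersect_genes",
    "log1p_bulk",
]


def qc_filter_genes(
    x: ExpressionMatrix, low_frac: float = 0.05, high_frac: float = 0.95
) -> ExpressionMatrix:
    """Drop genes detected in too few or too many cells.

    A gene is removed when its fraction of non-zero entries is strictly below
    ``low_frac`` or strictly above ``high_frac``; genes sitting exactly on a
    boundary are kept. Idempotent by construction.
    """
    if x.layer != "raw":
        raise ValueError("QC operates on the raw layer")
    if not (0 <= low_frac < high_frac <= 1):
        raise ValueError("require 0 <= low_frac < high_frac <= 1")
    frac = (x.values > 0).mean(axis=1)
    keep = np.flatnonzero((frac >= low_frac) & (frac <= high_frac))
    if keep.size == 0:
        raise ValueError(
            "QC removed every gene; relax thresholds or rerun with --no-qc"
        )
    return x.subset_genes(keep)


def lognormalize(x: ExpressionMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """Library-size normalize and log-transform counts.

    Each entry m_ij becomes ln(m_ij * scale / s_j + 1) where s_j is cell j's
    total count. Natural log; zeros map to zero.
    """
    if x.layer != "raw":
        raise ValueError("lognormalize operates on the raw layer")
    totals = x.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total count: {', '.join(x.cell_ids[i] for i in zero[:5])}"
        )
    normalized = np.log1p(x.values * (scale / totals))
    return ExpressionMatrix(
        values=normalized, gene_ids=x.gene_ids, cell_ids=x.cell_ids, layer="normalized"
    )


def _fit_log_variance_trend(log_mean: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Smooth log10(variance) as a function of log10(mean).

    Uses a lowess smooth when enough genes are available, otherwise a
    degree-2 polynomial. Returns fitted log10-variance at each gene.
    """
    if log_mean.size >= 30:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        order = np.argsort(log_mean, kind="stable")
        fitted = lowess(
            log_var[order], log_mean[order], frac=0.3, it=2, return_sorted=False
        )
        out = np.empty_like(fitted)
        out[order] = fitted
        return out
    deg = min(2, log_mean.size - 1)
    coef = np.polyfit(log_mean, log_var, deg)
    return np.polyval(coef, log_mean)


def select_hvgs(x: ExpressionMatrix, n_hvg: int = 2000) -> GeneSelection:
    """Rank genes by variance-stabilized variability on raw counts.

    Per gene: compute mean and variance of raw counts, smooth log10(variance)
    against log10(mean) across genes, standardize each gene's counts by its
    trend-fitted standard deviation, clip the standardized values at sqrt(n)
    and score the gene by the variance of the clipped values. Constant genes
    are never selected. Returns the top ``min(n_hvg, #non-constant)`` genes,
    highest score first.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    if x.layer != "raw":
        raise ValueError("HVG selection operates on raw counts")
    n = x.n_cells
    mean = x.values.mean(axis=1)
    var = x.values.var(axis=1, ddof=1) if n > 1 else np.zeros(x.n_genes)
    nonconst = np.flatnonzero(var > 0)
    if nonconst.size < 3:
        raise ValueError("fewer than 3 non-constant genes; cannot rank variability")

    log_mean = np.log10(np.maximum(mean[nonconst], 1e-12))
    log_var = np.log10(var[nonconst])
    fitted_log_var = _fit_log_variance_trend(log_mean, log_var)
    fitted_sd = np.sqrt(10.0 ** fitted_log_var)

    clip = np.sqrt(n)
    z = (x.values[nonconst, :] - mean[nonconst, None]) / fitted_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    scores = z.var(axis=1, ddof=1)

    # stable sort on (-score, original index) so ties keep input gene order
    order = np.argsort(-scores, kind="stable")
    top = order[: min(n_hvg, nonconst.size)]
    kept_idx = nonconst[top]
    return GeneSelection(
        kept_gene_ids=[x.gene_ids[i] for i in kept_idx],
        dispersion_scores=scores[top],
    )


def intersect_genes(
    x: ExpressionMatrix, r: BulkPanel, selection: GeneSelection | None = None
) -> tuple[ExpressionMatrix, BulkPanel]:
    """Restrict both modalities to the shared (optionally HVG-selected) genes.

    The output gene order follows the selection order (or the single-cell
    matrix's order when no selection is given) and is identical on both sides.
    """
    wanted = selection.kept_gene_ids if selection is not None else x.gene_ids
    bulk_pos = {g: i for i, g in enumerate(r.gene_ids)}
    sc_pos = {g: i for i, g in enumerate(x.gene_ids)}
    shared = [g for g in wanted if g in bulk_pos and g in sc_pos]
    if not shared:
        raise ValueError("no genes shared between single-cell matrix and bulk panel")
    x_idx = np.array([sc_pos[g] for g in shared])
    r_idx = np.array([bulk_pos[g] for g in shared])
    return x.subset_genes(x_idx), r.subset_genes(r_idx)


def log1p_bulk(r: BulkPanel) -> BulkPanel:
    """Put bulk values on a log scale (ln(v+1)) to match normalized cells."""
    return BulkPanel(
        values=np.log1p(r.values),
        gene_ids=r.gene_ids,
        sample_ids=r.sample_ids,
        cell_type_labels=r.cell_type_labels,
    )
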