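"""Structured anchor-graph learning between reference samples and cells.

The model reconstructs each cell x_i as a convex combination of the d'
reference profiles (columns of R'), learning the anchor graph A (d' x n):

    min_A  ||X - R'A||^2 + delta ||A||^2 + beta Tr(F^T L F)
    s.t.   A >= 0, unit column sums, F^T F = I,

where L is the normalized Laplacian of the bipartite graph
B = [[0, A], [A^T, 0]] and F holds the eigenvectors of L's k smallest
eigenvalues. Driving the trace term to zero forces the bipartite graph to
exactly k connected components (the zero-eigenvalue multiplicity of L equals
the number of components), so the partition is built into the graph itself.

The objective is solved by alternating minimization: with F fixed (and the
degrees frozen at the current iterate, which makes the trace term linear and
separable per cell), each column of A is an exact simplex-constrained
quadratic program; with A fixed, F comes from an SVD of the degree-normalized
anchor graph — never from an (d'+n) x (d'+n) eigenproblem. beta is adapted
between iterations (doubled while the graph has too few components, halved
while too many) until exactly k components emerge.

Everything here costs O(d'^3 n) time and O(d' n) memory per iteration; no
n x n object is ever formed.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from ._simplex_qp import solve_simplex_qp
from .containers import (
    AnchorGraph,
    BipartiteLaplacian,
    ExpressionMatrix,
    FitState,
    ReferencePanel,
    SpectralEmbedding,
)

__all__ = [
    "init_anchor_graph",
    "bipartite_laplacian",
    "embed_spectral",
    "laplacian_penalty",
    "update_anchor_graph",
    "count_components",
    "objective",
    "frozen_objective",
    "fit_lfsc",
]

_DEG_FLOOR = 1e-12


def _qp_terms(x: ExpressionMatrix, rp: ReferencePanel, delta: float) -> tuple[np.ndarray, np.ndarray]:
    R = rp.values
    H = 2.0 * (R.T @ R + delta * np.eye(rp.n_samples))
    G0 = -2.0 * (R.T @ x.values)
    return H, G0


def init_anchor_graph(x: ExpressionMatrix, rp: ReferencePanel, delta: float) -> AnchorGraph:
    """Initial A: per-cell ridge reconstruction on the simplex (beta = 0)."""
    if rp.n_samples == 0:
        raise ValueError("empty reference panel")
    if x.n_genes != rp.n_genes:
        raise ValueError("gene spaces of cells and references are not aligned")
    if delta <= 0:
        raise ValueError("delta must be positive")
    H, G0 = _qp_terms(x, rp, delta)
    return AnchorGraph(A=solve_simplex_qp(H, G0))


def bipartite_laplacian(a: AnchorGraph) -> BipartiteLaplacian:
    """Degrees of B = [[0, A], [A^T, 0]]; anchors first, then cells.

    Cell degrees are exactly the unit column sums; anchor degrees are row
    sums. Degrees below 1e-12 (an anchor no cell uses) are floored so
    D^{-1/2} stays finite.
    """
    anchor_deg = a.A.sum(axis=1)
    cell_deg = a.A.sum(axis=0)
    deg = np.concatenate([anchor_deg, cell_deg])
    return BipartiteLaplacian(degree_vector=np.maximum(deg, _DEG_FLOOR), d_prime=a.d_prime)


def embed_spectral(a: AnchorGraph, k: int) -> SpectralEmbedding:
    """Eigenvectors of the k smallest Laplacian eigenvalues, via SVD of A.

    For the bipartite graph, L = I - D^{-1/2} B D^{-1/2} and each singular
    triplet (sigma, u, v) of the degree-normalized anchor graph
    Abar = D_anchor^{-1/2} A D_cell^{-1/2} yields the eigenpair
    (1 - sigma, (u, v)/sqrt(2)). The k largest singular values therefore give
    the k smallest eigenvalues without ever forming the (d'+n) x (d'+n) L.
    """
    if not (1 <= k <= a.d_prime):
        raise ValueError(f"need at least k reference samples (k={k}, d'={a.d_prime})")
    lap = bipartite_laplacian(a)
    abar = a.A / np.sqrt(lap.anchor_degrees)[:, None] / np.sqrt(lap.cell_degrees)[None, :]
    u, s, vt = np.linalg.svd(abar, full_matrices=False)
    eigenvalues = np.clip(1.0 - s[:k], 0.0, None)
    F = np.vstack([u[:, :k], vt[:k, :].T]) / np.sqrt(2.0)
    return SpectralEmbedding(F=F, eigenvalues=eigenvalues, d_prime=a.d_prime)


def laplacian_penalty(emb: SpectralEmbedding, lap: BipartiteLaplacian) -> np.ndarray:
    """Per-edge smoothness costs v[j, i] = 1/2 ||f_j/sqrt(d_j) - f_i/sqrt(d_i)||^2.

    Degrees are the frozen ones from the current iterate, which makes
    beta Tr(F^T L F) a linear function sum_ji a_ji v_ji of A — separable per
    cell, so the A-update stays a small QP per column.
    """
    fa = emb.anchor_rows / np.sqrt(lap.anchor_degrees)[:, None]
    fc = emb.cell_rows / np.sqrt(lap.cell_degrees)[:, None]
    sq_a = (fa ** 2).sum(axis=1)
    sq_c = (fc ** 2).sum(axis=1)
    v = 0.5 * (sq_a[:, None] + sq_c[None, :] - 2.0 * fa @ fc.T)
    return np.clip(v, 0.0, None)


def update_anchor_graph(
    x: ExpressionMatrix,
    rp: ReferencePanel,
    emb: SpectralEmbedding,
    lap: BipartiteLaplacian,
    delta: float,
    beta: float,
) -> AnchorGraph:
    """One A-update: exact per-cell simplex QP with the linearized trace term."""
    H, G0 = _qp_terms(x, rp, delta)
    v = laplacian_penalty(emb, lap)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite Laplacian penalty")
    return AnchorGraph(A=solve_simplex_qp(H, G0 + beta * v))


def count_components(a: AnchorGraph, zero_tol: float = 1e-8) -> int:
    """Connected components of the bipartite graph on the support of A.

    Entries at or below ``zero_tol`` are treated as absent edges; isolated
    vertices (anchors no cell uses) count as their own components.
    """
    rows, cols = np.nonzero(a.A > zero_tol)
    n_nodes = a.d_prime + a.n_cells
    adj = scipy.sparse.coo_matrix(
        (np.ones(rows.size), (rows, a.d_prime + cols)), shape=(n_nodes, n_nodes)
    )
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


def objective(
    x: ExpressionMatrix,
    rp: ReferencePanel,
    a: AnchorGraph,
    emb: SpectralEmbedding,
    delta: float,
    beta: float,
) -> float:
    """Reconstruction + ridge + beta * (sum of the k smallest eigenvalues)."""
    recon = float(np.linalg.norm(x.values - rp.values @ a.A) ** 2)
    ridge = float(delta * np.linalg.norm(a.A) ** 2)
    trace = float(beta * emb.eigenvalues.sum())
    return recon + ridge + trace


def frozen_objective(
    x: ExpressionMatrix,
    rp: ReferencePanel,
    a: AnchorGraph,
    v: np.ndarray,
    delta: float,
    beta: float,
) -> float:
    """The objective with the trace term linearized at frozen F and degrees.

    This is the exact quantity each A-update minimizes (summed over cells),
    so it is non-increasing across an update; used by the monotonicity
    checks.
    """
    recon = float(np.linalg.norm(x.values - rp.values @ a.A) ** 2)
    ridge = float(delta * np.linalg.norm(a.A) ** 2)
    return recon + ridge + float(beta * (a.A * v).sum())


def fit_lfsc(
    x: ExpressionMatrix,
    rp: ReferencePanel,
    k: int,
    delta: float = 1.0,
    beta0: float = 0.01,
    max_iter: int = 30,
    tol: float = 1e-6,
    seed: int = 0,
    adapt_beta: bool = True,
) -> tuple[AnchorGraph, SpectralEmbedding, FitState]:
    """Alternating optimization of the structured anchor graph.

    Each outer iteration updates F (SVD of the normalized anchor graph) then
    A (exact per-cell simplex QPs). After each iteration beta is doubled if
    the graph has fewer than k components and halved if more; once exactly k
    components coexist with a relative objective change below ``tol`` the fit
    stops. ``seed`` is accepted for interface uniformity; the solve itself is
    deterministic. On non-convergence the last iterate is returned with
    ``converged=False`` and a warning.
    """
    if k > rp.n_samples:
        raise ValueError(f"need at least k reference samples (k={k}, d'={rp.n_samples})")
    if x.n_genes != rp.n_genes:
        raise ValueError("gene spaces of cells and references are not aligned")
    if delta <= 0:
        raise ValueError("delta must be positive")
    # Gram-matrix form of the objective: ||X - R'A||^2 expands to
    # ||X||^2 + <G0, A> + <A, (R'^T R') A> with G0 = -2 R'^T X, so after the
    # one-time O(m d' n) products every iteration costs O(d'^2 n).
    R = rp.values
    RtR = R.T @ R
    H = 2.0 * (RtR + delta * np.eye(rp.n_samples))
    G0 = -2.0 * (R.T @ x.values)
    x_sq = float(np.sum(x.values**2))

    def fast_objective(A: np.ndarray, eig_sum: float, beta_: float) -> float:
        recon = x_sq + float(np.sum(G0 * A)) + float(np.sum(A * (RtR @ A)))
        return recon + delta * float(np.sum(A**2)) + beta_ * eig_sum

    a = AnchorGraph(A=solve_simplex_qp(H, G0))
    beta = float(beta0)
    state = FitState(delta=delta, beta=beta, k=k)
    prev_obj = None
    for t in range(1, max_iter + 1):
        lap = bipartite_laplacian(a)
        emb = embed_spectral(a, k)
        v = laplacian_penalty(emb, lap)
        a = AnchorGraph(A=solve_simplex_qp(H, G0 + beta * v))
        emb_new = embed_spectral(a, k)
        obj = fast_objective(a.A, float(emb_new.eigenvalues.sum()), beta)
        state.objective_trace.append(obj)
        state.t = t
        comp = count_components(a)
        state.component_count = comp
        state.beta = beta
        at_k = comp == k
        if (
            at_k
            and prev_obj is not None
            and abs(obj - prev_obj) <= tol * max(1.0, abs(prev_obj))
        ):
            state.converged = True
            break
        prev_obj = obj
        if adapt_beta:
            if comp < k:
                beta *= 2.0
            elif comp > k:
                beta /= 2.0
    emb = embed_spectral(a, k)
    if not state.converged:
        warnings.warn(
            f"anchor-graph fit stopped after {state.t} iterations with "
            f"{state.component_count} components (target {k})",
            RuntimeWarning,
            stacklevel=2,
        )
    return a, emb, state
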