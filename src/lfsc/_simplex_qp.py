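"""Exact minimization of simplex-constrained quadratics with a shared Hessian.

Every cell's coefficient column solves

    min_a  1/2 a^T H a + g^T a   s.t.  a >= 0, sum(a) = 1,

where H = 2 (R'^T R' + delta I) is the same small positive-definite matrix for
all cells and only the linear term g differs. The solver is a primal
active-set method (Lawson–Hanson style): solve the equality-constrained KKT
system on the current free set, drop the most negative coordinate while
primal-infeasible, re-admit the most dual-infeasible coordinate otherwise.
Because H is positive definite the per-column subproblem is strictly convex
and the method terminates at the exact optimum.

Columns are processed in lock-step, grouped by identical free-set masks so
each distinct KKT matrix is factored once per sweep — no per-column Python
loop. Columns that fail to settle within the sweep budget (not observed in
practice; guards against active-set cycling on degenerate ties) fall back to
a per-column SLSQP polish.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solve_simplex_qp"]

_TOL = 1e-12


def _solve_groups(
    H: np.ndarray,
    G: np.ndarray,
    free: np.ndarray,
    cols: np.ndarray,
    A: np.ndarray,
    lam: np.ndarray,
) -> None:
    """Solve the equality-constrained KKT system for each free-set group."""
    d = H.shape[0]
    weights = 1 << np.arange(d, dtype=np.int64)
    codes = weights @ free[:, cols]
    for code in np.unique(codes):
        grp = cols[codes == code]
        P = np.flatnonzero(free[:, grp[0]])
        p = P.size
        K = np.empty((p + 1, p + 1))
        K[:p, :p] = H[np.ix_(P, P)]
        K[:p, p] = 1.0
        K[p, :p] = 1.0
        K[p, p] = 0.0
        rhs = np.empty((p + 1, grp.size))
        rhs[:p] = -G[np.ix_(P, grp)]
        rhs[p] = 1.0
        sol = np.linalg.solve(K, rhs)
        A[:, grp] = 0.0
        A[np.ix_(P, grp)] = sol[:p]
        lam[grp] = sol[p]


def _slsqp_fallback(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    from scipy.optimize import minimize

    d = H.shape[0]
    res = minimize(
        lambda a: 0.5 * a @ H @ a + g @ a,
        np.full(d, 1.0 / d),
        jac=lambda a: H @ a + g,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * d,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    a = np.clip(res.x, 0.0, None)
    return a / a.sum()


def solve_simplex_qp(H: np.ndarray, G: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Minimize 1/2 a^T H a + g^T a over the probability simplex, per column.

    Parameters
    ----------
    H
        Shared positive-definite Hessian, shape (d, d). d must be <= 62
        (free sets are grouped via 64-bit masks; anchor panels are small).
    G
        Linear terms, one column per problem, shape (d, n).

    Returns
    -------
    A : shape (d, n), each column the exact optimizer of its subproblem.
    """
    H = np.asarray(H, dtype=float)
    G = np.asarray(G, dtype=float)
    d, n = G.shape
    if d == 1:
        return np.ones((1, n))
    if d > 62:
        raise ValueError("solver supports at most 62 anchors")

    free = np.ones((d, n), dtype=bool)
    A = np.zeros((d, n))
    lam = np.zeros(n)
    active = np.arange(n)
    col_idx = np.arange(n)

    for _ in range(4 * d + 12):
        if active.size == 0:
            break
        _solve_groups(H, G, free, active, A, lam)

        sub = np.where(free[:, active], A[:, active], np.inf)
        worst_idx = np.argmin(sub, axis=0)
        worst = sub[worst_idx, np.arange(active.size)]
        has_neg = worst < -tol

        neg_cols = active[has_neg]
        if neg_cols.size:
            drop = worst_idx[has_neg]
            free[drop, neg_cols] = False
            A[drop, neg_cols] = 0.0

        ok_cols = active[~has_neg]
        next_active = [neg_cols]
        if ok_cols.size:
            # clip tiny negatives left by the tolerance
            blk = A[:, ok_cols]
            np.clip(blk, 0.0, None, out=blk)
            A[:, ok_cols] = blk
            grad = H @ A[:, ok_cols] + G[:, ok_cols] + lam[ok_cols][None, :]
            mu = np.where(free[:, ok_cols], np.inf, grad)
            jmin = np.argmin(mu, axis=0)
            mu_min = mu[jmin, np.arange(ok_cols.size)]
            viol = mu_min < -max(tol, 1e-9)
            add_cols = ok_cols[viol]
            free[jmin[viol], add_cols] = True
            next_active.append(add_cols)
        active = np.concatenate(next_active) if next_active else col_idx[:0]

    for j in active:  # pragma: no cover - cycling guard, not hit in practice
        A[:, j] = _slsqp_fallback(H, G[:, j])

    # renormalize away factorization round-off; columns are already feasible
    A = np.clip(A, 0.0, None)
    A /= A.sum(axis=0, keepdims=True)
    return A
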