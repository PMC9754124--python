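import numpy as np
import pytest
from scipy.linalg import subspace_angles

from lfsc import (
    ReferencePanel,
    bipartite_laplacian,
    count_components,
    embed_spectral,
    fit_lfsc,
    frozen_objective,
    init_anchor_graph,
    laplacian_penalty,
    objective,
    update_anchor_graph,
)
from lfsc._simplex_qp import solve_simplex_qp
from lfsc.containers import AnchorGraph


def make_panel(values):
    values = np.asarray(values, dtype=float)
    return ReferencePanel(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        cell_type_labels=[f"t{j}" for j in range(values.shape[1])],
        provenance="sc-averaged",
    )


def dense_bipartite_laplacian(A):
    """Explicit (d'+n) x (d'+n) normalized Laplacian — brute-force oracle."""
    d, n = A.shape
    B = np.zeros((d + n, d + n))
    B[:d, d:] = A
    B[d:, :d] = A.T
    deg = np.maximum(B.sum(axis=1), 1e-12)
    return np.eye(d + n) - B / np.sqrt(np.outer(deg, deg))


def random_anchor_graph(rng, d, n, n_blocks=1, sparsify=0.0):
    """Random column-stochastic A, optionally block-structured then re-thresholded."""
    A = np.zeros((d, n))
    blocks_a = np.array_split(np.arange(d), n_blocks)
    blocks_c = np.array_split(np.arange(n), n_blocks)
    for ba, bc in zip(blocks_a, blocks_c):
        for i in bc:
            A[ba, i] = rng.dirichlet(np.ones(len(ba)))
    if sparsify:
        A[A < sparsify] = 0.0
        A[A.argmax(axis=0), np.arange(n)] += 1e-9  # keep columns non-empty
        A /= A.sum(axis=0)
    return AnchorGraph(A=A)


class TestInitAnchorGraph:
    def test_single_anchor_forces_unit_column(self, make_toy):
        x = make_toy(np.random.default_rng(0).normal(size=(4, 6)), layer="normalized")
        rp = make_panel(np.random.default_rng(1).normal(size=(4, 1)))
        a = init_anchor_graph(x, rp, delta=1.0)
        np.testing.assert_allclose(a.A, np.ones((1, 6)))

    def test_identical_anchors_split_evenly(self, make_toy):
        rng = np.random.default_rng(2)
        anchor = rng.normal(size=4)
        rp = make_panel(np.column_stack([anchor, anchor]))
        x = make_toy(rng.normal(size=(4, 5)), layer="normalized")
        a = init_anchor_graph(x, rp, delta=0.5)
        np.testing.assert_allclose(a.A, 0.5, atol=1e-9)

    def test_exact_anchor_match_concentrates_as_delta_vanishes(self, make_toy):
        r1 = np.array([1.0, 0.0, 0.0])
        r2 = np.array([0.0, 1.0, 0.0])
        rp = make_panel(np.column_stack([r1, r2]))
        x = make_toy(r1[:, None], layer="normalized")
        a = init_anchor_graph(x, rp, delta=1e-10)
        np.testing.assert_allclose(a.A[:, 0], [1.0, 0.0], atol=1e-6)


class TestBipartiteLaplacian:
    def test_two_node_graph_by_hand(self):
        a = AnchorGraph(A=np.array([[1.0]]))
        lap = bipartite_laplacian(a)
        np.testing.assert_allclose(lap.degree_vector, [1.0, 1.0])
        L = dense_bipartite_laplacian(a.A)
        np.testing.assert_allclose(L, [[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(np.linalg.eigvalsh(L), [0.0, 2.0], atol=1e-12)

    def test_block_diagonal_zero_eigenvalue_multiplicity(self):
        A = np.zeros((4, 6))
        A[:2, :3] = 1.0 / 2
        A[2:, 3:] = 1.0 / 2
        w = np.linalg.eigvalsh(dense_bipartite_laplacian(A))
        assert np.sum(w < 1e-10) == 2

    def test_eigenvalues_lie_between_zero_and_two(self):
        rng = np.random.default_rng(3)
        a = random_anchor_graph(rng, 4, 12)
        w = np.linalg.eigvalsh(dense_bipartite_laplacian(a.A))
        assert w.min() > -1e-10 and w.max() < 2 + 1e-10
        assert abs(w.min()) < 1e-10  # smallest eigenvalue is 0

    def test_cell_degrees_are_exactly_one(self):
        rng = np.random.default_rng(4)
        a = random_anchor_graph(rng, 5, 20)
        lap = bipartite_laplacian(a)
        np.testing.assert_allclose(lap.cell_degrees, 1.0, atol=1e-12)
        np.testing.assert_allclose(lap.anchor_degrees, a.A.sum(axis=1))


class TestEmbedSpectral:
    def test_connected_graph_kernel_vector(self):
        rng = np.random.default_rng(5)
        a = random_anchor_graph(rng, 3, 10)
        emb = embed_spectral(a, k=1)
        assert emb.eigenvalues[0] == pytest.approx(0.0, abs=1e-10)
        deg = bipartite_laplacian(a).degree_vector
        kernel = np.sqrt(deg) / np.linalg.norm(np.sqrt(deg))
        cos = abs(float(kernel @ emb.F[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("d,n,k", [(5, 20, 3), (4, 15, 2), (8, 30, 5)])
    def test_matches_dense_eigendecomposition(self, d, n, k):
        rng = np.random.default_rng(d * 100 + n)
        a = random_anchor_graph(rng, d, n)
        emb = embed_spectral(a, k=k)
        L = dense_bipartite_laplacian(a.A)
        w, V = np.linalg.eigh(L)
        np.testing.assert_allclose(emb.eigenvalues, w[:k], atol=1e-8)
        assert w[k] - w[k - 1] > 1e-8  # sane eigengap for a subspace comparison
        angle = subspace_angles(emb.F, V[:, :k]).max()
        assert angle < 1e-6
        np.testing.assert_allclose(emb.F.T @ emb.F, np.eye(k), atol=1e-8)

    def test_disjoint_blocks_have_zero_trace(self):
        rng = np.random.default_rng(6)
        a = random_anchor_graph(rng, 6, 18, n_blocks=3)
        emb = embed_spectral(a, k=3)
        assert emb.eigenvalues.sum() == pytest.approx(0.0, abs=1e-10)

    def test_k_exceeding_anchor_count_is_an_error(self):
        a = AnchorGraph(A=np.ones((2, 4)) / 2)
        with pytest.raises(ValueError, match="reference samples"):
            embed_spectral(a, k=3)


class TestColumnQP:
    def brute_force_grid(self, obj, step=0.01):
        best = np.inf
        m = int(round(1.0 / step))
        for i in range(m + 1):
            for j in range(m + 1 - i):
                a = np.array([i, j, m - i - j]) / m
                best = min(best, obj(a))
        return best

    def test_matches_exhaustive_grid_search(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            R = rng.normal(size=(4, 3))
            xcol = rng.normal(size=4)
            delta = rng.uniform(0.05, 2.0)
            beta = rng.uniform(0.0, 2.0)
            v = rng.uniform(0.0, 1.0, size=3)
            H = 2 * (R.T @ R + delta * np.eye(3))
            g = -2 * R.T @ xcol + beta * v

            def obj(a):
                return (
                    np.linalg.norm(xcol - R @ a) ** 2 + delta * a @ a + beta * v @ a
                )

            a_hat = solve_simplex_qp(H, g[:, None])[:, 0]
            assert a_hat.min() >= -1e-12
            assert a_hat.sum() == pytest.approx(1.0, abs=1e-10)
            assert obj(a_hat) <= self.brute_force_grid(obj) + 1e-3

    def test_beta_zero_update_reduces_to_init(self, fitted_inputs):
        normed, rp, _ = fitted_inputs
        a0 = init_anchor_graph(normed, rp, delta=1.0)
        lap = bipartite_laplacian(a0)
        emb = embed_spectral(a0, k=3)
        a1 = update_anchor_graph(normed, rp, emb, lap, delta=1.0, beta=0.0)
        np.testing.assert_allclose(a1.A, a0.A, atol=1e-8)

    def test_huge_beta_concentrates_on_cheapest_anchor(self):
        rng = np.random.default_rng(8)
        R = rng.normal(size=(5, 3))
        H = 2 * (R.T @ R + 1.0 * np.eye(3))
        v = np.array([0.0, 1.0, 1.0])
        g = -2 * R.T @ rng.normal(size=5) + 1e8 * v
        a = solve_simplex_qp(H, g[:, None])[:, 0]
        np.testing.assert_allclose(a, [1.0, 0.0, 0.0], atol=1e-6)


class TestCountComponents:
    def test_block_and_dense_cases(self):
        rng = np.random.default_rng(9)
        for nb in (1, 2, 3):
            a = random_anchor_graph(rng, 6, 12, n_blocks=nb)
            assert count_components(a) == nb
        dense = AnchorGraph(A=np.full((4, 9), 0.25))
        assert count_components(dense) == 1

    def test_matches_zero_eigenvalue_multiplicity(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            d = int(rng.integers(3, 8))
            n = int(rng.integers(6, 25))
            nb = int(rng.integers(1, min(d, 4) + 1))
            a = random_anchor_graph(rng, d, n, n_blocks=nb, sparsify=0.15)
            support = (a.A > 1e-8).astype(float)
            iso = int(np.sum(support.sum(axis=1) == 0))
            keep = support.sum(axis=1) > 0
            w = np.linalg.eigvalsh(dense_bipartite_laplacian(a.A[keep]))
            assert count_components(a) == int(np.sum(w < 1e-8)) + iso


class TestObjective:
    def test_exact_reconstruction_is_zero(self, make_toy):
        rng = np.random.default_rng(11)
        R = rng.normal(size=(4, 3))
        A = rng.dirichlet(np.ones(3), size=6).T
        x = make_toy(R @ A, layer="normalized")
        rp = make_panel(R)
        ag = AnchorGraph(A=A)
        emb = embed_spectral(ag, k=1)
        assert objective(x, rp, ag, emb, delta=0.0, beta=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_ridge_term_of_even_column(self, make_toy):
        # one cell with coefficients (0.5, 0.5): delta * ||a||^2 = 2 * 0.5 = 1
        R = np.array([[1.0, 0.0], [0.0, 1.0]])
        A = np.array([[0.5], [0.5]])
        x = make_toy(R @ A, layer="normalized")
        ag = AnchorGraph(A=A)
        emb = embed_spectral(ag, k=1)
        assert objective(x, make_panel(R), ag, emb, delta=2.0, beta=0.0) == pytest.approx(1.0)

    def test_matches_naive_dense_recomputation(self, make_toy):
        rng = np.random.default_rng(12)
        R = rng.normal(size=(5, 4))
        A = rng.dirichlet(np.ones(4), size=10).T
        X = rng.normal(size=(5, 10))
        delta, beta, k = 0.7, 1.3, 2
        ag = AnchorGraph(A=A)
        emb = embed_spectral(ag, k=k)
        got = objective(make_toy(X, layer="normalized"), make_panel(R), ag, emb, delta, beta)
        w = np.linalg.eigvalsh(dense_bipartite_laplacian(A))
        naive = (
            np.sum((X - R @ A) ** 2) + delta * np.sum(A**2) + beta * np.sum(w[:k])
        )
        assert got == pytest.approx(naive, abs=1e-10)


class TestFit:
    def test_reaches_k_components_on_separated_data(self, fitted_inputs):
        normed, rp, truth = fitted_inputs
        a, emb, state = fit_lfsc(normed, rp, k=3, seed=0)
        assert state.component_count == 3
        assert state.converged
        assert count_components(a) == 3

    def test_same_seed_same_trace(self, fitted_inputs):
        normed, rp, _ = fitted_inputs
        _, _, s1 = fit_lfsc(normed, rp, k=3, seed=1)
        _, _, s2 = fit_lfsc(normed, rp, k=3, seed=1)
        assert s1.objective_trace == s2.objective_trace

    def test_a_updates_never_increase_frozen_objective(self, fitted_inputs):
        normed, rp, _ = fitted_inputs
        delta, beta = 1.0, 0.5
        a = init_anchor_graph(normed, rp, delta)
        for _ in range(10):
            lap = bipartite_laplacian(a)
            emb = embed_spectral(a, k=3)
            v = laplacian_penalty(emb, lap)
            before = frozen_objective(normed, rp, a, v, delta, beta)
            a = update_anchor_graph(normed, rp, emb, lap, delta, beta)
            after = frozen_objective(normed, rp, a, v, delta, beta)
            assert after <= before + 1e-9

    def test_k_larger_than_panel_is_an_error(self, fitted_inputs):
        normed, rp, _ = fitted_inputs
        with pytest.raises(ValueError, match="reference samples"):
            fit_lfsc(normed, rp, k=rp.n_samples + 1)

    def test_columns_remain_simplex_feasible(self, fitted_inputs):
        normed, rp, _ = fitted_inputs
        a, _, _ = fit_lfsc(normed, rp, k=3, seed=0)
        assert a.A.min() >= -1e-8
        np.testing.assert_allclose(a.A.sum(axis=0), 1.0, atol=1e-8)
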