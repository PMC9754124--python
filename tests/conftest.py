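import numpy as np
import pytest

from lfsc import (
    ExpressionMatrix,
    build_sc_references,
    lognormalize,
    make_bulk_from_truth,
    make_clusters,
)


@pytest.fixture(scope="session")
def well_separated():
    """Small, strongly separated 3-cluster dataset with matched bulk."""
    ds = make_clusters(
        n_cells=120, n_genes=200, k=3, separation=5.0, dropout_rate=0.3, seed=42
    )
    bulk = make_bulk_from_truth(ds, n_decoys=2, noise_sd=0.05, seed=42)
    return ds, bulk


@pytest.fixture(scope="session")
def fitted_inputs():
    """Normalized cells plus per-type sc-averaged references, ready to fit."""
    ds = make_clusters(
        n_cells=90, n_genes=150, k=3, separation=4.0, dropout_rate=0.2, seed=7
    )
    normed = lognormalize(ds.counts)
    rp = build_sc_references(normed, ds.true_labels)
    return normed, rp, ds.true_labels


def toy_matrix(values, layer="raw"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        cell_ids=[f"c{j}" for j in range(values.shape[1])],
        layer=layer,
    )


@pytest.fixture
def make_toy():
    return toy_matrix
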