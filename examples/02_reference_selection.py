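"""How the bulk reference panel is pruned before graph learning.

Each cell votes for the bulk sample it correlates with best (Pearson, over
the shared highly variable genes); only samples winning at least one vote
become anchors. Decoy samples unrelated to any cell collect no votes.
"""

import numpy as np

from lfsc import (
    intersect_genes,
    lognormalize,
    make_bulk_from_truth,
    make_clusters,
    pearson_matrix,
    select_bulk_references,
)

ds = make_clusters(n_cells=90, n_genes=150, k=3, separation=4.0, dropout_rate=0.2, seed=3)
bulk = make_bulk_from_truth(ds, n_decoys=3, noise_sd=0.05, seed=3)

normed, bulk_aligned = intersect_genes(lognormalize(ds.counts), bulk, None)
corr = pearson_matrix(normed.values, bulk_aligned.values)  # cells x samples
votes = np.bincount(np.argmax(corr, axis=1), minlength=bulk_aligned.n_samples)

print("sample        votes  mean corr")
for j, sample in enumerate(bulk_aligned.sample_ids):
    print(f"{sample:<13s} {votes[j]:>5d}  {corr[:, j].mean():+.3f}")

panel = select_bulk_references(normed, bulk_aligned)
print(f"\nretained as anchors: {panel.sample_ids}")
# Every cell's best match is its own population's bulk profile, so the three
# population samples each collect ~30 votes and all decoys are dropped.
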