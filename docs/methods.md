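# Methods

## Model and assumptions

`lfsc` treats clustering as structured dictionary learning. Each cell's
normalized profile x_i is reconstructed as a convex combination of d′
reference profiles (the columns of R′), giving the anchor graph A (d′ × n):
nonnegative, each column on the probability simplex. The bipartite graph
B = [[0, A], [Aᵀ, 0]] connects anchors to cells; its normalized Laplacian
L = I − D^{−1/2}BD^{−1/2} has a zero eigenvalue of multiplicity equal to the
number of connected components. The fit minimizes

    ‖X − R′A‖² + δ‖A‖² + β·Tr(FᵀLF),   A ≥ 0, 1ᵀA = 1 (per column), FᵀF = I,

with F spanning the k smallest eigenvectors of L. When the trace term
reaches zero the graph has exactly k components, i.e. a k-way partition of
cells (and anchors) is encoded in the graph itself.

Assumptions worth stating: (i) each population of interest is represented by
at least one anchor whose profile correlates with its cells more than any
other anchor does; (ii) populations are separable in the shared
highly-variable-gene space after log-normalization; (iii) k ≤ d′, since the
embedding comes from an SVD of the d′ × n graph.

### Constraint orientation

The simplex constraint binds each **column** of A (one cell's coefficients
over anchors). Reconstruction X ≈ R′A is column-wise, so this is the
orientation under which the model is a per-cell mixture over references; it
also makes every cell degree exactly 1, which simplifies D and keeps the
SVD route exact.

## Optimization

Alternating minimization:

* **F-step.** For fixed A, the k smallest eigenpairs of L are obtained from
  the SVD of Ā = D_a^{−1/2} A D_c^{−1/2}: a singular triplet (σ, u, v) maps
  to the eigenpair (1 − σ, (u, v)/√2). Cost O(d′²n); the explicit
  (d′+n)×(d′+n) Laplacian is never formed (it only appears in test oracles).
* **A-step.** For fixed F, Tr(FᵀLF) is linearized by freezing the degrees at
  the current iterate: with v_ji = ½‖f_j^a/√d_j − f_i^c/√d_i‖², the trace
  term becomes Σ a_ji v_ji and the problem separates into n independent
  strictly convex QPs over the simplex, all sharing the Hessian
  2(R′ᵀR′ + δI). Each QP is solved **exactly** by a primal active-set
  method; columns are processed in lock-step grouped by identical free sets,
  so each distinct KKT factorization is done once per sweep. Freezing the
  degrees is what makes the subproblem separable; it is also why the
  monotonicity guarantee below is stated for frozen degrees.
* **β adaptation.** The rank constraint is enforced by bisection pressure:
  after each iteration β doubles while the graph has fewer than k components
  and halves while it has more. The fit stops when exactly k components
  coexist with a relative objective change below `tol`, or at `max_iter`
  (returning the last iterate with `converged=False` and a warning).

Per A-update (frozen β, F, degrees) the objective cannot increase, since
every column QP is solved to optimality; this is asserted in the test suite
to 1e-9. The recorded `objective_trace` evaluates the trace term as the sum
of the k smallest eigenvalues of the *updated* graph and is not monotone
across iterations, because β changes between them.

The objective inside the fit loop is evaluated in Gram form
(‖X − R′A‖² = ‖X‖² − 2⟨R′ᵀX, A⟩ + ⟨A, R′ᵀR′A⟩), so after one O(md′n) setup
every iteration costs O(d′²n) time and O(d′n) memory.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| δ (`delta`) | 1.0 | ridge weight on A; spreads a cell's coefficients over correlated anchors. Clustering is insensitive over δ ∈ [0.1, 100] (asserted in tests). |
| β₀ (`beta0`) | 0.01 | initial connectivity pressure; adapted geometrically, so only its order of magnitude matters. |
| k | estimated | number of clusters = target component count; `estimate_k` when not given. |
| `max_iter` / `tol` | 30 / 1e-6 | outer iterations / relative objective change for convergence. |
| QC bounds | 5% / 95% | genes detected in strictly fewer than 5% (or more than 95%) of cells are dropped; boundary values are kept (strict inequalities). |
| `n_hvg` | 2000 | highly variable genes retained (all non-constant genes if fewer). |
| scale | 10⁴ | library-size target in ln(count·scale/total + 1); natural log. |
| annotation threshold | 0.6 | a cluster takes a reference's type only when Pearson r strictly exceeds this; otherwise "Unknown type". |
| `downsample_ratio` | 1.0 | fraction of labeled cells averaged per reference; ⌈ratio·n_type⌉ with ceiling so every type keeps ≥ 1 cell. |

## Preprocessing choices

Order: gene QC on raw counts → HVG ranking on raw counts of QC-passed genes
→ log-normalization → intersection with the reference gene set. HVG scoring
is variance-stabilizing: per-gene mean/variance, a lowess smooth of
log10(var) on log10(mean) (degree-2 polynomial below 30 genes), counts
standardized by the trend-fitted SD, clipped at √n, genes ranked by the
variance of the clipped values. Bulk panels are put on a log scale with
ln(v+1) before any correlation or reconstruction (`log_transform_bulk=False`
skips this for panels already on a log scale, e.g. the synthetic ones).

Pearson correlation against a zero-variance vector is defined as 0; argmax
ties break to the lowest index. Anchor degrees below 1e-12 are floored
before D^{−1/2}.

## Cluster-number estimation

`estimate_k` operationalizes cluster-tree stability: seeded K-means on the
top 20 PCs for each k in the grid, consecutive levels linked by shared
cells, per-level instability = fraction of cells whose cluster splits into
≥ 2 children each holding ≥ 20% of it. The estimate is the smallest grid k
from which every higher level stays within a 5% instability budget — the
resolution beyond which further splits are noise. (A rule that instead
required all *lower* levels to be stable can never fire: genuine cluster
discoveries below the true k are themselves large splits.) This is a
diagnostic heuristic; on data with heavy continuous noise balanced K-means
splits can keep registering as instability and push the estimate high, so
`--k` always overrides.

## Synthetic data

`make_clusters` emulates the structure the method exploits: k populations
differing by disjoint blocks of marker genes (10% of genes per population)
elevated by `separation` on the natural-log scale of relative expression;
negative-binomial counts (dispersion 0.3) around log-normal library sizes
(μ = 9.2, σ = 0.3 on the log scale, ≈ 10⁴ counts/cell); independent dropout
zeroing. `make_bulk_from_truth` derives the matched panel from per-type
means of log-normalized counts plus optional Gaussian noise and decoy
samples. It does **not** model batch effects, trajectories/doublets,
gene–gene correlation beyond the block structure, or ambient RNA — passing
tests demonstrate correctness of the algorithmic machinery under the stated
generative model, not performance on any real tissue.

Study conditions used by the checks: perfect recovery on 300 cells × 500
genes at separation 5 with 30% dropout and half-of-cluster references;
hyperparameter stability and the downsampling sweep on separation-2 data
(200–300 cells); the runtime-linearity comparison at n = 2000 vs n = 8000
cells with fixed d′ = k = 3 and a fixed iteration count.

## Numerical notes and limitations

* The active-set QP solver caps sweeps at 4d′ + 12 and falls back to SLSQP
  for any unsettled column (a guard against active-set cycling on degenerate
  ties; not observed in practice). Columns are renormalized after the solve
  to remove factorization round-off; feasibility holds to 1e-8 everywhere.
* Free sets are grouped via 64-bit masks, so the solver supports at most 62
  anchors — ample for cell-type panels.
* Eigenvector sign/rotation within degenerate eigenspaces is arbitrary;
  downstream K-means is invariant to it, and tests compare subspaces.
* With d′ > k and large β, component counts can oscillate around k (a hard
  assignment of cells to anchors can split anchors into more than k
  groups); the halving schedule damps this, but non-convergence is reported
  honestly via the `converged` flag rather than hidden.
* `estimate_k` is the weakest link on noisy data (see above); supplying k
  from domain knowledge is recommended whenever available.
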