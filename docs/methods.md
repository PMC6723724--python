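# Methods

This note documents the models and procedures implemented in `mofuzz`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions adopted where
the design was genuinely open.

## Filtering

Counts are first booleanized (entry 1 iff count > 0); all three filters
act on this detection pattern only, so they are invariant to count
rescaling. Thresholds are strict inequalities: cells are kept when they
detect **more than** `min_cell_detected` genes (default 2000), genes when
detected in **more than** 3 and **fewer than** 500 cells. The upper gene
bound removes ubiquitously detected genes that carry little clustering
signal in plate-scale data. Finally the `k` most variable genes are
retained (default 3000), with variance computed on the raw post-filter
counts using the unbiased (n−1) denominator; a `variance_on_log1p` option
ranks on log1p counts instead. Ties at the k-th rank break by input gene
order, and the output preserves input gene order, so the step is
deterministic. The defaults suit experiments with a few hundred cells
and ~20k genes; smaller (e.g. simulated) matrices need proportionally
smaller thresholds.

## Depth normalization

The count–depth relationship of gene g is the slope of a quantile
regression (τ = 0.5 by default) of log non-zero counts on log sequencing
depth (column sums). Counts proportional to depth give slope 1; properly
normalized data give slope 0. Genes expressed in fewer than 10 cells are
excluded from slope estimation.

Normalization proceeds by escalation on the number of slope groups K:

1. Genes with estimable slopes are split into K equal-size slope bins.
2. Each bin's pooled quantile regression (log non-zero counts, centered
   per gene by their median so between-gene level differences cannot
   leak into the slope; points subsampled to at most 50,000) yields a
   group slope b; every count of that bin in cell c is divided by
   `(depth_c / median depth)^b`. Zeros are preserved exactly. Sparse
   genes without slopes inherit the dominant bin of their
   median-expression group.
3. Genes are (once, from the raw matrix) ranked into 10 equal-size groups
   by non-zero median expression; the kernel-density mode (Gaussian KDE,
   Silverman bandwidth, 512-point grid) of each group's
   post-normalization slopes is computed. If every |mode| ≤ 0.1 the
   attempt is accepted; otherwise K+1 is tried from the raw counts, up to
   `k_max` (default 10), after which the best attempt is returned with
   `converged=False` (a warning, not an error).

This is a deliberately simplified re-implementation of the SCnorm idea
that keeps exactly the testable contract — slopes, ten median groups,
modes within 0.1 of zero, K escalation — and replaces the original's
iterative spline/quantile machinery with group-wise median regression.
The K it selects is therefore not comparable to the original tool's K on
real data. A useful exact identity keeps the diagnostics cheap: the
quantile-regression slope is equivariant under subtracting a linear
function of the regressor, so a gene's post-normalization slope (against
the **original** depths — the count–depth relationship is always assessed
against raw depth) equals its raw slope minus the applied group slope.
The test suite verifies this identity against a full refit. Known
limitation: lowly expressed genes can be over-normalized toward negative
slopes; no remedy is applied. Re-normalizing an already normalized
matrix is near-idempotent but its depth spread is small, which makes the
refitted slopes noisy; the matrix itself changes little.

A `skip_normalization` ablation replaces the procedure with plain depth
scaling (counts / depth × median depth).

## Fuzzy c-means

The objective `J = Σ_j Σ_q u_jq^m ‖x_q − cen_j‖²` is minimized by
alternating the membership-weighted center update and the standard
membership update
`u_jq = [Σ_s (‖x_q−cen_j‖/‖x_q−cen_s‖)^{2/(m−1)}]^{-1}`
(the only form satisfying column-stochasticity) with Euclidean
distances. Iteration stops when the largest membership change is ≤ ε
(default 1e−6) or after `max_iter` (300). Memberships are initialized
uniformly at random and column-normalized from a seeded generator;
`n_init` restarts (default 5) keep the run with the smallest final J.
A point coinciding with one or more centers takes membership split
equally among the coincident centers. J is non-increasing across
iterations by construction, and the suite asserts it on every run.

The fuzzifier must satisfy m > 1 (the update is undefined at m = 1) and
defaults to the conventional m = 2 at the algorithm level. **For cell
clustering the pipeline defaults to m = 1.2.** The reason is
dimensionality: with hundreds of log-expression features, squared
distances concentrate and m = 2 drives the iteration into its known
degenerate stationary point — every center at the grand mean, every
membership exactly 1/cl, PC = 1/cl and MPC = 0 for all cl — which makes
validity-index-based model selection impossible in principle. A
fuzzifier slightly above 1 keeps memberships informative while remaining
genuinely fuzzy; empirically the degenerate point disappears and
cluster-number selection becomes reliable. Hard labels are the
per-column argmax with ties to the lowest cluster index.

Features for clustering are log2(normalized + 1) with cells as points;
optional per-gene standardization is off by default (it equalizes the
influence of noise genes with that of markers).

## Validity indices

For memberships U (cl × n, columns summing to 1):

* `PE = −(1/n) Σ u ln u` with 0·ln 0 ≡ 0; range [0, ln cl]; lower better.
* `PC = (1/n) Σ u²`; range [1/cl, 1]; higher better.
* `MPC = 1 − cl/(cl−1)·(1 − PC)`; affine in PC with MPC(uniform) = 0,
  MPC(hard) = 1.
* Fuzzy silhouette: per point the crisp silhouette
  `S = (β − δ)/max(β, δ)` (δ mean distance to own crisp cluster's other
  members, β smallest mean distance to another cluster's members;
  singletons score 0), averaged with weights `u₁ − u₂`, the gap between
  the point's two largest memberships (weight exponent 1). With hard
  memberships it reduces exactly to the classical mean silhouette, which
  the suite cross-checks against an independent implementation.

## TOPSIS selection

The sweep's (udc−1) × 4 validity matrix (criteria ordered FSI, PE, PC,
MPC; impacts ↑↓↑↑) is normalized, weighted, and ranked by relative
closeness `RC = d⁻/(d⁻ + d⁺)` (Minkowski-p separations from the
per-criterion ideal and anti-ideal profiles; both-zero separations score
0.5; tied RCs share the better rank). Three normalizations are
implemented — vector (root-sum-square), max, and min-max with cost
columns reversed — and p ∈ {1, 2}.

The default configuration for cluster-number selection is **pinned by a
brute-force calibration** (`mofuzz.topsis.calibrate_configuration`)
against a published worked example of the nine-case validity table: over
{vector, max, minmax} × {PE as an equally weighted cost criterion, PE
zero-weighted} × p ∈ {1, 2}, the combination minimizing the worst-case
deviation from the reference score column is **vector normalization,
p = 2, weights (1/3, 0, 1/3, 1/3)**. PE ends up zero-weighted because
the reference ranking scores its worst alternative exactly 0, which is
only possible when that alternative is the anti-ideal on every criterion
that carries weight — and in the reference table the worst alternative
has a mid-range PE. The calibration achieves a worst-case deviation of
0.030 and reproduces the reference ranking exactly; the equal 4-way
weighting remains selectable. `udc` defaults to 10 and is never
auto-extended.

## Differential expression

Each cluster is contrasted against all remaining cells on
log2(normalized + 1). Per gene the two-group pooled variance s² (d =
n − 2 df) is shrunk toward a prior: `s̃² = (d₀s₀² + d s²)/(d₀ + d)`,
with (d₀, s₀²) estimated by closed-form method of moments on log s² —
the marginal mean and variance of log s² under the scaled-F sampling
model involve digamma/trigamma functions of d/2 and d₀/2, and the
trigamma equation is inverted by Newton iteration. When the observed
spread of log s² does not exceed its pure sampling component, d₀ = ∞ and
the reference distribution is normal; otherwise the moderated
t = Δ/(s̃√(1/n₁+1/n₂)) is referred to t with d₀ + d df, two-sided.
P-values are Bonferroni-adjusted (×G, capped at 1); DEGs have adjusted
p < 0.05. Up-regulated markers are DEGs whose linear-scale fold change
`(mean_in + 1)/(mean_rest + 1)` on normalized values exceeds 2, ranked
by adjusted p, then |log2 FC|, then gene order. For two clusters the two
contrasts are sign mirrors and share one DEG set. The expression scale
fed to the test (log2 of normalized + 1) is this package's documented
choice.

## Network metrics

Per cluster (≥ 3 cells), adjacency between cells is |Pearson r| of their
expression profiles (soft-threshold power 1, standard weighted
coexpression conventions): connectivity k_i is the row sum, scaled
connectivity k_i/max k, MAR_i = Σa²/Σa, density the mean off-diagonal
adjacency, and average correlation the mean signed r. Pairs with
undefined correlation (constant profiles) are skipped with a warning.
These are descriptive diagnostics; no published values are targeted.

## Synthetic data

The generator plants K cell clusters: per-cell depth factors are
log-uniform on `depth_range` (default 1–10, one order of magnitude);
baseline gene means are log-normal (meanlog 1.5, sdlog 1 — a realistic
spread of lowly to highly expressed genes with median mean ≈ 4.5
counts); the first K·`n_markers_per_cluster` genes are disjoint marker
blocks whose mean is multiplied by `marker_fold` (default 4) in their
cluster; counts are negative-binomial with size 10 (variance
μ + μ²/10, moderate overdispersion); and entries are then zeroed
independently with probability 0.1. The flat zeroing rate is kept small
deliberately: unlike biological dropout, it is magnitude-independent and
at higher rates would put implausible variance on highly expressed
genes. Defaults are desk-scale (200 cells × 2000 genes) so full test
runs finish in minutes.

What it does **not** emulate: expression-dependent dropout, gene–gene
correlation beyond cluster structure, batch effects, gene length/GC
bias, or realistic library-size distributions. Passing recovery tests
therefore demonstrate correctness of the machinery under the stated
generative model, not performance on real tissue.

## Test problem sizes

The end-to-end recovery checks run 20 seeded replicates per K ∈ {2,3,4}
at 60 cells per cluster, 500 genes, 40 markers per cluster at fold 8
("strong separation"), sweep cl = 2..6 with 3 restarts — sizes chosen so
the whole suite completes in a few minutes while leaving each stage
non-trivial. Marker-recovery sensitivity is measured at the generator's
defaults (2 × 100 cells, 2000 genes, 50 markers, fold 4).

## Known limitations

* The cluster-number sweep is O(udc · n_init · max_iter · n · a); very
  large matrices need feature reduction first (as the pipeline's
  top-variance step provides).
* The normalization is a contract-faithful simplification; its selected
  K is not comparable to the original SCnorm's.
* Rare-cell/outlier detection, enrichment analysis, and HDF5/10x
  ingestion are out of scope.
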