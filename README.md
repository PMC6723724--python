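# mofuzz

Multi-objective optimized fuzzy clustering for single-cell RNA-seq count
matrices.

Choosing the number of cell clusters is the perennial open question in
scRNA-seq analysis. `mofuzz` treats it as a multi-criteria decision
problem: it sweeps fuzzy c-means over a range of cluster numbers, scores
every candidate clustering with four fuzzy validity indices, and lets
TOPSIS — a classical multi-criteria ranking method — pick the cluster
number whose index profile is closest to the ideal. The selected
clustering then drives empirical-Bayes differential expression and
fold-change marker calling per cluster. It is aimed at analysts working
with plate-scale experiments (hundreds of cells) who want a transparent,
fully scripted alternative to graph-based clustering with a defensible
choice of k.

## Method

Given a genes × cells count matrix the pipeline runs:

1. **Filtering** — cells detecting > 2000 genes are kept; then genes
   detected in more than 3 and fewer than 500 cells; then the top 3000
   most variable genes (all thresholds configurable).
2. **Depth normalization** — a simplified SCnorm-style procedure: the
   count–depth slope of each gene (median regression of log counts on log
   sequencing depth) is estimated, genes are grouped into K
   slope-homogeneous groups, and counts are rescaled by
   `(depth_c / median depth)^b` per group; K grows from 1 until the slope
   modes of ten median-expression gene groups all sit within 0.1 of zero.
3. **Fuzzy c-means sweep** — for cl = 2..udc, minimize
   `J = Σ_j Σ_q u_jq^m ‖x_q − cen_j‖²` over memberships U (columns sum
   to 1) and centers, by the standard alternating updates, on
   log2(normalized + 1) cell features.
4. **Validity indices** — partition entropy (PE, minimize), partition
   coefficient (PC), modified partition coefficient (MPC), and the fuzzy
   silhouette index (FSI) (maximize) for each cl.
5. **TOPSIS selection** — the (udc−1) × 4 validity matrix is normalized,
   weighted, and each cluster number is ranked by its relative closeness
   `RC = d⁻/(d⁻ + d⁺)` to the ideal/anti-ideal index profile; the rank-1
   cl wins.
6. **Differential expression** — each cluster vs the rest with an
   independently implemented empirical-Bayes moderated t
   (`s̃² = (d₀s₀² + d s²)/(d₀ + d)`), Bonferroni correction, DEG calls at
   adjusted p < 0.05, and up-regulated markers at fold change > 2.

A seeded synthetic-data generator (negative-binomial counts, log-uniform
depth factors, independent dropout, planted marker blocks) makes every
stage testable without any download.

## Worked example

Simulate three planted cell clusters and run the whole pipeline:

```sh
mofuzz simulate --cells-per-cluster 60,60,60 --genes 500 --markers 40 \
    --fold 8 --seed 11 --out counts.csv
printf 'min_cell_detected: 50\ntop_variant: 200\nudc: 6\nn_init: 3\nmax_iter: 200\nepsilon: 1.0e-5\n' > config.yaml
mofuzz run-all counts.csv --config config.yaml --outdir out --seed 11
# {"selected_cl": 3, "outdir": "out"}
```

`out/validity_table.tsv` holds the four indices per candidate cluster
number, and `out/topsis_table.tsv` the ranking (values abridged):

```
cl  FSI    PE     PC     MPC        closeness  rank
2   0.123  0.409  0.749  0.499      0.596      3
3   0.163  0.358  0.831  0.746      0.935      1
4   0.168  0.662  0.646  0.529      0.688      2
5   0.177  0.875  0.523  0.403      0.567      4
6   0.029  1.051  0.415  0.298      0.000      5
```

The planted cluster number (3) wins: it has the lowest partition entropy
and the highest PC/MPC, so its index profile sits closest to the ideal.
The normalization manifest entry reports `chosen_k: 3, converged: true,
max_abs_mode: 0.028` — all ten post-normalization slope modes are within
0.1 of zero. Per-cluster DE then finds 92/82/87 Bonferroni-significant
genes and 35/34/35 up-regulated markers (of 40 planted each); the top
marker rows of `out/markers_cluster_0.tsv` show linear fold changes of
6–8 against a planted fold of 8:

```
gene_id   log2_fc  p_adjusted  fold_change
gene_66   2.976    2.46e-27    7.55
gene_51   2.572    5.47e-27    6.25
```

Every artifact (memberships, labels, PCA coordinates, slope diagnostics,
network metrics, run manifest with output hashes) is plain delimited text
or JSON under `out/`.

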