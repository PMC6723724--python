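"""Seeded synthetic scRNA-seq count matrices with planted structure.

The generator emulates the three data properties the pipeline assumes:
per-cell sequencing-depth variation (log-uniform depth factors spanning up
to an order of magnitude or more), negative-binomial overdispersion with
independent dropout, and K planted cell clusters distinguished by marker
genes at a configurable fold change. Gene baseline means are log-normal,
so the matrix mixes lowly and highly expressed genes.

It is deliberately minimal: no batch effects, no gene-gene correlation
beyond the cluster structure, no library-preparation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from mofuzz.sc_io import CountMatrix
from mofuzz.topsis import DecisionMatrix


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated matrix."""

    labels: np.ndarray  # 0-based cluster label per cell
    marker_genes: dict[int, list[str]]  # cluster -> planted marker ids
    marker_fold: float
    depth_factor: np.ndarray  # per-cell depth multiplier
    baseline_mean: np.ndarray  # per-gene baseline mean
    nb_dispersion: float
    dropout: float
    seed: int
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_clusters = int(len(np.unique(self.labels)))


def generate_counts(
    n_cells_per_cluster: tuple[int, ...] = (100, 100),
    n_genes: int = 2000,
    n_markers_per_cluster: int = 50,
    marker_fold: float = 4.0,
    depth_range: tuple[float, float] = (1.0, 10.0),
    nb_dispersion: float = 10.0,
    dropout: float = 0.1,
    seed: int = 0,
    baseline_log_mean: float = 1.5,
    baseline_log_sd: float = 1.0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a genes x cells count matrix with K planted clusters.

    Per-cell depth factors are log-uniform on ``depth_range``; baseline
    gene means are log-normal; the first ``K * n_markers_per_cluster``
    genes are markers, cluster k's block having mean ``baseline *
    marker_fold`` in cluster k. Counts are negative binomial with mean
    ``depth * mean`` and size ``nb_dispersion`` (variance mu + mu^2/size),
    then zeroed independently with probability ``dropout``.
    """
    if marker_fold < 1:
        raise ValueError("marker_fold must be >= 1")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    lo, hi = depth_range
    if not 0 < lo <= hi:
        raise ValueError("depth_range must satisfy 0 < lo <= hi")
    k = len(n_cells_per_cluster)
    if k * n_markers_per_cluster > n_genes:
        raise ValueError("more planted markers than genes")

    rng = np.random.default_rng(seed)
    n_cells = int(sum(n_cells_per_cluster))
    labels = np.repeat(np.arange(k), n_cells_per_cluster)

    depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))

    gene_ids = [f"gene_{i}" for i in range(n_genes)]
    marker_genes: dict[int, list[str]] = {}
    mean = np.tile(baseline[:, None], (1, n_cells))
    for c in range(k):
        start = c * n_markers_per_cluster
        idx = np.arange(start, start + n_markers_per_cluster)
        marker_genes[c] = [gene_ids[i] for i in idx]
        mean[np.ix_(idx, labels == c)] *= marker_fold
    mu = mean * depth[None, :]

    p = nb_dispersion / (nb_dispersion + mu)
    counts = rng.negative_binomial(nb_dispersion, p).astype(float)
    if dropout > 0:
        counts[rng.uniform(size=counts.shape) < dropout] = 0.0

    cell_ids = [f"cell_{i}" for i in range(n_cells)]
    truth = SyntheticTruth(
        labels=labels,
        marker_genes=marker_genes,
        marker_fold=marker_fold,
        depth_factor=depth,
        baseline_mean=baseline,
        nb_dispersion=nb_dispersion,
        dropout=dropout,
        seed=seed,
    )
    return CountMatrix(counts, gene_ids, cell_ids), truth


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("mofuzz.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_fixture() -> DecisionMatrix:
    """The nine-row validity-score decision matrix of the published worked
    example (cl = 2..10; criteria FSI, PE, PC, MPC; FSI/PC/MPC benefit, PE
    cost; equal weights)."""
    df = _load_fixture("table1_validity.tsv")
    return DecisionMatrix(
        values=df[["FSI", "PE", "PC", "MPC"]].to_numpy(),
        impacts=["benefit", "cost", "benefit", "benefit"],
        weights=None,
        alternatives=[f"cl={c}" for c in df["cl"]],
        criteria=["FSI", "PE", "PC", "MPC"],
    )


def table2_scores() -> np.ndarray:
    """The published TOPSIS score column the calibration targets
    (cl = 2..10, descending)."""
    return _load_fixture("table2_scores.tsv")["score"].to_numpy(dtype=float)
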