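"""Count-depth normalization for single-cell count matrices.

A simplified SCnorm-style procedure. Each gene's count-depth relationship
is the slope of a quantile (default median) regression of log non-zero
counts on log sequencing depth; before normalization this slope sits near 1
(counts scale with depth), after successful normalization it should sit
near 0. Genes are partitioned into K slope-homogeneous groups; a pooled
quantile regression per group yields a group slope ``b``, and each count in
cell ``c`` is divided by the factor ``(depth_c / median_depth) ** b``.
Success is judged on 10 median-expression gene groups: when every group's
kernel-density mode of post-normalization slopes lies within 0.1 of zero
the normalization is accepted, otherwise K is incremented and the procedure
restarts from the raw counts.

The quantile-regression slope is equivariant under subtracting a linear
function of the regressor, so the post-normalization slope of a gene equals
its raw slope minus the group ``b`` that was applied to it; diagnostics use
this identity instead of refitting every gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde

from mofuzz.errors import TooFewSlopesError, ZeroDepthError
from mofuzz.sc_io import CountMatrix

logger = logging.getLogger(__name__)

_MAX_POOLED_POINTS = 50_000


def sequencing_depth(m: CountMatrix) -> np.ndarray:
    """Per-cell sequencing depth: the column sum of counts."""
    depths = m.counts.sum(axis=0)
    if np.any(depths <= 0):
        bad = [m.cell_ids[i] for i in np.flatnonzero(depths <= 0)]
        raise ZeroDepthError(f"cells with zero total counts: {bad[:5]}")
    return depths


def _quantile_slope(x: np.ndarray, y: np.ndarray, tau: float) -> float:
    """Slope of a quantile-tau regression of y on x.

    An exact linear relationship is detected first and returned via least
    squares (the IRLS quantile fit is ill-conditioned at zero residuals).
    """
    coeffs = np.polyfit(x, y, 1)
    if np.max(np.abs(np.polyval(coeffs, x) - y)) < 1e-10:
        return float(coeffs[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, sm.add_constant(x)).fit(q=tau)
    return float(res.params[1])


def gene_depth_slope(
    gene_counts: np.ndarray,
    depths: np.ndarray,
    tau: float = 0.5,
    min_nonzero: int = 10,
) -> float:
    """Count-depth slope of one gene, or NaN when coverage is too sparse.

    Fits log(count) ~ log(depth) by quantile-tau regression over the cells
    with non-zero counts; genes expressed in fewer than ``min_nonzero``
    cells are excluded from slope estimation (returned as NaN).
    """
    gene_counts = np.asarray(gene_counts, dtype=float)
    depths = np.asarray(depths, dtype=float)
    nz = gene_counts > 0
    if nz.sum() < max(min_nonzero, 2):
        return float("nan")
    x = np.log(depths[nz])
    y = np.log(gene_counts[nz])
    if np.ptp(x) == 0:
        return float("nan")
    return _quantile_slope(x, y, tau)


def gene_depth_slopes(
    m: CountMatrix, depths: np.ndarray, tau: float = 0.5, min_nonzero: int = 10
) -> np.ndarray:
    """Vector of per-gene count-depth slopes (NaN for sparse genes)."""
    return np.array(
        [gene_depth_slope(m.counts[g], depths, tau, min_nonzero) for g in range(m.n_genes)]
    )


def _equal_size_bins(order: np.ndarray, n_groups: int) -> np.ndarray:
    """Labels 1..n_groups along ``order``, remainder going to the lowest bins."""
    n = order.size
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    labels = np.empty(n, dtype=np.int64)
    start = 0
    for g, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = g
        start += size
    return labels


def group_genes_by_median(m: CountMatrix, n_groups: int = 10) -> np.ndarray:
    """Bin genes into equal-size groups by their non-zero median expression.

    Labels run 1..n_groups from the lowest to the highest median; when the
    gene count is not divisible, the lower bins take the remainder. Ties
    break by input gene order.
    """
    if n_groups > m.n_genes:
        raise ValueError(f"n_groups={n_groups} exceeds {m.n_genes} genes")
    medians = np.empty(m.n_genes)
    for g in range(m.n_genes):
        nz = m.counts[g][m.counts[g] > 0]
        if nz.size == 0:
            raise ValueError(f"gene {m.gene_ids[g]} has no non-zero entries")
        medians[g] = np.median(nz)
    order = np.argsort(medians, kind="stable")
    return _equal_size_bins(order, n_groups)


def slope_mode(slopes: np.ndarray) -> float:
    """Location of the peak of a Gaussian KDE over the slopes.

    Silverman-rule bandwidth, evaluated on a 512-point grid spanning the
    data range; ties (and the degenerate all-equal case) resolve to the
    lower value.
    """
    slopes = np.asarray(slopes, dtype=float)
    slopes = slopes[np.isfinite(slopes)]
    if slopes.size < 2:
        raise TooFewSlopesError(f"need >= 2 finite slopes, got {slopes.size}")
    if np.ptp(slopes) == 0:
        return float(slopes[0])
    kde = gaussian_kde(slopes, bw_method="silverman")
    grid = np.linspace(slopes.min(), slopes.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class SlopeDiagnostics:
    """Per-gene slopes and group-mode diagnostics of one normalization."""

    gene_ids: list[str]
    raw_slope: np.ndarray
    normalized_slope: np.ndarray
    slope_group: np.ndarray  # 1..K, 0 for genes scaled via their median group
    median_group: np.ndarray  # 1..n_median_groups
    group_modes: dict[int, float]
    chosen_k: int
    converged: bool
    max_abs_mode: float
    scale_exponent: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "raw_slope": self.raw_slope,
                "normalized_slope": self.normalized_slope,
                "slope_group": self.slope_group,
                "median_group": self.median_group,
                "scale_exponent": self.scale_exponent,
            }
        )


def _pooled_slope(
    counts: np.ndarray, log_depths: np.ndarray, gene_idx: np.ndarray, tau: float
) -> float:
    """Pooled quantile slope over a gene group.

    Log non-zero counts are centered per gene (by their median) before
    pooling so that between-gene level differences do not leak into the
    slope; centering does not change the fitted slope of any single gene.
    """
    xs, ys = [], []
    for g in gene_idx:
        row = counts[g]
        nz = row > 0
        if nz.sum() < 2:
            continue
        y = np.log(row[nz])
        xs.append(log_depths[nz])
        ys.append(y - np.median(y))
    if not xs:
        return 0.0
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size > _MAX_POOLED_POINTS:
        step = x.size // _MAX_POOLED_POINTS + 1
        x, y = x[::step], y[::step]
    if np.ptp(x) == 0:
        return 0.0
    return _quantile_slope(x, y, tau)


def scnorm_normalize(
    m: CountMatrix,
    mode_threshold: float = 0.1,
    k_init: int = 1,
    k_max: int = 10,
    tau: float = 0.5,
    min_nonzero: int = 10,
    n_median_groups: int = 10,
) -> tuple[CountMatrix, SlopeDiagnostics]:
    """Depth-normalize counts until all group slope modes are near zero.

    For each candidate K (starting at ``k_init``), genes with estimable
    slopes are split into K equal-size slope bins; each bin's pooled
    quantile-regression slope ``b`` defines per-cell scale factors
    ``(depth_c / median_depth) ** b`` dividing that bin's counts. Genes too
    sparse for slope estimation inherit the dominant bin of their
    median-expression group. The attempt is accepted when the slope modes
    of all ``n_median_groups`` median-expression groups (computed on the
    normalized counts) fall within ``mode_threshold`` of zero; otherwise K
    is incremented and normalization restarts from the raw counts. If
    ``k_max`` is exhausted the best attempt (smallest worst-case |mode|) is
    returned with ``converged=False``.
    """
    depths = sequencing_depth(m)
    log_depths = np.log(depths)
    log_ratio = log_depths - np.log(np.median(depths))

    raw_slopes = gene_depth_slopes(m, depths, tau, min_nonzero)
    eligible = np.isfinite(raw_slopes)
    median_group = group_genes_by_median(m, n_median_groups)
    if eligible.sum() < 2:
        raise TooFewSlopesError(
            "fewer than 2 genes have enough non-zero entries for slope estimation"
        )

    best: tuple[float, CountMatrix, SlopeDiagnostics] | None = None
    for k in range(k_init, k_max + 1):
        elig_idx = np.flatnonzero(eligible)
        n_bins = min(k, elig_idx.size)
        order_within = np.argsort(raw_slopes[elig_idx], kind="stable")
        bin_labels = _equal_size_bins(np.arange(elig_idx.size), n_bins)
        slope_group = np.zeros(m.n_genes, dtype=np.int64)
        slope_group[elig_idx[order_within]] = bin_labels

        group_b = {}
        for g in range(1, n_bins + 1):
            members = np.flatnonzero(slope_group == g)
            group_b[g] = _pooled_slope(m.counts, log_depths, members, tau)
        global_b = _pooled_slope(m.counts, log_depths, elig_idx, tau)

        # sparse genes inherit the dominant slope bin of their median group
        applied_b = np.empty(m.n_genes)
        for g in range(m.n_genes):
            if slope_group[g] > 0:
                applied_b[g] = group_b[slope_group[g]]
            else:
                peers = slope_group[(median_group == median_group[g]) & eligible]
                if peers.size:
                    dominant = np.bincount(peers).argmax()
                    applied_b[g] = group_b[dominant]
                else:
                    applied_b[g] = global_b

        scale = np.exp(np.outer(applied_b, log_ratio))  # genes x cells
        normalized = CountMatrix(m.counts / scale, list(m.gene_ids), list(m.cell_ids))

        norm_slopes = np.where(eligible, raw_slopes - applied_b, np.nan)
        modes: dict[int, float] = {}
        for mg in range(1, n_median_groups + 1):
            vals = norm_slopes[(median_group == mg) & eligible]
            if vals.size >= 2:
                modes[mg] = slope_mode(vals)
        max_abs = max(abs(v) for v in modes.values()) if modes else float("inf")

        diag = SlopeDiagnostics(
            gene_ids=list(m.gene_ids),
            raw_slope=raw_slopes,
            normalized_slope=norm_slopes,
            slope_group=slope_group,
            median_group=median_group,
            group_modes=modes,
            chosen_k=k,
            converged=max_abs <= mode_threshold,
            max_abs_mode=max_abs,
            scale_exponent=applied_b,
        )
        if diag.converged:
            return normalized, diag
        if best is None or max_abs < best[0]:
            best = (max_abs, normalized, diag)

    logger.warning(
        "normalization did not converge by K=%d (best max |mode| = %.3f)",
        k_max,
        best[0],
    )
    return best[1], best[2]


def depth_scale(m: CountMatrix) -> CountMatrix:
    """Plain depth scaling: counts / depth x median depth (ablation mode)."""
    depths = sequencing_depth(m)
    factor = depths / np.median(depths)
    return CountMatrix(m.counts / factor, list(m.gene_ids), list(m.cell_ids))
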