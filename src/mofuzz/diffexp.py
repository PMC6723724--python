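"""Per-cluster differential expression by an empirical-Bayes moderated t.

Each cluster is contrasted against the union of all other cells on
log2(normalized + 1) expression. Per gene the two-group pooled residual
variance s_g^2 (d = n - 2 degrees of freedom) is shrunk toward a prior
variance s0^2 with prior degrees of freedom d0,

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

and the moderated statistic t_g = (mean_1 - mean_2) / (s~_g * sqrt(1/n1 +
1/n2)) is referred to a t distribution with d0 + d degrees of freedom.
The hyperparameters (d0, s0^2) are estimated by the closed-form method of
moments on z_g = log s_g^2, whose marginal mean and variance under the
scaled-F sampling model involve digamma/trigamma functions of d/2 and
d0/2; the trigamma equation is inverted by Newton iteration. When the
observed spread of z is no larger than its pure sampling component, d0 is
infinite and s~^2 = s0^2 with a normal reference.

P-values are Bonferroni-adjusted (multiply by the number of tested genes,
cap at 1); genes with adjusted p below 0.05 are flagged differentially
expressed, and up-regulated markers are the DEGs whose linear-scale
fold change (pseudocount 1) exceeds a cutoff (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from mofuzz.errors import GroupTooSmallError
from mofuzz.sc_io import CountMatrix


def log_transform(m: CountMatrix | np.ndarray) -> np.ndarray:
    """Elementwise log2(value + 1)."""
    values = m.counts if isinstance(m, CountMatrix) else np.asarray(m, dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    return np.log2(values + 1.0)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from gene-wise variances.

    Matches the mean and variance of z = log(s^2) to the scaled-F
    reference with df residual and d0 prior degrees of freedom. Returns
    (inf, s0^2) when the between-gene spread of z does not exceed its
    sampling variance trigamma(df/2).
    """
    s2 = np.asarray(s2, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.log(s2)
    z = z[np.isfinite(z)]
    if z.size < 2:
        return float("inf"), float(np.exp(z.mean())) if z.size else 1.0
    e_z = z.mean()
    var_z = z.var(ddof=1)
    excess = var_z - float(special.polygamma(1, df / 2.0))
    base = e_z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    if excess <= 0:
        return float("inf"), float(np.exp(base))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = np.exp(base + float(special.digamma(d0 / 2.0)) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


@dataclass
class DEResult:
    """Moderated-t results for one cluster-vs-rest contrast."""

    cluster: int
    table: pd.DataFrame
    d0: float
    s0_squared: float
    n_cluster: int
    n_rest: int

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["is_DEG"]]


def moderated_t_test(
    expr: np.ndarray,
    labels: np.ndarray,
    cluster: int,
    gene_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> DEResult:
    """Empirical-Bayes moderated t for one cluster vs all other cells.

    ``expr`` is a genes x cells matrix of log-scale expression; ``labels``
    assigns each cell a cluster id. Both groups need at least 2 cells.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    in_grp = labels == cluster
    n1, n2 = int(in_grp.sum()), int((~in_grp).sum())
    if n1 < 2 or n2 < 2:
        raise GroupTooSmallError(
            f"cluster {cluster}: group sizes {n1} vs {n2}; both must be >= 2"
        )
    n_genes = expr.shape[0]
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(n_genes)]

    x1, x2 = expr[:, in_grp], expr[:, ~in_grp]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + (
        (x2 - mean2[:, None]) ** 2
    ).sum(axis=1)
    df_res = n1 + n2 - 2
    s2 = ss / df_res

    d0, s0_2 = fit_variance_prior(s2, df_res)
    if np.isinf(d0):
        s2_mod = np.full(n_genes, s0_2)
        df_total = float("inf")
    else:
        s2_mod = (d0 * s0_2 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    delta = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = bonferroni(p)

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_cluster": mean1,
            "mean_rest": mean2,
            "log2_fc": delta,
            "var_residual": s2,
            "var_moderated": s2_mod,
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "p_adjusted": p_adj,
            "is_DEG": p_adj < alpha,
        }
    )
    return DEResult(
        cluster=int(cluster),
        table=table,
        d0=d0,
        s0_squared=s0_2,
        n_cluster=n1,
        n_rest=n2,
    )


def bonferroni(pvals: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * number of tests)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, pvals * pvals.size)


def call_markers(
    norm: CountMatrix,
    labels: np.ndarray,
    fc_cutoff: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[dict[int, DEResult], dict[int, pd.DataFrame]]:
    """DE tables and up-regulated marker lists for every cluster.

    DE runs on log2(normalized + 1); the marker fold change is computed on
    the linear normalized scale as (mean_in + pseudocount) / (mean_rest +
    pseudocount). Markers are DEGs with fold change above ``fc_cutoff``,
    ranked by adjusted p ascending, then |log2 fc| descending, then input
    gene order.
    """
    labels = np.asarray(labels)
    expr = log_transform(norm)
    de_results: dict[int, DEResult] = {}
    markers: dict[int, pd.DataFrame] = {}
    for cluster in np.unique(labels):
        cluster = int(cluster)
        de = moderated_t_test(expr, labels, cluster, list(norm.gene_ids), alpha)
        in_grp = labels == cluster
        fc = (norm.counts[:, in_grp].mean(axis=1) + pseudocount) / (
            norm.counts[:, ~in_grp].mean(axis=1) + pseudocount
        )
        table = de.table.copy()
        table["fold_change"] = fc
        table["is_up_marker"] = table["is_DEG"] & (fc > fc_cutoff)
        table["_order"] = np.arange(len(table))
        table = table.sort_values(
            by=["p_adjusted", "log2_fc", "_order"],
            ascending=[True, False, True],
            key=lambda col: col.abs() if col.name == "log2_fc" else col,
        ).drop(columns="_order")
        de.table = table
        de_results[cluster] = de
        markers[cluster] = table[table["is_up_marker"]].reset_index(drop=True)
    return de_results, markers
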