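"""Initial filtering of a raw count matrix.

The pipeline order is fixed: cells first, then genes, then top-variance
gene selection. All detection filters act on the booleanized matrix
(an entry "detects" a gene in a cell iff its count is non-zero), so they
depend only on the detection pattern, not on count magnitudes. All
thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mofuzz.errors import EmptyResultError
from mofuzz.sc_io import CountMatrix


@dataclass
class FilterReport:
    """Summary of one filtering step."""

    step: str
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    thresholds: dict = field(default_factory=dict)
    kept_gene_ids: list[str] = field(default_factory=list)
    kept_cell_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            **{f"threshold_{k}": v for k, v in self.thresholds.items()},
        }


def booleanize(m: CountMatrix) -> np.ndarray:
    """Detection matrix: 1 where the count is non-zero, else 0."""
    return (m.counts > 0).astype(np.int64)


def filter_cells(
    m: CountMatrix, min_detected: int = 2000
) -> tuple[CountMatrix, FilterReport]:
    """Keep cells detecting strictly more than ``min_detected`` genes."""
    if min_detected < 0:
        raise ValueError("min_detected must be >= 0")
    detected_per_cell = booleanize(m).sum(axis=0)
    keep = detected_per_cell > min_detected
    if not keep.any():
        raise EmptyResultError(
            f"no cell detects more than {min_detected} genes"
        )
    out = m.subset_cells(keep)
    report = FilterReport(
        step="filter_cells",
        n_cells_in=m.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=m.n_genes,
        n_genes_out=out.n_genes,
        thresholds={"min_detected": min_detected},
        kept_gene_ids=list(out.gene_ids),
        kept_cell_ids=list(out.cell_ids),
    )
    return out, report


def filter_genes(
    m: CountMatrix, min_detected: int = 3, max_detected: int = 500
) -> tuple[CountMatrix, FilterReport]:
    """Keep genes detected in strictly more than ``min_detected`` and
    strictly fewer than ``max_detected`` cells."""
    if not min_detected < max_detected:
        raise ValueError("min_detected must be < max_detected")
    detected_per_gene = booleanize(m).sum(axis=1)
    keep = (detected_per_gene > min_detected) & (detected_per_gene < max_detected)
    if not keep.any():
        raise EmptyResultError(
            f"no gene detected in ({min_detected}, {max_detected}) cells"
        )
    out = m.subset_genes(keep)
    report = FilterReport(
        step="filter_genes",
        n_cells_in=m.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=m.n_genes,
        n_genes_out=out.n_genes,
        thresholds={"min_detected": min_detected, "max_detected": max_detected},
        kept_gene_ids=list(out.gene_ids),
        kept_cell_ids=list(out.cell_ids),
    )
    return out, report


def select_top_variant_genes(
    m: CountMatrix, k: int = 3000, log1p: bool = False
) -> tuple[CountMatrix, FilterReport]:
    """Keep the ``k`` genes with the largest across-cell variance.

    Variance uses the unbiased (n-1) denominator on the counts as stored;
    ``log1p=True`` ranks on log1p-transformed counts instead. Ties at the
    k-th rank break by input gene order, and the output preserves input
    gene order.
    """
    if not 1 <= k <= m.n_genes:
        raise ValueError(f"k={k} outside [1, {m.n_genes}]")
    values = np.log1p(m.counts) if log1p else m.counts
    variances = values.var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    # stable sort on negated variance keeps input order among ties
    order = np.argsort(-variances, kind="stable")[:k]
    keep = np.zeros(m.n_genes, dtype=bool)
    keep[order] = True
    out = m.subset_genes(keep)
    report = FilterReport(
        step="select_top_variant_genes",
        n_cells_in=m.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=m.n_genes,
        n_genes_out=out.n_genes,
        thresholds={"k": k, "log1p": log1p},
        kept_gene_ids=list(out.gene_ids),
        kept_cell_ids=list(out.cell_ids),
    )
    return out, report
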