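"""Reading and writing count matrices and tabular pipeline outputs.

On-disk orientation is genes-as-rows, cells-as-columns (the dominant
scRNA-seq convention); ``transposed=True`` accepts cell-rowed input.
Matrix Market files use 1-based indices on disk and carry their gene and
cell identifiers in plain-text sidecar files next to the matrix
(``<stem>_genes.txt`` and ``<stem>_cells.txt``, one identifier per line).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from mofuzz.errors import (
    DimensionMismatchError,
    DuplicateIdentifierError,
    MissingFileError,
    NegativeEntryError,
)


@dataclass
class CountMatrix:
    """A genes x cells matrix of non-negative values with identifiers.

    Raw integer counts and normalized (real-valued) matrices share this
    type; every entry must be >= 0 and identifiers must be unique.
    """

    counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise DimensionMismatchError(
                f"counts must be 2-D, got shape {self.counts.shape}"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(self.counts.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.counts.shape[1])]
        if np.any(self.counts < 0):
            raise NegativeEntryError("count matrix contains negative entries")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DuplicateIdentifierError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DuplicateIdentifierError("duplicate cell identifiers")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DimensionMismatchError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.counts[mask, :],
            [g for g, keep in zip(self.gene_ids, mask) if keep]
            if mask.dtype == bool
            else [self.gene_ids[i] for i in mask],
            list(self.cell_ids),
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.counts[:, mask],
            list(self.gene_ids),
            [c for c, keep in zip(self.cell_ids, mask) if keep]
            if mask.dtype == bool
            else [self.cell_ids[i] for i in mask],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_genes.txt"), Path(f"{stem}_cells.txt")


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise MissingFileError(f"identifier sidecar not found: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def read_count_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    transposed: bool = False,
) -> CountMatrix:
    """Read a count matrix from Matrix Market or delimited text.

    Parameters
    ----------
    path
        ``.mtx`` file (with ``<stem>_genes.txt``/``<stem>_cells.txt``
        sidecars) or a CSV/TSV with a header row of cell identifiers and
        gene identifiers in the first column.
    format
        One of ``{"mtx", "csv", "tsv"}``; inferred from the suffix when
        omitted.
    transposed
        Set when the file stores cells as rows.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in {"mtx", "csv", "tsv"}:
        raise ValueError(f"unsupported format {format!r}")

    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes_path, cells_path = _sidecar_paths(path)
        gene_ids = _read_ids(genes_path)
        cell_ids = _read_ids(cells_path)
    else:
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]

    if transposed:
        mat = mat.T
        gene_ids, cell_ids = cell_ids, gene_ids
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise DimensionMismatchError(
            f"matrix shape {mat.shape} does not match sidecar lengths "
            f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
        )
    return CountMatrix(mat, gene_ids, cell_ids)


def write_count_matrix(
    m: CountMatrix, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a CountMatrix as .mtx (+ identifier sidecars) or CSV/TSV."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.counts))
        genes_path, cells_path = _sidecar_paths(path)
        genes_path.write_text("\n".join(m.gene_ids) + "\n")
        cells_path.write_text("\n".join(m.cell_ids) + "\n")
    elif format in {"csv", "tsv"}:
        sep = "," if format == "csv" else "\t"
        m.to_frame().to_csv(path, sep=sep, index_label="gene_id")
    else:
        raise ValueError(f"unsupported format {format!r}")


def write_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a tabular result as delimited text with a header row.

    The delimiter follows the suffix (TSV for ``.tsv``, CSV otherwise);
    read-back with :func:`pandas.read_csv` reproduces the content.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
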