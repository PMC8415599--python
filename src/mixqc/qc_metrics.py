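"""Per-cell quality-control metrics from a gene-by-cell count matrix.

The two metrics the mixture model consumes are *library complexity*
(number of unique genes with nonzero counts in a cell) and the
*mitochondrial fraction* (percent of a cell's counts mapping to
mitochondrially encoded genes, on a 0-100 scale).  A hard prefilter
removes cells that are unambiguous failures before any model is fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CountMatrix",
    "identify_mito_genes",
    "compute_cell_qc",
    "prefilter",
    "QC_COLUMNS",
]

#: canonical column order of a per-cell metrics table
QC_COLUMNS = ["cell_id", "total_counts", "detected_genes", "pct_mito", "zero_total_flag"]


@dataclass
class CountMatrix:
    """Gene-by-cell count matrix (rows = genes, columns = cells).

    Parameters
    ----------
    values
        Nonnegative counts, dense ndarray or any scipy sparse matrix;
        stored internally as CSC for fast per-cell (column) reductions.
    gene_ids
        Unique gene identifiers, one per row.  When a separate symbol
        column is available (10x features files), pass symbols here or
        in ``gene_symbols`` — mitochondrial matching prefers symbols.
    cell_ids
        Unique cell barcodes, one per column.
    gene_symbols
        Optional human-readable symbols aligned with ``gene_ids``.
    """

    values: sparse.csc_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    gene_symbols: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not sparse.issparse(self.values):
            self.values = sparse.csc_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsc()
        n_genes, n_cells = self.values.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != row count {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != column count {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.gene_symbols is not None and len(self.gene_symbols) != n_genes:
            raise ValueError("gene_symbols length must match gene count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def matching_names(self) -> list[str]:
        """Names used for mitochondrial-gene matching (symbols if present)."""
        return self.gene_symbols if self.gene_symbols is not None else self.gene_ids


def identify_mito_genes(
    gene_ids: list[str] | np.ndarray,
    pattern: str = "MT-",
    explicit: list[str] | None = None,
    allow_hyphenless: bool = False,
) -> np.ndarray:
    """Return sorted indices of mitochondrial genes.

    By default a gene is mitochondrial when its name starts with the
    case-insensitive prefix ``MT-`` (the convention of human/mouse
    reference annotations).  ``allow_hyphenless`` additionally accepts a
    bare ``MT`` prefix (e.g. ``MTND1``); off by default because it also
    matches nuclear genes such as ``MTOR``.  An ``explicit`` list of
    names overrides pattern matching entirely.

    An empty pattern-based result only warns — the annotation may simply
    use another convention — but the caller should treat a 0% mito
    fraction everywhere with suspicion.
    """
    gene_ids = [str(g) for g in gene_ids]
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    if explicit is not None:
        wanted = {str(g) for g in explicit}
        idx = [i for i, g in enumerate(gene_ids) if g in wanted]
        return np.asarray(idx, dtype=np.int64)

    pat = pattern.upper()
    idx = []
    for i, g in enumerate(gene_ids):
        gu = g.upper()
        if gu.startswith(pat) or (allow_hyphenless and gu.startswith(pat.rstrip("-"))):
            idx.append(i)
    if not idx:
        warnings.warn(
            f"no gene matched mitochondrial pattern {pattern!r}; "
            "pct_mito will be 0 for every cell",
            UserWarning,
            stacklevel=2,
        )
    return np.asarray(idx, dtype=np.int64)


def compute_cell_qc(m: CountMatrix, mito_idx: np.ndarray | list[int]) -> pd.DataFrame:
    """Compute the per-cell metrics table.

    Returns a DataFrame with columns ``cell_id``, ``total_counts``,
    ``detected_genes`` (genes with count > 0), ``pct_mito`` (percent of
    counts in mitochondrial genes, 0-100) and ``zero_total_flag``.
    Cells with zero total counts get ``pct_mito = 0`` and the flag set,
    so the table is defined for every input cell.
    """
    mito_idx = np.asarray(mito_idx, dtype=np.int64)
    if mito_idx.size and (mito_idx.min() < 0 or mito_idx.max() >= m.n_genes):
        raise IndexError("mitochondrial gene index out of range")

    X = m.values
    total = np.asarray(X.sum(axis=0)).ravel()
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    mito_total = (
        np.asarray(X[mito_idx, :].sum(axis=0)).ravel()
        if mito_idx.size
        else np.zeros_like(total)
    )
    zero = total == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(zero, 0.0, 100.0 * mito_total / np.where(zero, 1, total))
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "total_counts": total.astype(np.int64),
            "detected_genes": detected.astype(np.int64),
            "pct_mito": pct.astype(float),
            "zero_total_flag": zero,
        }
    )


def prefilter(
    cells: pd.DataFrame, min_total: int = 500, min_genes: int = 100
) -> tuple[pd.DataFrame, list[str]]:
    """Drop unambiguously failed cells before model fitting.

    A cell is removed when it has strictly fewer than ``min_total``
    total counts or strictly fewer than ``min_genes`` detected genes.
    Returns the retained table (original order, reindexed) and the list
    of removed cell ids.
    """
    bad = (cells["total_counts"] < min_total) | (cells["detected_genes"] < min_genes)
    removed = cells.loc[bad, "cell_id"].tolist()
    return cells.loc[~bad].reset_index(drop=True), removed
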