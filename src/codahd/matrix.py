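"""Core containers for gene x cell count data and per-cell annotations.

Counts are stored sparse (CSC) with genes as rows everywhere in this
package, matching the 10x MatrixMarket convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "CellAnnotation"]


def _as_str_list(ids: Sequence[str]) -> list[str]:
    return [str(i) for i in ids]


@dataclass
class CountMatrix:
    """Sparse non-negative integer count matrix, genes x cells.

    Parameters
    ----------
    values
        Any scipy sparse matrix or dense array; stored as CSC with
        float64 data holding integral values (raw counts).
    gene_ids
        Unique row identifiers, length D.
    cell_ids
        Unique column identifiers, length N.
    """

    values: sp.csc_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csc_matrix(np.asarray(self.values))
        self.values = self.values.tocsc()
        self.values.eliminate_zeros()
        self.gene_ids = _as_str_list(self.gene_ids)
        self.cell_ids = _as_str_list(self.cell_ids)
        D, N = self.values.shape
        if len(self.gene_ids) != D:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != number of rows {D}"
            )
        if len(self.cell_ids) != N:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != number of columns {N}"
            )
        if len(set(self.gene_ids)) != D:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != N:
            raise ValueError("cell_ids are not unique")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data), atol=1e-8):
                raise ValueError("counts must be integral")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- summaries ------------------------------------------------------
    def cell_totals(self) -> np.ndarray:
        """Per-cell total counts S_j (length N)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (nonzero) genes per cell."""
        return np.diff(self.values.indptr)

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells with nonzero count per gene."""
        return np.diff(self.values.tocsr().indptr)

    def gene_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        return np.array([lookup[g] for g in ids], dtype=int)

    # -- subsetting -----------------------------------------------------
    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.values.tocsr()[idx, :].tocsc(),
            [self.gene_ids[i] for i in idx],
            list(self.cell_ids),
        )

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.cell_ids[i] for i in idx],
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class CellAnnotation:
    """Per-cell ground-truth labels used by the evaluation tasks."""

    cell_ids: list[str]
    cell_type: Optional[np.ndarray] = None
    time: Optional[np.ndarray] = None
    branch: Optional[np.ndarray] = None
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_list(self.cell_ids)
        n = len(self.cell_ids)
        for name in ("cell_type", "time", "branch", "quality"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != n:
                    raise ValueError(f"{name} length {v.shape[0]} != n_cells {n}")
                setattr(self, name, v)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, idx: np.ndarray) -> "CellAnnotation":
        idx = np.asarray(idx)
        def take(v):
            return None if v is None else v[idx]
        return CellAnnotation(
            [self.cell_ids[i] for i in idx],
            cell_type=take(self.cell_type),
            time=take(self.time),
            branch=take(self.branch),
            quality=take(self.quality),
        )
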