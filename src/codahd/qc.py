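"""Quality-control filtering and highly-variable-gene selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import scipy.sparse as sp

from .matrix import CountMatrix
from .transforms import LogNormMatrix, LogRatioMatrix

__all__ = ["QCParams", "FilterReport", "filter_cells", "filter_genes", "select_hvg"]


@dataclass(frozen=True)
class QCParams:
    """Thresholds for cell/gene filtering.

    Cells expressing fewer than ``min_genes_per_cell`` genes are dropped,
    then cells whose log1p total counts, log1p detected genes, or
    mitochondrial percentage lie more than ``outlier_mads``
    median-absolute-deviations from the median (upper side only for the
    mitochondrial fraction). Genes detected in fewer than
    ``min_cells_per_gene`` cells are dropped.
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 10
    mt_prefix: str = "MT-"
    outlier_mads: float = 3.0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("thresholds must be non-negative")
        if self.outlier_mads <= 0:
            raise ValueError("outlier_mads must be positive")


@dataclass
class FilterReport:
    """Removed cells and the reason each was removed."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def add(self, cell_id: str, reason: str) -> None:
        self.removed.append((cell_id, reason))

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_dict(self) -> dict:
        return {"n_removed": self.n_removed, "removed": [list(r) for r in self.removed]}


def percent_mitochondrial(X: CountMatrix, mt_prefix: str = "MT-") -> np.ndarray:
    """Percentage (0-100) of each cell's counts on mt-prefixed genes."""
    mask = np.array([g.startswith(mt_prefix) for g in X.gene_ids])
    S = X.cell_totals()
    if not mask.any():
        return np.zeros(X.n_cells)
    mt = np.asarray(X.values[mask, :].sum(axis=0)).ravel()
    out = np.zeros(X.n_cells)
    nz = S > 0
    out[nz] = 100.0 * mt[nz] / S[nz]
    return out


def _mad_outliers(x: np.ndarray, nmads: float, upper_only: bool = False) -> np.ndarray:
    if not np.isfinite(nmads):
        return np.zeros(x.size, dtype=bool)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros(x.size, dtype=bool)
    hi = x > med + nmads * mad
    if upper_only:
        return hi
    return hi | (x < med - nmads * mad)


def filter_cells(X: CountMatrix, p: QCParams) -> tuple[CountMatrix, FilterReport]:
    """Drop low-complexity cells, then MAD-outlier cells.

    The outlier medians are computed after the low-complexity cells are
    removed, so a flood of near-empty cells cannot mask true outliers.
    """
    report = FilterReport()
    n_feat = X.genes_per_cell()
    keep = n_feat >= p.min_genes_per_cell
    for i in np.where(~keep)[0]:
        report.add(X.cell_ids[i], f"detected_genes {n_feat[i]} < {p.min_genes_per_cell}")
    idx = np.where(keep)[0]
    if idx.size == 0:
        raise ValueError("all cells removed by min_genes_per_cell filter")
    sub = X.subset_cells(idx)

    log_counts = np.log1p(sub.cell_totals())
    log_feats = np.log1p(sub.genes_per_cell())
    pct_mt = percent_mitochondrial(sub, p.mt_prefix)
    out = (
        _mad_outliers(log_counts, p.outlier_mads)
        | _mad_outliers(log_feats, p.outlier_mads)
        | _mad_outliers(pct_mt, p.outlier_mads, upper_only=True)
    )
    for i in np.where(out)[0]:
        report.add(sub.cell_ids[i], f"{p.outlier_mads}-MAD outlier (counts/features/pct_mt)")
    idx2 = np.where(~out)[0]
    if idx2.size == 0:
        raise ValueError("all cells removed by MAD outlier filter")
    return sub.subset_cells(idx2), report


def filter_genes(X: CountMatrix, p: QCParams) -> CountMatrix:
    """Drop genes detected in fewer than ``min_cells_per_gene`` cells."""
    n_cells = X.cells_per_gene()
    keep = np.where(n_cells >= p.min_cells_per_gene)[0]
    if keep.size == 0:
        raise ValueError("all genes removed by min_cells_per_gene filter")
    return X.subset_genes(keep)


def select_hvg(
    M: Union[LogRatioMatrix, LogNormMatrix],
    n: int = 3000,
) -> list[str]:
    """Top-n genes by per-gene variance of the transformed matrix.

    Ties broken by gene id, lexicographically smaller first, so the
    selection is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(M, LogRatioMatrix):
        ids = M.component_ids
        V = M.values
        var = V.var(axis=1)
    else:
        ids = M.gene_ids
        V = M.values
        if sp.issparse(V):
            mean = np.asarray(V.mean(axis=1)).ravel()
            sq = np.asarray(V.multiply(V).mean(axis=1)).ravel()
            var = sq - mean**2
        else:
            var = np.asarray(V).var(axis=1)
    if n > len(ids):
        raise ValueError(f"requested {n} genes but matrix has {len(ids)}")
    order = sorted(range(len(ids)), key=lambda i: (-var[i], ids[i]))
    return [ids[i] for i in order[:n]]
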