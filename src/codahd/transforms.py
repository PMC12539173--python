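"""Count-addition schemes and log-ratio transformations for sparse counts.

All transforms operate in log space and never materialize a dense
genes x cells intermediate unless the output itself is that large.
Natural logarithms throughout; the log-normalization/CLR equivalence
only holds with a consistent log base.

Key fact exploited for sparsity: with a per-cell offset ``delta_j`` every
zero entry of cell ``j`` contributes the same term ``log(delta_j)``, so
per-cell log-means cost O(nnz + N) rather than O(D * N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .matrix import CountMatrix

__all__ = [
    "CountAdditionScheme",
    "LogRatioMatrix",
    "LogNormMatrix",
    "DEFAULT_HOUSEKEEPING",
    "compute_cell_offsets",
    "clr",
    "ilr",
    "hkglr",
    "lognormalize",
    "clr_from_lognorm",
]

#: Default housekeeping panel for the housekeeping-gene log-ratio.
DEFAULT_HOUSEKEEPING = ("SDHA", "ACTB", "UBC", "YWHAZ", "GAPDH")

_SCHEME_KINDS = ("constant", "s10000", "smax", "sgm", "half_min")


@dataclass(frozen=True)
class CountAdditionScheme:
    """Per-cell positive offset added to raw counts before taking ratios.

    kind
        ``constant``  delta_j = `constant` for every cell.
        ``s10000``    delta_j = S_j / `constant` (default divisor 10000).
        ``smax``      delta_j = S_j / max_k S_k  (maximum offset is 1).
        ``sgm``       delta_j = S_j / GM_k(S_k)  (geometric mean of offsets is 1).
        ``half_min``  zeros only are replaced by half the smallest nonzero
                      count (0.5 for integer counts). Kept for completeness;
                      not recommended — it performs poorly on sparse data.
    constant
        The fixed offset for ``constant`` or the divisor for ``s10000``.
    """

    kind: str = "sgm"
    constant: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}; one of {_SCHEME_KINDS}")
        if self.constant <= 0:
            raise ValueError("scheme constant must be positive")

    # convenience constructors -----------------------------------------
    @classmethod
    def const(cls, c: float = 1.0) -> "CountAdditionScheme":
        return cls("constant", c)

    @classmethod
    def s10000(cls, divisor: float = 10000.0) -> "CountAdditionScheme":
        return cls("s10000", divisor)

    @classmethod
    def smax(cls) -> "CountAdditionScheme":
        return cls("smax")

    @classmethod
    def sgm(cls) -> "CountAdditionScheme":
        return cls("sgm")

    @classmethod
    def half_min(cls) -> "CountAdditionScheme":
        return cls("half_min")


@dataclass
class LogRatioMatrix:
    """Dense transformed matrix: output components x cells."""

    values: np.ndarray
    transform: str  # CLR | ILR | HKGLR | CLR_FROM_LOGNORM
    scheme: Optional[CountAdditionScheme]
    component_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.component_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match component/cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-ratio values must be finite")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_components(self, ids: Sequence[str]) -> "LogRatioMatrix":
        lookup = {g: i for i, g in enumerate(self.component_ids)}
        idx = [lookup[g] for g in ids]
        return LogRatioMatrix(
            self.values[idx, :], self.transform, self.scheme,
            [self.component_ids[i] for i in idx], list(self.cell_ids),
        )

    def astype(self, dtype) -> "LogRatioMatrix":
        return LogRatioMatrix(
            self.values.astype(dtype), self.transform, self.scheme,
            list(self.component_ids), list(self.cell_ids),
        )


@dataclass
class LogNormMatrix:
    """Library-size log-normalized matrix; zeros stay zero (sparse-friendly)."""

    values: Union[sp.spmatrix, np.ndarray]
    scale_factor: float
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        shape = self.values.shape
        if shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# offsets
# ---------------------------------------------------------------------------

def _check_totals(X: CountMatrix) -> np.ndarray:
    S = X.cell_totals()
    bad = np.where(S <= 0)[0]
    if bad.size:
        names = [X.cell_ids[i] for i in bad[:5]]
        raise ValueError(f"cells with zero total counts: {names}")
    return S


def compute_cell_offsets(X: CountMatrix, scheme: CountAdditionScheme) -> np.ndarray:
    """Per-cell offsets delta_j (length N, strictly positive).

    ``half_min`` has no uniform per-cell offset (only zeros are replaced)
    and is rejected here; the transforms handle it internally.
    """
    S = _check_totals(X)
    if scheme.kind == "constant":
        return np.full(X.n_cells, float(scheme.constant))
    if scheme.kind == "s10000":
        return S / scheme.constant
    if scheme.kind == "smax":
        return S / S.max()
    if scheme.kind == "sgm":
        return S / np.exp(np.mean(np.log(S)))
    raise ValueError(f"scheme {scheme.kind!r} does not define per-cell offsets")


def _half_min_value(X: CountMatrix) -> float:
    if X.values.nnz == 0:
        raise ValueError("matrix has no nonzero counts")
    return 0.5 * float(X.values.data.min())


def _entry_columns(M: sp.csc_matrix) -> np.ndarray:
    """Column index of every stored entry of a CSC matrix."""
    return np.repeat(np.arange(M.shape[1]), np.diff(M.indptr))


def _log_shifted_data(X: CountMatrix, scheme: CountAdditionScheme):
    """Sparse log-transform machinery shared by CLR/ILR/HKGLR.

    Returns ``(log_nnz, zero_logval, nnz_cols)`` where ``log_nnz`` holds
    log(x_ij + delta_j) for stored entries (in CSC order), ``zero_logval``
    is the per-cell log value taken by all zero entries, and ``nnz_cols``
    maps stored entries to their cell index.
    """
    M = X.values
    cols = _entry_columns(M)
    if scheme.kind == "half_min":
        _check_totals(X)
        hm = _half_min_value(X)
        log_nnz = np.log(M.data)
        zero_logval = np.full(X.n_cells, np.log(hm))
    else:
        delta = compute_cell_offsets(X, scheme)
        log_nnz = np.log(M.data + delta[cols])
        zero_logval = np.log(delta)
    return log_nnz, zero_logval, cols


def _percell_log_mean(X: CountMatrix, log_nnz, zero_logval, cols) -> np.ndarray:
    """Mean over all D genes of log(x'_ij), per cell, in O(nnz + N)."""
    D, N = X.shape
    nnz_per_cell = X.genes_per_cell()
    sums = np.bincount(cols, weights=log_nnz, minlength=N)
    return (sums + (D - nnz_per_cell) * zero_logval) / D


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def clr(
    X: CountMatrix,
    scheme: CountAdditionScheme,
    genes_out: Optional[Sequence[str]] = None,
) -> LogRatioMatrix:
    """Centered log-ratio of offset counts.

    value_ij = log(x_ij + delta_j) - (1/D) sum_k log(x_kj + delta_j)

    The geometric-mean denominator always runs over *all* D genes, even
    when ``genes_out`` restricts the output rows (some ecosystems center
    on the subset instead — we deliberately do not). With a subset of g
    genes the memory cost is O(nnz + N*g); no D x N dense intermediate
    is allocated.
    """
    if X.n_genes == 0 or X.n_cells == 0:
        raise ValueError("empty count matrix")
    log_nnz, zero_logval, cols = _log_shifted_data(X, scheme)
    mean_log = _percell_log_mean(X, log_nnz, zero_logval, cols)

    if genes_out is None:
        rows = np.arange(X.n_genes)
        ids = list(X.gene_ids)
    else:
        rows = X.gene_index(genes_out)
        ids = [str(g) for g in genes_out]

    # start from the value every zero entry takes, then overwrite nonzeros
    out = np.tile(zero_logval - mean_log, (len(rows), 1))
    csr = X.values.tocsr()[rows, :]
    row_pos = np.repeat(np.arange(len(rows)), np.diff(csr.indptr))
    csr_cols = csr.indices
    if scheme.kind == "half_min":
        csr_log = np.log(csr.data)
    else:
        delta = np.exp(zero_logval)  # delta_j, recovered without recompute
        csr_log = np.log(csr.data + delta[csr_cols])
    out[row_pos, csr_cols] = csr_log - mean_log[csr_cols]
    return LogRatioMatrix(out, "CLR", scheme, ids, list(X.cell_ids))


def _dense_log_shifted(X: CountMatrix, scheme: CountAdditionScheme) -> np.ndarray:
    """Dense D x N log(x'_ij); used where the output is dense anyway."""
    log_nnz, zero_logval, cols = _log_shifted_data(X, scheme)
    L = np.tile(zero_logval, (X.n_genes, 1))
    csr = X.values.tocsr()
    row_pos = np.repeat(np.arange(X.n_genes), np.diff(csr.indptr))
    if scheme.kind == "half_min":
        vals = np.log(csr.data)
    else:
        delta = np.exp(zero_logval)
        vals = np.log(csr.data + delta[csr.indices])
    L[row_pos, csr.indices] = vals
    return L


def ilr(X: CountMatrix, scheme: CountAdditionScheme) -> LogRatioMatrix:
    """Isometric log-ratio (pivot coordinates), D-1 components per cell.

    component_i = sqrt((D-i)/(D-i+1)) *
                  log( x'_i / (prod_{k=i+1..D} x'_k)^(1/(D-i)) )

    Computed from suffix sums of log(x'_ij): O(D) per cell. Gene order
    is input order; permuting genes changes individual coordinates but
    preserves all inter-cell distances (isometry with CLR geometry).
    """
    D = X.n_genes
    if D < 2:
        raise ValueError("ILR requires at least 2 genes")
    L = _dense_log_shifted(X, scheme)
    # suffix[i] = sum_{k>i} L_k (0-based row i)
    suffix = np.cumsum(L[::-1], axis=0)[::-1]
    tail_sum = np.vstack([suffix[1:], np.zeros((1, X.n_cells))])
    i = np.arange(1, D, dtype=float)  # 1-based component index, 1..D-1
    denom = (D - i)[:, None]
    coef = np.sqrt((D - i) / (D - i + 1))[:, None]
    vals = coef * (L[:-1] - tail_sum[:-1] / denom)
    ids = [f"ilr{k}" for k in range(1, D)]
    return LogRatioMatrix(vals, "ILR", scheme, ids, list(X.cell_ids))


def hkglr(
    X: CountMatrix,
    scheme: CountAdditionScheme,
    hkg: Sequence[str] = DEFAULT_HOUSEKEEPING,
) -> LogRatioMatrix:
    """Log-ratio against the geometric mean of a housekeeping panel.

    value_ij = log(x'_ij) - (1/|hkg|) sum_{k in hkg} log(x'_kj)
    """
    hkg = list(hkg)
    if not hkg:
        raise ValueError("housekeeping gene list is empty")
    missing = [g for g in hkg if g not in set(X.gene_ids)]
    if missing:
        raise KeyError(f"housekeeping genes not in matrix: {missing}")
    L = _dense_log_shifted(X, scheme)
    idx = X.gene_index(hkg)
    ref = L[idx, :].mean(axis=0)
    return LogRatioMatrix(L - ref, "HKGLR", scheme, list(X.gene_ids), list(X.cell_ids))


def lognormalize(X: CountMatrix, scale_factor: float = 10000.0) -> LogNormMatrix:
    """log(x_ij * scale / S_j + 1), natural log; zeros map to zeros."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    S = _check_totals(X)
    M = X.values.copy().astype(float)
    cols = _entry_columns(M)
    M.data = np.log1p(M.data * scale_factor / S[cols])
    return LogNormMatrix(M, scale_factor, list(X.gene_ids), list(X.cell_ids))


def clr_from_lognorm(
    LN: LogNormMatrix,
    genes_center: Optional[Sequence[str]] = None,
) -> LogRatioMatrix:
    """Center log-normalized data per cell: yields a CLR representation.

    value_ij = LN_ij - mean_{k in centering set} LN_kj

    With the full gene set this equals ``clr(X, s10000)`` (matching scale
    factor) elementwise — log-normalized public data can be carried into
    the log-ratio framework without the raw counts.
    """
    gene_ids = LN.gene_ids
    if genes_center is None:
        center_idx = np.arange(LN.n_genes)
    else:
        genes_center = list(genes_center)
        if not genes_center:
            raise ValueError("centering gene set is empty")
        lookup = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in genes_center if g not in lookup]
        if missing:
            raise KeyError(f"centering genes not in matrix: {missing}")
        center_idx = np.array([lookup[g] for g in genes_center])

    V = LN.values
    if sp.issparse(V):
        dense = np.asarray(V.todense())
    else:
        dense = np.asarray(V, dtype=float)
    center = dense[center_idx, :].mean(axis=0)
    scheme = CountAdditionScheme.s10000(LN.scale_factor)
    return LogRatioMatrix(
        dense - center, "CLR_FROM_LOGNORM", scheme, list(gene_ids), list(LN.cell_ids)
    )
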