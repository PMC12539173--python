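"""Dimension reduction (exact and truncated SVD of centered log-ratios)
and delegation to standard clustering algorithms."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .matrix import CountMatrix
from .transforms import CountAdditionScheme, LogNormMatrix, LogRatioMatrix, clr

__all__ = ["EmbeddingResult", "lra_exact", "pca_truncated", "cluster_cells"]


@dataclass
class EmbeddingResult:
    """Truncated SVD/PCA output.

    scores
        cells x k coordinates (right singular vectors scaled by the
        singular values).
    loadings
        genes x k left singular vectors.
    """

    scores: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        s = self.singular_values
        if np.any(np.diff(s) > 1e-9 * max(1.0, abs(s[0]))):
            raise ValueError("singular values must be non-increasing")
        if np.any(self.variance_explained < 0) or self.variance_explained.sum() > 1 + 1e-8:
            raise ValueError("variance_explained must be fractions summing to <= 1")

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, c]))
        if U[i, c] < 0:
            U[:, c] *= -1
            V[:, c] *= -1
    return U, V


def _embed_from_svd(U, s, Vt, total_var, cell_ids) -> EmbeddingResult:
    order = np.argsort(s)[::-1]
    U, s, V = U[:, order], s[order], Vt.T[:, order]
    U, V = _fix_signs(U, V)
    return EmbeddingResult(
        scores=V * s,
        loadings=U,
        singular_values=s,
        variance_explained=(s**2) / total_var if total_var > 0 else np.zeros_like(s),
        cell_ids=list(cell_ids),
    )


def _center_rows(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=1, keepdims=True)


def lra_exact(X: CountMatrix, scheme: CountAdditionScheme, k: int) -> EmbeddingResult:
    """Log-ratio analysis by full SVD of the double-centered CLR matrix.

    Exactness oracle for :func:`pca_truncated` — use on small matrices
    only (full dense SVD).
    """
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(D, N)={min(X.shape)}")
    M = clr(X, scheme)
    A = _center_rows(M.values)  # CLR already sums to 0 per cell; this double-centers
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    total = float((s**2).sum())
    return _embed_from_svd(U[:, :k], s[:k], Vt[:k, :], total, X.cell_ids)


def pca_truncated(
    M: Union[LogRatioMatrix, LogNormMatrix, np.ndarray],
    k: int = 10,
    seed: int = 0,
    cell_ids=None,
) -> EmbeddingResult:
    """Per-gene mean centering followed by truncated SVD (Lanczos).

    Deterministic given ``seed`` (fixed Lanczos starting vector).
    Accepts a log-ratio matrix, a log-normalized matrix, or a plain
    genes x cells array.
    """
    if isinstance(M, LogRatioMatrix):
        A, ids = M.values, M.cell_ids
    elif isinstance(M, LogNormMatrix):
        A = M.values
        if sp.issparse(A):
            A = np.asarray(A.todense())
        ids = M.cell_ids
    else:
        A = np.asarray(M, dtype=float)
        ids = cell_ids if cell_ids is not None else [str(i) for i in range(A.shape[1])]
    if not np.all(np.isfinite(A)):
        raise ValueError("input contains non-finite values")
    if k >= min(A.shape):
        raise ValueError(f"k={k} must be < min(genes, cells)={min(A.shape)}")
    A = _center_rows(np.asarray(A, dtype=float))
    total = float((A**2).sum())
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(A.shape))
    U, s, Vt = svds(A, k=k, v0=v0)
    return _embed_from_svd(U, s, Vt, total, ids)


def cluster_cells(
    E: EmbeddingResult,
    n_clusters: int,
    algorithm: str = "kmeans",
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells on their PC scores; labels 0..K-1, reproducible.

    ``kmeans`` uses 10 restarts; ``graph`` builds a 15-nearest-neighbour
    graph and runs Leiden, scanning the resolution to hit ``n_clusters``
    (requires python-igraph + leidenalg).
    """
    n_cells = E.scores.shape[0]
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_cells < n_clusters:
        raise ValueError(f"{n_cells} cells < {n_clusters} clusters")
    if algorithm == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        return km.fit_predict(E.scores)
    if algorithm == "graph":
        return _leiden_fixed_k(E.scores, n_clusters, seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _leiden_fixed_k(scores: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    k = min(15, scores.shape[0] - 1)
    adj = kneighbors_graph(scores, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    g = igraph.Graph(
        n=scores.shape[0],
        edges=list(zip(adj.row.tolist(), adj.col.tolist())),
        directed=False,
    ).simplify()

    def run(res):
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
        )
        return np.array(part.membership)

    lo, hi = 1e-3, 10.0
    best = run(1.0)
    for _ in range(30):
        mid = np.sqrt(lo * hi)
        lab = run(mid)
        kk = len(np.unique(lab))
        if abs(kk - n_clusters) < abs(len(np.unique(best)) - n_clusters):
            best = lab
        if kk == n_clusters:
            return lab
        if kk < n_clusters:
            lo = mid
        else:
            hi = mid
    return best
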