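"""Desk-scale simulation benchmarks comparing transform pipelines.

These reproduce, at reduced size, the head-to-head protocol used for the
evaluation tasks: simulate grouped counts with dropout, run each
transform through the shared HVG -> truncated PCA -> k-means protocol,
and score agreement with the ground truth.
"""

from __future__ import annotations

import numpy as np

from .dimred import cluster_cells, pca_truncated
from .matrix import CellAnnotation, CountMatrix
from .metrics import adjusted_rand_index
from .qc import select_hvg
from .simulate import SimParams, simulate_counts, spike_degraded
from .transforms import CountAdditionScheme, LogRatioMatrix
from .pipeline import transform_counts

__all__ = [
    "default_benchmark_params",
    "embed_counts",
    "pipeline_ari",
    "clustering_benchmark",
    "degraded_benchmark",
]


def default_benchmark_params(seed: int, n_genes: int = 2000, n_cells: int = 600) -> SimParams:
    """Moderate-difficulty 3-group dropout regime used by the benchmarks."""
    return SimParams(
        n_genes=n_genes,
        n_cells=n_cells,
        de_prob=0.1,
        de_factor_logmean=0.3,
        de_factor_logsd=0.4,
        libsize_logmean=float(np.log(1500)),
        libsize_logsd=0.35,
        dropout_midpoint=0.5,
        dropout_shape=-1.0,
        seed=seed,
    )


def embed_counts(
    X: CountMatrix,
    transform: str,
    scheme: CountAdditionScheme,
    seed: int,
    hvg: int = 3000,
    n_pcs: int = 10,
):
    """Shared protocol: transform -> HVG on the transformed matrix -> PCA."""
    M = transform_counts(X, transform, scheme)
    if isinstance(M, LogRatioMatrix):
        n = min(hvg, M.n_components)
        sub = M.subset_components(select_hvg(M, n))
    else:
        n = min(hvg, M.n_genes)
        genes = select_hvg(M, n)
        if n < M.n_genes:
            import scipy.sparse as sp

            from .transforms import LogNormMatrix

            lookup = {g: i for i, g in enumerate(M.gene_ids)}
            idx = [lookup[g] for g in genes]
            vals = M.values.tocsr()[idx, :] if sp.issparse(M.values) else M.values[idx, :]
            sub = LogNormMatrix(vals, M.scale_factor, genes, list(M.cell_ids))
        else:
            sub = M
    return pca_truncated(sub, k=n_pcs, seed=seed)


def pipeline_ari(
    X: CountMatrix,
    truth_labels: np.ndarray,
    transform: str,
    scheme: CountAdditionScheme,
    seed: int,
) -> float:
    E = embed_counts(X, transform, scheme, seed)
    labels = cluster_cells(E, len(np.unique(truth_labels)), "kmeans", seed)
    return adjusted_rand_index(labels, truth_labels)


def clustering_benchmark(seed: int, n_genes: int = 2000, n_cells: int = 600) -> dict:
    """k-means ARI of SGM-CLR, constant-addition CLR (+1) and log
    normalization on one simulated dropout dataset."""
    X, truth = simulate_counts(default_benchmark_params(seed, n_genes, n_cells))
    g = truth.group
    return {
        "sgm_clr": pipeline_ari(X, g, "clr", CountAdditionScheme.sgm(), seed),
        "p1_clr": pipeline_ari(X, g, "clr", CountAdditionScheme.const(1.0), seed),
        "lognorm": pipeline_ari(X, g, "lognorm", CountAdditionScheme.sgm(), seed),
    }


def degraded_benchmark(
    seed: int,
    n_genes: int = 2000,
    n_cells: int = 600,
    cell_fraction: float = 0.10,
    zero_fraction: float = 0.60,
) -> dict:
    """ARI for separating degraded spike-in copies from their originals.

    The whole spiked dataset is embedded under each transform; 2-means on
    the target-type subset of the embedding is scored against the
    original-vs-degraded truth.
    """
    from sklearn.cluster import KMeans

    X, truth = simulate_counts(default_benchmark_params(seed, n_genes, n_cells))
    ann = CellAnnotation(X.cell_ids, cell_type=truth.group.astype(object))
    X2, ann2 = spike_degraded(
        X, ann, "Group1", cell_fraction=cell_fraction,
        zero_fraction=zero_fraction, seed=seed,
    )
    mask = np.isin(ann2.cell_type, ["Group1", "Group1-zero"])
    sub_truth = (ann2.cell_type[mask] == "Group1-zero").astype(int)

    out = {}
    for key, transform, scheme in (
        ("sgm_clr", "clr", CountAdditionScheme.sgm()),
        ("lognorm", "lognorm", CountAdditionScheme.sgm()),
    ):
        E = embed_counts(X2, transform, scheme, seed)
        labels = KMeans(2, n_init=10, random_state=seed).fit_predict(E.scores[mask])
        out[key] = adjusted_rand_index(labels, sub_truth)
    return out
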