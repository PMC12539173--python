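"""Synthetic scRNA-seq generator with ground truth, and the degraded-cell
spike-in procedure.

The generator follows the familiar gamma-Poisson recipe: gamma gene base
means, per-group log-normal differential-expression factors, log-normal
library sizes, Poisson emission, then logistic dropout on log(mu + 1).
Both the observed (dropout) matrix and the pre-dropout truth matrix are
returned so that transforms can be benchmarked against a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .matrix import CellAnnotation, CountMatrix

__all__ = ["SimParams", "SimTruth", "simulate_counts", "spike_degraded", "select_truth_markers"]

# substream labels: one child seed per stage so that, e.g., changing the
# number of cells never perturbs the gene-level draws
_STAGES = ("gene_means", "de", "groups", "libsize", "poisson", "dropout")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the gamma-Poisson / logistic-dropout generator."""

    n_genes: int = 10000
    n_cells: int = 1500
    group_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_logmean: float = 9.0
    libsize_logsd: float = 0.35
    de_prob: float = 0.1
    de_factor_logmean: float = 0.1
    de_factor_logsd: float = 0.4
    dropout_midpoint: float = 1.0
    dropout_shape: float = -1.0
    dropout: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.group_proportions, dtype=float)
        if props.ndim != 1 or props.size == 0 or np.any(props < 0):
            raise ValueError("group_proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("group_proportions must sum to 1")
        if not (0.0 <= self.de_prob <= 1.0):
            raise ValueError("de_prob must be in [0, 1]")
        for name in ("mean_shape", "mean_rate", "libsize_logsd", "de_factor_logsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated count matrix."""

    group: np.ndarray  # label per cell
    group_names: list[str]
    de_factors: np.ndarray  # genes x groups multiplicative factors (1 = not DE)
    dropped: sp.csc_matrix  # boolean mask of entries zeroed by dropout
    no_dropout_counts: CountMatrix
    library_sizes: np.ndarray

    def de_genes(self, group: str) -> dict[str, float]:
        """Genes DE in ``group`` with their factors."""
        g = self.group_names.index(group)
        ids = self.no_dropout_counts.gene_ids
        col = self.de_factors[:, g]
        return {ids[i]: float(col[i]) for i in np.where(col != 1.0)[0]}


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STAGES))
    return {name: np.random.default_rng(c) for name, c in zip(_STAGES, children)}


def simulate_counts(p: SimParams) -> tuple[CountMatrix, SimTruth]:
    """Draw a (dropout, truth) pair of count matrices with group labels.

    Expected count for gene i in cell j of group g:
        mu_ij = L_j * lambda_i f_{i,g} / sum_k lambda_k f_{k,g}
    Counts are Poisson(mu); dropout zeroes each positive entry with
    probability expit(shape * (log(mu + 1) - midpoint)).
    """
    rngs = _stage_rngs(p.seed)
    D, N = p.n_genes, p.n_cells
    G = len(p.group_proportions)

    lam = rngs["gene_means"].gamma(p.mean_shape, 1.0 / p.mean_rate, size=D)
    lam = np.maximum(lam, 1e-12)

    de_rng = rngs["de"]
    factors = np.ones((D, G))
    for g in range(G):
        is_de = de_rng.random(D) < p.de_prob
        mags = np.exp(de_rng.normal(p.de_factor_logmean, p.de_factor_logsd, size=D))
        up = de_rng.random(D) < 0.5
        f = np.where(up, mags, 1.0 / mags)
        factors[:, g] = np.where(is_de, f, 1.0)

    props = np.asarray(p.group_proportions, dtype=float)
    group_idx = rngs["groups"].choice(G, size=N, p=props / props.sum())
    L = np.exp(rngs["libsize"].normal(p.libsize_logmean, p.libsize_logsd, size=N))

    profile = lam[:, None] * factors  # D x G
    profile = profile / profile.sum(axis=0, keepdims=True)
    mu = profile[:, group_idx] * L[None, :]
    if not np.all(mu.sum(axis=0) > 0):
        raise ValueError("degenerate parameters: zero expected library size")

    counts_true = rngs["poisson"].poisson(mu).astype(np.int64)

    if p.dropout:
        p_drop = expit(p.dropout_shape * (np.log(mu + 1.0) - p.dropout_midpoint))
        keep = rngs["dropout"].random(mu.shape) >= p_drop
    else:
        keep = np.ones(mu.shape, dtype=bool)
    counts_obs = np.where(keep, counts_true, 0)
    dropped = (~keep) & (counts_true > 0)

    gene_ids = [f"Gene{i + 1}" for i in range(D)]
    cell_ids = [f"Cell{j + 1}" for j in range(N)]
    group_names = [f"Group{g + 1}" for g in range(G)]
    groups = np.array([group_names[g] for g in group_idx])

    X = CountMatrix(sp.csc_matrix(counts_obs), gene_ids, cell_ids)
    truth = SimTruth(
        group=groups,
        group_names=group_names,
        de_factors=factors,
        dropped=sp.csc_matrix(dropped),
        no_dropout_counts=CountMatrix(sp.csc_matrix(counts_true), gene_ids, cell_ids),
        library_sizes=L,
    )
    return X, truth


def spike_degraded(
    X: CountMatrix,
    ann: CellAnnotation,
    target_type: str,
    cell_fraction: float = 0.10,
    zero_fraction: float = 0.60,
    seed: int = 0,
) -> tuple[CountMatrix, CellAnnotation]:
    """Append zero-inflated copies of cells of one type.

    round(cell_fraction * n_type) cells of ``target_type`` are copied;
    in each copy an independent uniform-random ``zero_fraction`` of genes
    is set to zero. Copies are appended as new cells labeled
    ``<target_type>-zero``; the original cells are untouched.
    """
    if ann.cell_type is None:
        raise ValueError("annotation lacks cell_type labels")
    if not (0.0 < cell_fraction < 1.0) or not (0.0 < zero_fraction < 1.0):
        raise ValueError("fractions must lie in (0, 1)")
    idx_type = np.where(ann.cell_type == target_type)[0]
    if idx_type.size == 0:
        raise ValueError(f"no cells of type {target_type!r}")
    n_copy = int(round(cell_fraction * idx_type.size))
    if n_copy < 1:
        raise ValueError(
            f"cell_fraction {cell_fraction} selects no cells "
            f"(type has {idx_type.size})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx_type, size=n_copy, replace=False)

    D = X.n_genes
    n_zero = int(round(zero_fraction * D))
    cols = []
    for j in chosen:
        col = X.values[:, j].toarray().ravel()
        zero_rows = rng.choice(D, size=n_zero, replace=False)
        col[zero_rows] = 0
        cols.append(col)
    extra = sp.csc_matrix(np.column_stack(cols))

    new_ids = [f"{X.cell_ids[j]}-zero{k + 1}" for k, j in enumerate(chosen)]
    new_values = sp.hstack([X.values, extra]).tocsc()
    out = CountMatrix(new_values, list(X.gene_ids), list(X.cell_ids) + new_ids)

    def extend(v, fill):
        if v is None:
            return None
        return np.concatenate([v, np.full(n_copy, fill, dtype=v.dtype if v.dtype.kind != "U" else object)])

    new_type = np.concatenate(
        [np.asarray(ann.cell_type, dtype=object), [f"{target_type}-zero"] * n_copy]
    )
    new_ann = CellAnnotation(
        out.cell_ids,
        cell_type=new_type,
        time=extend(ann.time, np.nan) if ann.time is not None else None,
        branch=None if ann.branch is None else np.concatenate(
            [np.asarray(ann.branch, dtype=object), ["degraded"] * n_copy]
        ),
        quality=np.concatenate(
            [np.ones(ann.n_cells, dtype=bool), np.zeros(n_copy, dtype=bool)]
        ),
    )
    return out, new_ann


def select_truth_markers(
    truth: SimTruth,
    group_a: str,
    group_b: str,
    n_top: int = 10,
    n_null: int = 50,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Top DE genes between two groups and a random panel of non-DE genes.

    DEGs are ranked by |log(f_a / f_b)| (descending); the null panel is
    drawn uniformly from genes DE in neither group. The two lists never
    intersect by construction.
    """
    for g in (group_a, group_b):
        if g not in truth.group_names:
            raise KeyError(f"unknown group {g!r}")
    ia = truth.group_names.index(group_a)
    ib = truth.group_names.index(group_b)
    fa = truth.de_factors[:, ia]
    fb = truth.de_factors[:, ib]
    ratio = np.abs(np.log(fa) - np.log(fb))
    ids = truth.no_dropout_counts.gene_ids

    de_idx = np.where(ratio > 0)[0]
    if de_idx.size < n_top:
        raise ValueError(f"only {de_idx.size} DE genes available, need {n_top}")
    order = sorted(de_idx, key=lambda i: (-ratio[i], i))
    degs = [ids[i] for i in order[:n_top]]

    null_idx = np.where((fa == 1.0) & (fb == 1.0))[0]
    if null_idx.size < n_null:
        raise ValueError(f"only {null_idx.size} non-DE genes available, need {n_null}")
    rng = np.random.default_rng(seed)
    nulls = [ids[i] for i in rng.choice(null_idx, size=n_null, replace=False)]
    return degs, nulls
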