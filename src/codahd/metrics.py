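"""Evaluation statistics for clustering, trajectory, and biomarker tasks.

Entropy/NMI formulas use natural logarithms. Lower entropy-of-accuracy
and entropy-of-purity indicate better clustering; higher ARI/NMI, SCC,
POS and AUROC indicate better performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata, spearmanr

__all__ = [
    "entropy_accuracy",
    "entropy_purity",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "pseudotime_scc",
    "pseudotime_pos",
    "BranchMatch",
    "branch_overlap_rates",
    "match_branches",
    "marker_auc",
    "marker_panel_report",
    "clustering_report",
    "baseline_delta",
]


def _check_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("empty partition")
    if pred.shape != truth.shape:
        raise ValueError(
            f"partitions cover different cell sets: {pred.shape} vs {truth.shape}"
        )
    return pred, truth


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Counts C[i, j] = #cells in predicted cluster i and true group j."""
    pi, pinv = np.unique(pred, return_inverse=True)
    ti, tinv = np.unique(truth, return_inverse=True)
    C = np.zeros((pi.size, ti.size), dtype=np.int64)
    np.add.at(C, (pinv, tinv), 1)
    return C


def _mean_row_entropy(C: np.ndarray) -> float:
    """(sum of within-row entropies) / number of rows, natural log."""
    tot = C.sum(axis=1, keepdims=True).astype(float)
    P = C / np.where(tot == 0, 1, tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return float(-terms.sum() / C.shape[0])


def entropy_accuracy(pred, truth) -> float:
    """Entropy of the true-group mixture within each predicted cluster,
    averaged over the M predicted clusters; in [0, log M]."""
    pred, truth = _check_pair(pred, truth)
    return _mean_row_entropy(_contingency(pred, truth))


def entropy_purity(pred, truth) -> float:
    """Entropy of the predicted-cluster mixture within each true group,
    averaged over the N true groups; in [0, log N]."""
    pred, truth = _check_pair(pred, truth)
    return _mean_row_entropy(_contingency(truth, pred))


def adjusted_rand_index(pred, truth) -> float:
    """Pair-counting adjusted Rand index from the contingency table."""
    pred, truth = _check_pair(pred, truth)
    C = _contingency(pred, truth)
    n = C.sum()
    if n < 2:
        raise ValueError("need at least 2 cells")

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(C).sum()
    a = comb2(C.sum(axis=1)).sum()
    b = comb2(C.sum(axis=0)).sum()
    expected = a * b / comb2(n)
    max_index = 0.5 * (a + b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def normalized_mutual_information(pred, truth) -> float:
    """NMI = 2 I(G, Ghat) / (H(G) + H(Ghat)), natural log."""
    pred, truth = _check_pair(pred, truth)
    C = _contingency(pred, truth).astype(float)
    n = C.sum()
    P = C / n
    pa = P.sum(axis=1)
    pb = P.sum(axis=0)
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if ha + hb == 0:
        # both single-cluster: identical by construction
        return 1.0
    outer = np.outer(pa, pb)
    nz = P > 0
    mi = float(np.sum(P[nz] * np.log(P[nz] / outer[nz])))
    return float(2.0 * mi / (ha + hb))


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def pseudotime_scc(pred_pseudotime, true_time) -> float:
    """Spearman rank correlation (midrank ties) between predicted
    pseudotime and the ground-truth time labels."""
    pt = np.asarray(pred_pseudotime, dtype=float)
    tt = np.asarray(true_time, dtype=float)
    if pt.shape != tt.shape:
        raise ValueError("pseudotime and truth cover different cell sets")
    if pt.size < 3:
        raise ValueError("need at least 3 cells")
    if np.unique(tt).size < 2:
        raise ValueError("true time must take at least 2 distinct values")
    if np.unique(pt).size < 2:
        raise ValueError("constant pseudotime: correlation undefined")
    rho = spearmanr(pt, tt).statistic
    return float(rho)


def pseudotime_pos(pred_pseudotime, true_time) -> float:
    """Pairwise ordering concordance score in [-1, 1].

    Over all cell pairs with different true time labels: +1 if the
    predicted pseudotime orders them the same way, -1 if reversed, 0 if
    predicted tied; the score is the mean over comparable pairs.
    """
    pt = np.asarray(pred_pseudotime, dtype=float)
    tt = np.asarray(true_time, dtype=float)
    if pt.shape != tt.shape:
        raise ValueError("pseudotime and truth cover different cell sets")
    dt = np.sign(tt[:, None] - tt[None, :])
    dp = np.sign(pt[:, None] - pt[None, :])
    comparable = dt != 0
    iu = np.triu_indices(pt.size, k=1)
    mask = comparable[iu]
    if not mask.any():
        raise ValueError("no cell pairs with different true times")
    concord = (dt[iu][mask] * dp[iu][mask])
    return float(concord.sum() / mask.sum())


@dataclass
class BranchMatch:
    """Branch assignment agreement between predicted and true lineages."""

    mapping: dict  # predicted branch label -> matched true branch label
    true_overlap_rate: dict  # predicted branch -> |pred ∩ true| / |true|
    overlap_rates: dict  # predicted branch -> {true branch -> rate}
    trajectory_false_rate: float
    incorrect_cell_type_proportion: float


def _branch_masks(branches, n_cells: Optional[int] = None) -> dict:
    """Normalize branch input to {label: boolean mask}.

    Accepts a per-cell label array (a partition) or a mapping of branch
    label -> boolean mask / index array. The mapping form allows branches
    to overlap, as lineages do (a progenitor type belongs to every
    lineage passing through it).
    """
    if isinstance(branches, dict):
        masks = {}
        for label, sel in branches.items():
            sel = np.asarray(sel)
            if sel.dtype == bool:
                masks[label] = sel
            else:
                if n_cells is None:
                    raise ValueError("index-array branches need n_cells")
                m = np.zeros(n_cells, dtype=bool)
                m[sel] = True
                masks[label] = m
        sizes = {m.size for m in masks.values()}
        if len(sizes) > 1:
            raise ValueError("branch masks have inconsistent lengths")
        return masks
    arr = np.asarray(branches)
    return {label: arr == label for label in np.unique(arr)}


def branch_overlap_rates(pred_branches, true_branches, n_cells=None) -> dict:
    """Overlap rate |pred ∩ true| / |true| for every (pred, true) pair."""
    pred = _branch_masks(pred_branches, n_cells)
    truth = _branch_masks(true_branches, n_cells)
    out: dict = {}
    for p, pm in pred.items():
        out[p] = {
            t: float((pm & tm).sum() / tm.sum()) if tm.sum() else 0.0
            for t, tm in truth.items()
        }
    return out


def match_branches(pred_branches, true_branches, n_cells=None) -> BranchMatch:
    """Match each predicted branch to the true branch with the largest
    cell overlap (ties: larger true branch, then label order).

    Either side may be a label array (partition) or a mapping of branch
    label -> cell mask, which permits overlapping lineage branches.
    Reported per matched pair (pred p -> true t):
      * true overlap rate = |p ∩ t| / |t|
      * trajectory false rate = mean fraction of t's cells found in
        predicted branches other than p
      * incorrect cell type proportion = mean fraction of p's cells that
        are not in t
    """
    pred = _branch_masks(pred_branches, n_cells)
    truth = _branch_masks(true_branches, n_cells)
    if not pred or not truth:
        raise ValueError("need at least one predicted and one true branch")
    for label, m in {**pred, **truth}.items():
        if not m.any():
            raise ValueError(f"branch {label!r} is empty")
    true_sizes = {t: int(m.sum()) for t, m in truth.items()}

    mapping: dict = {}
    overlap_rate: dict = {}
    rates = branch_overlap_rates(pred, truth)
    false_rates = []
    incorrect = []
    for p, pm in pred.items():
        overlaps = {t: int((pm & tm).sum()) for t, tm in truth.items()}
        best = sorted(
            truth, key=lambda t: (-overlaps[t], -true_sizes[t], str(t))
        )[0]
        mapping[p] = best
        ov = overlaps[best]
        overlap_rate[p] = ov / true_sizes[best]
        others = np.zeros(pm.size, dtype=bool)
        for q, qm in pred.items():
            if q != p:
                others |= qm
        false_rates.append(float((truth[best] & others).sum() / true_sizes[best]))
        incorrect.append((int(pm.sum()) - ov) / int(pm.sum()))

    return BranchMatch(
        mapping=mapping,
        true_overlap_rate=overlap_rate,
        overlap_rates=rates,
        trajectory_false_rate=float(np.mean(false_rates)),
        incorrect_cell_type_proportion=float(np.mean(incorrect)),
    )


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

def marker_auc(values, positive) -> float:
    """Rank-based (Mann-Whitney) AUROC with midrank tie handling."""
    v = np.asarray(values, dtype=float)
    pos = np.asarray(positive, dtype=bool)
    if v.shape != pos.shape:
        raise ValueError("values and labels have different lengths")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(v)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def marker_panel_report(
    auc_table: dict,
    cutoffs: Sequence[float] = (0.6, 0.75, 0.9),
    nondeg_auc_table: Optional[dict] = None,
) -> dict:
    """Fractions of marker genes with AUC above each cutoff; optionally
    the same fractions for known non-markers (false-positive rates)."""
    if not auc_table:
        raise ValueError("empty AUC table")
    aucs = np.array(list(auc_table.values()), dtype=float)
    report = {
        "n_markers": int(aucs.size),
        "frac_above": {str(c): float((aucs > c).mean()) for c in cutoffs},
    }
    if nondeg_auc_table:
        null_aucs = np.array(list(nondeg_auc_table.values()), dtype=float)
        report["n_non_markers"] = int(null_aucs.size)
        report["false_positive_frac"] = {
            str(c): float((null_aucs > c).mean()) for c in cutoffs
        }
    return report


# ---------------------------------------------------------------------------
# aggregate reporting
# ---------------------------------------------------------------------------

def clustering_report(pred, truth) -> dict:
    """All four clustering metrics as a flat dict."""
    return {
        "H_acc": entropy_accuracy(pred, truth),
        "H_pur": entropy_purity(pred, truth),
        "ARI": adjusted_rand_index(pred, truth),
        "NMI": normalized_mutual_information(pred, truth),
    }


#: metrics where smaller is better (baseline delta is baseline - method)
_LOWER_BETTER = {"H_acc", "H_pur"}


def baseline_delta(method: dict, baseline: dict) -> dict:
    """Per-metric improvement over a baseline run.

    Higher-is-better metrics report (method - baseline); entropies report
    (baseline - method), so positive deltas always mean improvement.
    """
    out = {}
    for k, v in method.items():
        if k not in baseline:
            continue
        if k in _LOWER_BETTER:
            out[k] = baseline[k] - v
        else:
            out[k] = v - baseline[k]
    return out
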