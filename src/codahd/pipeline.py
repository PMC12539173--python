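"""End-to-end run orchestration: QC -> transform -> HVG -> PCA ->
clustering -> evaluation, with every stage written to disk and logged."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .dimred import cluster_cells, pca_truncated
from .io import (
    read_counts,
    read_labels,
    write_embedding_csv,
    write_json,
    write_labels,
    write_logratio_csv,
)
from .matrix import CountMatrix
from .metrics import baseline_delta, clustering_report
from .qc import QCParams, filter_cells, filter_genes, select_hvg
from .transforms import (
    CountAdditionScheme,
    clr,
    clr_from_lognorm,
    hkglr,
    ilr,
    lognormalize,
)

__all__ = ["RunConfig", "run_pipeline", "transform_counts"]

_TRANSFORMS = ("clr", "ilr", "hkglr", "lognorm-clr", "lognorm")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from scratch."""

    input_path: str
    out_dir: str
    transform: str = "clr"  # clr | ilr | hkglr | lognorm-clr | lognorm
    scheme_kind: str = "sgm"  # constant | s10000 | smax | sgm | half_min
    scheme_constant: float = 1.0
    hvg: int = 3000
    n_pcs: int = 10
    cluster_algorithm: str = "kmeans"
    n_clusters: Optional[int] = None  # default: number of distinct truth labels
    truth_labels: Optional[str] = None  # CSV path
    qc: bool = True
    qc_params: QCParams = field(default_factory=QCParams)
    with_baseline: bool = True
    transpose: bool = False
    seed: int = 0

    def scheme(self) -> CountAdditionScheme:
        if self.scheme_kind == "constant":
            return CountAdditionScheme.const(self.scheme_constant)
        if self.scheme_kind == "s10000":
            return CountAdditionScheme.s10000()
        return CountAdditionScheme(self.scheme_kind)


def transform_counts(X: CountMatrix, transform: str, scheme: CountAdditionScheme):
    """Dispatch a named transform; ``lognorm`` returns the log-normalized
    matrix itself (the conventional baseline), others a log-ratio matrix."""
    if transform == "clr":
        return clr(X, scheme)
    if transform == "ilr":
        return ilr(X, scheme)
    if transform == "hkglr":
        return hkglr(X, scheme)
    if transform == "lognorm-clr":
        return clr_from_lognorm(lognormalize(X))
    if transform == "lognorm":
        return lognormalize(X)
    raise ValueError(f"unknown transform {transform!r}; one of {_TRANSFORMS}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _embed_and_cluster(M, cfg: RunConfig, n_clusters: Optional[int]):
    genes = select_hvg(M, min(cfg.hvg, _n_components(M)))
    from .transforms import LogNormMatrix, LogRatioMatrix

    if isinstance(M, LogRatioMatrix):
        sub = M.subset_components(genes)
    else:
        lookup = {g: i for i, g in enumerate(M.gene_ids)}
        idx = [lookup[g] for g in genes]
        import scipy.sparse as sp

        vals = M.values.tocsr()[idx, :] if sp.issparse(M.values) else M.values[idx, :]
        sub = LogNormMatrix(vals, M.scale_factor, genes, list(M.cell_ids))
    E = pca_truncated(sub, k=cfg.n_pcs, seed=cfg.seed)
    labels = None
    if n_clusters is not None:
        labels = cluster_cells(E, n_clusters, cfg.cluster_algorithm, cfg.seed)
    return E, labels


def _n_components(M) -> int:
    from .transforms import LogRatioMatrix

    return M.n_components if isinstance(M, LogRatioMatrix) else M.n_genes


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the pipeline, write artifacts, return the run report.

    Stages run in fixed order; any failure aborts with the stage name.
    If truth labels are present, clustering is evaluated and (unless
    disabled) the log-normalization baseline is run under the same
    protocol, reporting per-metric deltas with positive = improvement.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {**asdict(cfg), "qc_params": asdict(cfg.qc_params)},
        "stages": [],
        "checksums": {},
        "warnings": [],
    }

    def stage(name):
        log["stages"].append(name)

    try:
        stage("read")
        X = read_counts(cfg.input_path, transpose=cfg.transpose)

        if cfg.qc:
            stage("qc")
            X, report = filter_cells(X, cfg.qc_params)
            X = filter_genes(X, cfg.qc_params)
            log["filter_report"] = report.to_dict()

        truth = None
        n_clusters = cfg.n_clusters
        if cfg.truth_labels:
            stage("truth")
            s = read_labels(cfg.truth_labels)
            missing = [c for c in X.cell_ids if c not in s.index]
            if missing:
                log["warnings"].append(
                    f"{len(missing)} cells lack truth labels; evaluation skipped"
                )
            else:
                truth = s.loc[X.cell_ids].to_numpy()
                if n_clusters is None:
                    n_clusters = int(len(np.unique(truth)))

        stage("transform")
        M = transform_counts(X, cfg.transform, cfg.scheme())
        from .transforms import LogRatioMatrix

        if isinstance(M, LogRatioMatrix):
            write_logratio_csv(M, out / "transformed.csv")
            log["checksums"]["transformed.csv"] = _sha256(out / "transformed.csv")

        stage("embed")
        E, labels = _embed_and_cluster(M, cfg, n_clusters)
        write_embedding_csv(E, out / "embedding.csv")
        log["checksums"]["embedding.csv"] = _sha256(out / "embedding.csv")

        metrics = None
        if labels is not None:
            stage("cluster")
            write_labels(labels, X.cell_ids, out / "clusters.csv", column="cluster")
            log["checksums"]["clusters.csv"] = _sha256(out / "clusters.csv")

        if truth is not None and labels is not None:
            stage("evaluate")
            metrics = clustering_report(labels, truth)
            log["metrics"] = metrics
            if cfg.with_baseline and cfg.transform != "lognorm":
                stage("baseline")
                MB = transform_counts(X, "lognorm", cfg.scheme())
                _, bl = _embed_and_cluster(MB, cfg, n_clusters)
                base = clustering_report(bl, truth)
                log["baseline_metrics"] = base
                log["delta_vs_lognorm"] = baseline_delta(metrics, base)
        elif cfg.truth_labels and truth is None:
            log["warnings"].append("evaluation stages skipped (missing truth labels)")

        write_json(log, out / "run_log.json")
        return log
    except Exception as e:  # noqa: BLE001
        current = log["stages"][-1] if log["stages"] else "init"
        raise RuntimeError(f"pipeline failed at stage {current!r}: {e}") from e
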