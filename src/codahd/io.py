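"""Reading and writing count matrices, transforms, labels, and reports.

Genes are rows everywhere internally (10x MatrixMarket convention).
Gzip is handled transparently for all text formats.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import CountMatrix
from .transforms import LogRatioMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "write_logratio_csv",
    "read_matrix_csv",
    "write_embedding_csv",
    "write_json",
]


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Optional[Path]:
    for name in (stem, stem + ".gz"):
        cand = dirpath / name
        if cand.exists():
            return cand
    return None


def _dedup_ids(ids: list[str]) -> list[str]:
    """Suffix duplicate identifiers deterministically: x, x.1, x.2, ..."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_counts(path: Union[str, Path], transpose: bool = False) -> CountMatrix:
    """Read counts from a 10x MatrixMarket triplet directory or a CSV.

    A directory must contain matrix.mtx, features.tsv (or genes.tsv) and
    barcodes.tsv, each optionally gzipped, with genes as matrix rows. A
    CSV has gene ids in the first column and cell ids in the header; pass
    ``transpose=True`` for a cells x genes CSV. Non-integer values are
    rejected with a clear error.
    """
    path = Path(path)
    if path.is_dir():
        X, gene_ids, cell_ids = _read_mtx_dir(path)
    else:
        X, gene_ids, cell_ids = _read_csv(path)
    if transpose:
        X = X.T
        gene_ids, cell_ids = cell_ids, gene_ids
    gene_ids = _dedup_ids(gene_ids)
    cell_ids = _dedup_ids(cell_ids)
    data = X.tocsc()
    if data.nnz and not np.allclose(data.data, np.round(data.data), atol=1e-8):
        raise ValueError(
            f"{path}: matrix contains non-integer values; raw counts expected"
        )
    return CountMatrix(data, gene_ids, cell_ids)


def _read_mtx_dir(dirpath: Path):
    mtx = _find(dirpath, "matrix.mtx")
    if mtx is None:
        raise FileNotFoundError(f"no matrix.mtx[.gz] in {dirpath}")
    features = _find(dirpath, "features.tsv") or _find(dirpath, "genes.tsv")
    barcodes = _find(dirpath, "barcodes.tsv")
    if features is None or barcodes is None:
        raise FileNotFoundError(f"missing features/barcodes tables in {dirpath}")
    with _open_maybe_gz(mtx, "rb") as fh:
        try:
            M = scipy.io.mmread(fh)
        except Exception as e:  # noqa: BLE001
            raise ValueError(f"malformed MatrixMarket file {mtx}: {e}") from e
    M = sp.csc_matrix(M)
    gene_ids = _read_id_column(features)
    cell_ids = _read_id_column(barcodes)
    if M.shape == (len(gene_ids), len(cell_ids)):
        pass
    elif M.shape == (len(cell_ids), len(gene_ids)):
        M = M.T.tocsc()  # stored cells x genes; normalize orientation
    else:
        raise ValueError(
            f"matrix shape {M.shape} matches neither ({len(gene_ids)} genes, "
            f"{len(cell_ids)} cells) nor its transpose"
        )
    return M, gene_ids, cell_ids


def _read_csv(path: Path):
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    return sp.csc_matrix(values), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_counts(X: CountMatrix, dirpath: Union[str, Path]) -> Path:
    """Write a 10x-style triplet directory (uncompressed text)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    with open(dirpath / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(X.values), field="integer")
    pd.DataFrame({"id": X.gene_ids}).to_csv(
        dirpath / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"id": X.cell_ids}).to_csv(
        dirpath / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return dirpath


def read_labels(path: Union[str, Path], column: Optional[str] = None) -> pd.Series:
    """Read per-cell labels from a CSV with cell ids in the first column."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no label columns")
    col = column if column is not None else df.columns[0]
    if col not in df.columns:
        raise KeyError(f"{path}: no column {col!r}")
    s = df[col]
    s.index = s.index.astype(str)
    return s


def write_labels(labels, cell_ids, path: Union[str, Path], column: str = "label") -> None:
    pd.DataFrame({column: np.asarray(labels)}, index=pd.Index(cell_ids, name="cell_id")).to_csv(path)


def write_logratio_csv(M: LogRatioMatrix, path: Union[str, Path], float32: bool = False) -> None:
    vals = M.values.astype(np.float32) if float32 else M.values
    pd.DataFrame(
        vals, index=pd.Index(M.component_ids, name="component"), columns=M.cell_ids
    ).to_csv(path)


def read_matrix_csv(path: Union[str, Path]):
    """Generic dense matrix CSV (rows labelled, header = cell ids)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_embedding_csv(E, path: Union[str, Path]) -> None:
    cols = {f"PC{i + 1}": E.scores[:, i] for i in range(E.k)}
    pd.DataFrame(cols, index=pd.Index(E.cell_ids, name="cell_id")).to_csv(path)


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
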