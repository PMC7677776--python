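"""Reading and writing expression matrices and run configuration.

Supported on-disk formats: delimited text (CSV/TSV, genes as rows with a
header row of cell IDs and an index column of gene IDs) and MatrixMarket
triplets with ``genes.txt`` / ``cells.txt`` sidecar files. Orientation is
never auto-detected — silent transposition is a classic failure mode — but
an explicit ``transpose`` flag is available.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix

__all__ = ["read_matrix", "write_matrix", "RunConfig"]

_DELIMS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "mtx"):
        return suffix
    if suffix == "txt":
        return "tsv"
    raise ValueError(f"cannot infer format from {path.name}; pass format=")


def read_matrix(path, fmt: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    For MTX the files ``genes.txt`` and ``cells.txt`` (one ID per line) are
    expected next to the matrix file. Negative entries, missing values and
    duplicate identifiers are rejected.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in _DELIMS:
        with open(path) as fh:  # pandas silently renames duplicate columns
            header = fh.readline().rstrip("\n").split(_DELIMS[fmt])[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: cell ids are not unique")
        df = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0)
        if df.isna().any().any():
            raise ValueError(f"{path}: missing or ragged entries")
        values = df.to_numpy(dtype=float)
        gene_ids, cell_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    elif fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        gene_ids = Path(path.parent / "genes.txt").read_text().split()
        cell_ids = Path(path.parent / "cells.txt").read_text().split()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    if np.any(values < 0):
        raise ValueError(f"{path}: negative entries are not valid counts")
    return ExpressionMatrix(values, gene_ids, cell_ids)


def write_matrix(m: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix so that ``read_matrix`` round-trips it exactly.

    CSV/TSV uses full ``repr`` float formatting; MTX writes the dense
    triplet plus the ID sidecars.
    """
    if m.values.size == 0:
        raise ValueError("refusing to write an empty matrix")
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in _DELIMS:
        m.to_dataframe().to_csv(path, sep=_DELIMS[fmt])
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(m.values))
        (path.parent / "genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


@dataclass
class RunConfig:
    """All pipeline tunables in one serializable record."""

    n_neighbor: int = 40
    t: float = 0.5
    lam: float | None = None
    theta: float = 0.1
    max_outer: int = 10
    pseudo: float = 1.01
    variance_kept: float = 0.4
    normalize: bool = True
    remove_outliers: bool = True
    iteration: bool = True
    seed: int = 42
    log_level: str = "info"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
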