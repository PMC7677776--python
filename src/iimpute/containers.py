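"""In-memory containers for expression matrices.

The package works on genes x cells matrices throughout: rows are genes,
columns are cells, matching the orientation scRNA-seq count files ship in.
A thin dataclass wraps the numpy array together with gene/cell identifiers
so that outlier removal and file round-trips can keep track of labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "LatentMatrix"]


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    Used both for raw counts (non-negative, dropouts encoded as zeros) and
    for processed log-scale expression. Invariants: entries are finite and
    non-negative; gene and cell identifiers are unique.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_cells(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.cell_ids[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class LatentMatrix:
    """Reduced K x N representation of cells (principal-component scores).

    ``values[k, j]`` is the score of cell j on component k; K < min(M, N).
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("latent matrix must be 2-dimensional")
        if self.cell_ids and len(self.cell_ids) != self.values.shape[1]:
            raise ValueError("cell id count does not match latent columns")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]
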