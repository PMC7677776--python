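"""Imputation evaluation: recovery error and clustering agreement.

Recovery against ground truth is scored by RMSE and Pearson correlation
over the flattened matrices on the processed (log) scale. Cell-grouping
quality is scored by Ward hierarchical clustering followed by the adjusted
Rand index and normalized mutual information against the true labels, and
by the silhouette width of the true labels on the expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

__all__ = [
    "EvaluationReport",
    "rmse",
    "pearson_flat",
    "ari",
    "nmi",
    "silhouette",
    "hierarchical_cluster",
    "evaluate",
]


@dataclass
class EvaluationReport:
    rmse: float
    pearson: float
    ari: float
    nmi: float
    silhouette: float

    def to_dict(self) -> dict:
        return asdict(self)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared elementwise difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson_flat(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over flattened entries."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index: 1 for identical partitions, ~0 for random ones."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    return float(normalized_mutual_info_score(labels_a, labels_b))


def silhouette(x: np.ndarray, labels) -> float:
    """Mean silhouette width of cells (columns of x) under Euclidean distance."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(silhouette_score(np.asarray(x, dtype=float).T, labels,
                                  metric="euclidean"))


def hierarchical_cluster(x: np.ndarray, k: int) -> np.ndarray:
    """Ward agglomerative clustering of cells (columns of x) into k groups."""
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(x.T)


def evaluate(
    imputed: np.ndarray,
    truth: np.ndarray,
    labels,
    k: int | None = None,
) -> EvaluationReport:
    """Score an imputed matrix against truth and group labels.

    Clustering is run on the imputed matrix with k = number of distinct
    true labels unless overridden.
    """
    labels = np.asarray(labels)
    if k is None:
        k = int(np.unique(labels).size)
    pred = hierarchical_cluster(imputed, k)
    return EvaluationReport(
        rmse=rmse(imputed, truth),
        pearson=pearson_flat(imputed, truth),
        ari=ari(labels, pred),
        nmi=nmi(labels, pred),
        silhouette=silhouette(imputed, labels),
    )
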