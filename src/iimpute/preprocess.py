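"""Preprocessing: library-size normalization, PCA reduction, outlier removal.

Raw counts are scaled per cell to the median library size and moved to a
log10 scale with a pseudo-count slightly above one, so that zeros map to a
small positive constant distinguishable from genuinely low expression. Cell
geometry for affinity computation lives in a PCA space of "metagenes";
isolated cells in that space are flagged as outliers and kept out of the
imputation regression entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix, LatentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_counts",
    "reduce_dimension",
    "detect_outlier_cells",
    "preprocess",
    "PreprocessResult",
    "DEFAULT_PSEUDO",
    "DEFAULT_VARIANCE_KEPT",
]

DEFAULT_PSEUDO = 1.01
DEFAULT_VARIANCE_KEPT = 0.4


def normalize_counts(counts: ExpressionMatrix, pseudo: float = DEFAULT_PSEUDO) -> ExpressionMatrix:
    """Scale each cell to the median library size, then log10(x + pseudo).

    Parameters
    ----------
    counts
        Raw non-negative genes x cells counts.
    pseudo
        Pseudo-count added before the log; must exceed 1 so the output is
        non-negative everywhere (zeros map to log10(pseudo) > 0).

    Raises
    ------
    ValueError
        If any cell has a zero library size (the scaling is undefined); the
        error message names the offending cell(s).
    """
    if pseudo <= 1.0 - np.finfo(float).eps:
        raise ValueError(f"pseudo-count must exceed 1, got {pseudo}")
    lib = counts.values.sum(axis=0)
    zero_lib = np.flatnonzero(lib == 0)
    if zero_lib.size:
        names = ", ".join(counts.cell_ids[i] for i in zero_lib[:5])
        raise ValueError(f"cell(s) with zero library size: {names}")
    target = float(np.median(lib))
    scaled = counts.values * (target / lib)
    return ExpressionMatrix(
        np.log10(scaled + pseudo), list(counts.gene_ids), list(counts.cell_ids)
    )


def log_transform(counts: ExpressionMatrix, pseudo: float = DEFAULT_PSEUDO) -> ExpressionMatrix:
    """log10(x + pseudo) without library-size scaling."""
    return ExpressionMatrix(
        np.log10(counts.values + pseudo), list(counts.gene_ids), list(counts.cell_ids)
    )


def reduce_dimension(
    x: ExpressionMatrix, variance_kept: float = DEFAULT_VARIANCE_KEPT
) -> LatentMatrix:
    """PCA scores of cells retaining a cumulative explained-variance fraction.

    Genes are centered (and scaled to unit variance where non-constant)
    before the decomposition; K is the smallest number of leading components
    whose cumulative explained variance reaches ``variance_kept``, capped at
    N - 1.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    data = x.values.T  # cells x genes for sklearn
    std = data.std(axis=0, ddof=0)
    if not np.any(std > 0):
        raise ValueError("matrix is constant: no variance to decompose")
    scale = np.where(std > 0, std, 1.0)
    data = (data - data.mean(axis=0)) / scale
    n_max = min(data.shape[0] - 1, data.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    scores = pca.fit_transform(data)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, n_max)
    return LatentMatrix(scores[:, :k].T, list(x.cell_ids))


def detect_outlier_cells(
    z: LatentMatrix, n_neighbors: int = 5, iqr_factor: float = 3.0
) -> set[int]:
    """Flag isolated cells in latent space.

    A cell is an outlier when its Euclidean distance to its
    ``n_neighbors``-th nearest neighbor exceeds Q3 + ``iqr_factor`` * IQR of
    that statistic over all cells. The default factor is Tukey's "far out"
    fence: on sparse data the k-NN distance distribution is heavy-tailed,
    and the conventional 1.5 fence flags ordinary cells. With two or fewer
    cells no cell can be called isolated and the empty set is returned.
    """
    n = z.n_cells
    if n <= 2:
        return set()
    k = min(n_neighbors, n - 1)
    pts = z.values.T
    d2 = (
        np.sum(pts**2, axis=1)[:, None]
        + np.sum(pts**2, axis=1)[None, :]
        - 2 * pts @ pts.T
    )
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)
    kth = np.sqrt(np.sort(d2, axis=1)[:, k - 1])
    q1, q3 = np.percentile(kth, [25, 75])
    cutoff = q3 + iqr_factor * (q3 - q1)
    return set(np.flatnonzero(kth > cutoff).tolist())


@dataclass
class PreprocessResult:
    x: ExpressionMatrix  # processed matrix, retained cells only
    z: LatentMatrix  # latent coordinates of retained cells
    outlier_cells: list[int]  # indices into the original cell order
    retained_cells: list[int]
    x_full: ExpressionMatrix  # processed matrix over all cells, input order


def preprocess(
    counts: ExpressionMatrix,
    pseudo: float = DEFAULT_PSEUDO,
    variance_kept: float = DEFAULT_VARIANCE_KEPT,
    n_neighbors: int = 5,
    normalize: bool = True,
    remove_outliers: bool = True,
) -> PreprocessResult:
    """Full preprocessing pipeline: normalize, reduce, drop outliers.

    With ``normalize=False`` the input is treated as already processed and
    passed through untouched (no scaling, no log transform); dimension
    reduction and outlier removal still run on it.
    """
    x_full = normalize_counts(counts, pseudo) if normalize else ExpressionMatrix(
        counts.values.copy(), list(counts.gene_ids), list(counts.cell_ids)
    )
    z_full = reduce_dimension(x_full, variance_kept)
    outliers = detect_outlier_cells(z_full, n_neighbors) if remove_outliers else set()
    retained = [i for i in range(x_full.n_cells) if i not in outliers]
    if len(retained) < 3:
        logger.warning("outlier removal left %d cells; keeping all", len(retained))
        outliers, retained = set(), list(range(x_full.n_cells))
    x = x_full.subset_cells(retained)
    if outliers:
        logger.info("excluding %d outlier cell(s) from imputation", len(outliers))
        z = reduce_dimension(x, variance_kept)
    else:
        z = z_full
    return PreprocessResult(
        x=x,
        z=z,
        outlier_cells=sorted(outliers),
        retained_cells=retained,
        x_full=x_full,
    )
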