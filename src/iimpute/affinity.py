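"""Cell-cell affinity from an adaptive Gaussian kernel on latent coordinates.

For each cell i the kernel bandwidth sigma_i is set to the distance between
cell i and its n-th nearest neighbor, so every cell keeps a comparable
number of non-zero affinities regardless of local density:

    Dist(i, j) = ||z_i - z_j||^2          (squared Euclidean)
    sigma_i    = n-th smallest Dist(i, .) over j != i
    A_ij       = exp(-Dist(i, j) / (2 sigma_i^2))   if Dist(i, j) <= sigma_i
               = 0                                   otherwise

Because sigma_i adapts per row, A is generally not symmetric. The hard
truncation at sigma_i means each row supports exactly the n nearest
neighbors of cell i (plus any ties at the boundary, which the <= includes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import LatentMatrix

__all__ = ["AffinityMatrix", "pairwise_distance", "bandwidth", "build_affinity"]

DEFAULT_N_NEIGHBOR = 40


@dataclass
class AffinityMatrix:
    """N x N affinities in [0, 1] with the per-cell bandwidths that built them."""

    values: np.ndarray
    bandwidths: np.ndarray
    n_neighbor: int

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def pairwise_distance(z: LatentMatrix) -> np.ndarray:
    """Squared Euclidean distances between latent columns (cells).

    Symmetric, zero diagonal.
    """
    pts = z.values.T
    sq = np.sum(pts**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return d2


def bandwidth(dist: np.ndarray, i: int, n: int) -> float:
    """The n-th smallest off-diagonal entry of row i of the distance matrix."""
    n_cells = dist.shape[0]
    if not 1 <= n <= n_cells - 1:
        raise ValueError(f"n must be in [1, {n_cells - 1}], got {n}")
    row = np.delete(dist[i], i)
    return float(np.partition(row, n - 1)[n - 1])


def build_affinity(z: LatentMatrix, n: int = DEFAULT_N_NEIGHBOR) -> AffinityMatrix:
    """Adaptive Gaussian-kernel affinity over latent coordinates.

    Duplicate cells can force sigma_i = 0; the kernel limit as sigma -> 0+
    is used there: affinity 1 to exact duplicates, 0 elsewhere.
    """
    n_cells = z.n_cells
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if not 1 <= n <= n_cells - 1:
        raise ValueError(f"n must be in [1, {n_cells - 1}], got {n}")
    dist = pairwise_distance(z)
    sigmas = np.empty(n_cells)
    a = np.zeros((n_cells, n_cells))
    for i in range(n_cells):
        s = bandwidth(dist, i, n)
        sigmas[i] = s
        if s == 0.0:
            a[i] = (dist[i] == 0.0).astype(float)
        else:
            support = dist[i] <= s
            a[i, support] = np.exp(-dist[i, support] / (2.0 * s * s))
    return AffinityMatrix(values=a, bandwidths=sigmas, n_neighbor=n)
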