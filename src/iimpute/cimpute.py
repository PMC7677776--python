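"""Single-pass imputation core (C-Impute).

Entries whose dropout probability crosses a threshold t are replaced by the
prediction of a per-cell non-negative lasso regression; all other entries
are kept bit-identical. For cell j the regression target and design are
both weighted by confidence (1 - D) and by cell affinity:

    y      = (1 - D_j) o X_j                       (length M)
    W[:,c] = (1 - D_c) * A_jc * X_c,  c != j       (M x (N-1))

    min_b  ||y - W b||_2^2 + lambda ||b||_1,  b >= 0

so genes likely to be dropouts contribute nothing to the fit, and only
cells within the affinity support of j (its n nearest neighbors) have
non-zero design columns. The L1 penalty zeroes the weights of unhelpful
neighbors. The problem is solved by cyclic coordinate descent with exact
per-coordinate minimization, which makes the objective non-increasing per
sweep.

Predictions for the flagged entries are the weighted fit W b normalized by
the per-gene sum of effective weights (1 - D_c) * A_jc * b_c, i.e. a
confidence-weighted average of the neighbors' values for that gene. The
normalization matters: a neighbor whose own entry is a probable dropout
enters the design as (almost) zero yet its weight would still count, so the
un-normalized fit underestimates every imputed value by roughly the
neighborhood's observed fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .affinity import AffinityMatrix
from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationConfig",
    "CellWeights",
    "ImputedMatrix",
    "build_regression_problem",
    "nnlasso_coordinate_descent",
    "nnlasso_objective",
    "cimpute",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_LAMBDA_FRACTION = 0.01
DEFAULT_MAX_SWEEPS = 1000
DEFAULT_CD_TOL = 1e-6


@dataclass
class ImputationConfig:
    """Tunables of the imputation core.

    ``t``: dropout-probability threshold above which an entry is imputed.
    ``lam``: L1 penalty; None selects it per cell as a fixed fraction
    (``lam_fraction``) of the smallest penalty that would zero all weights.
    """

    t: float = DEFAULT_THRESHOLD
    lam: float | None = None
    lam_fraction: float = DEFAULT_LAMBDA_FRACTION
    max_sweeps: int = DEFAULT_MAX_SWEEPS
    tol: float = DEFAULT_CD_TOL

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("threshold t must be in [0, 1]")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class CellWeights:
    """Non-negative regression weights of one cell over all other cells."""

    b: np.ndarray
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_sweeps: int = 0


@dataclass
class ImputedMatrix:
    """Imputed expression with the mask of entries that were replaced."""

    values: np.ndarray
    imputed_mask: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def to_expression(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.values, list(self.gene_ids), list(self.cell_ids))


def _cd_kernel_py(w: np.ndarray, y: np.ndarray, lam: float,
                  max_sweeps: int, tol: float):
    m, p = w.shape
    beta = np.zeros(p)
    h = np.empty(p)
    for c in range(p):
        s = 0.0
        for i in range(m):
            s += w[i, c] * w[i, c]
        h[c] = s
    r = y.copy()
    trace = np.empty(max_sweeps)
    sweeps = 0
    for _ in range(max_sweeps):
        max_delta = 0.0
        for c in range(p):
            if h[c] == 0.0:
                continue
            g = 0.0
            for i in range(m):
                g += w[i, c] * r[i]
            new = beta[c] + (g - lam) / h[c]
            if new < 0.0:
                new = 0.0
            d = new - beta[c]
            if d != 0.0:
                for i in range(m):
                    r[i] -= w[i, c] * d
                beta[c] = new
                if abs(d) > max_delta:
                    max_delta = abs(d)
        obj = 0.0
        for i in range(m):
            obj += r[i] * r[i]
        obj *= 0.5
        for c in range(p):
            obj += lam * beta[c]
        trace[sweeps] = obj
        sweeps += 1
        if max_delta < tol:
            break
    return beta, trace[:sweeps], sweeps


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _cd_kernel = njit(cache=True, fastmath=False)(_cd_kernel_py)
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


def nnlasso_objective(w: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """0.5 ||y - W b||^2 + lambda sum(b) (b assumed non-negative)."""
    r = y - w @ beta
    return float(0.5 * r @ r + lam * beta.sum())


def nnlasso_coordinate_descent(
    design: np.ndarray,
    target: np.ndarray,
    lam: float,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    tol: float = DEFAULT_CD_TOL,
) -> CellWeights:
    """Solve min_b 0.5||y - Wb||^2 + lam*sum(b), b >= 0 by coordinate descent.

    Each coordinate update is the exact one-dimensional minimizer
    b_c <- max(0, b_c + (w_c' r - lam) / ||w_c||^2), so the objective never
    increases. Sweeps run in ascending column order until the largest
    coordinate change in a sweep falls below ``tol``. All-zero design
    columns keep weight zero.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    w = np.ascontiguousarray(design, dtype=float)
    y = np.ascontiguousarray(target, dtype=float)
    if w.shape[0] != y.shape[0]:
        raise ValueError("design and target row counts differ")
    beta, trace, sweeps = _cd_kernel(w, y, float(lam), int(max_sweeps), float(tol))
    return CellWeights(b=beta, objective_trace=trace, n_sweeps=int(sweeps))


def build_regression_problem(
    x: np.ndarray, d: np.ndarray, a: np.ndarray, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted design and target for cell j's regression.

    Returns ``(design, target)`` where ``design`` has one column per other
    cell c: (1 - D[:, c]) * A[j, c] * X[:, c], and ``target`` is
    (1 - D[:, j]) * X[:, j]. Cells outside the affinity support of j
    (A[j, c] = 0) yield all-zero columns.
    """
    m, n = x.shape
    others = np.concatenate([np.arange(j), np.arange(j + 1, n)])
    design = (1.0 - d[:, others]) * a[j, others][None, :] * x[:, others]
    target = (1.0 - d[:, j]) * x[:, j]
    return design, target


def cimpute(
    x: ExpressionMatrix,
    d: np.ndarray,
    a: AffinityMatrix,
    cfg: ImputationConfig | None = None,
) -> ImputedMatrix:
    """One imputation pass over all cells.

    For each cell with at least one entry of dropout probability >= t, the
    weighted non-negative lasso is solved once and exactly those entries are
    replaced by the (non-negative) prediction; everything else is left
    bit-identical to the input. Cells with zero affinity to every other
    cell cannot borrow information and are left unchanged.
    """
    cfg = cfg or ImputationConfig()
    vals = x.values
    m, n = vals.shape
    if d.shape != (m, n) or a.values.shape != (n, n):
        raise ValueError("dropout/affinity shapes inconsistent with matrix")
    out = vals.copy()
    mask = d >= cfg.t
    for j in range(n):
        col_mask = mask[:, j]
        if not col_mask.any():
            continue
        others = np.concatenate([np.arange(j), np.arange(j + 1, n)])
        if not np.any(a.values[j, others] > 0):
            logger.warning("cell %s has no affine neighbors; left unimputed",
                           x.cell_ids[j])
            mask[:, j] = False
            continue
        design, target = build_regression_problem(vals, d, a.values, j)
        if cfg.lam is None:
            lam = cfg.lam_fraction * float(np.abs(design.T @ target).max())
        else:
            lam = cfg.lam
        weights = nnlasso_coordinate_descent(
            design, target, lam, cfg.max_sweeps, cfg.tol
        )
        pred = design @ weights.b
        # Normalize by the per-gene sum of effective weights so the
        # prediction is a confidence-weighted average of neighbor values:
        # without it, neighbors whose entry is itself a likely dropout
        # contribute a zero but still count, deflating every imputation.
        conf = (1.0 - d[:, others]) * a.values[j, others][None, :]
        denom = conf @ weights.b
        ok = col_mask & (denom > 1e-8)
        out[ok, j] = np.maximum(pred[ok] / denom[ok], 0.0)
        mask[:, j] = ok
    return ImputedMatrix(
        values=out, imputed_mask=mask,
        gene_ids=list(x.gene_ids), cell_ids=list(x.cell_ids),
    )
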