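"""Iterative self-consistent imputation (I-Impute).

A single imputation pass is viewed as a mapping f: X -> X on processed
matrices. The output is called self-consistent when feeding it back through
the full mapping changes it by less than a threshold theta, measured as the
root of the mean squared elementwise difference between X_out and f(X_out).
The outer loop therefore re-runs the whole core — refitting the dropout
mixture and the affinity matrix on the current matrix each round, since the
mapping must be the same function every time — until the between-iteration
RMSE drops below theta or an iteration cap is hit.

An optional pre-smoothing hook can transform the processed matrix before
the loop starts (the role a gene-wise shrinkage or external denoiser would
play); the default is to iterate the core directly on the processed data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .affinity import DEFAULT_N_NEIGHBOR, build_affinity
from .cimpute import DEFAULT_THRESHOLD, ImputationConfig, ImputedMatrix, cimpute
from .containers import ExpressionMatrix
from .dropout import dropout_probability, fit_mixture
from .preprocess import (
    DEFAULT_PSEUDO,
    DEFAULT_VARIANCE_KEPT,
    preprocess,
    reduce_dimension,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelfConsistencyReport",
    "self_consistency",
    "self_consistency_mse",
    "shrink_smooth",
    "iimpute",
    "DEFAULT_THETA",
    "DEFAULT_MAX_OUTER",
]

DEFAULT_THETA = 0.1
DEFAULT_MAX_OUTER = 10


@dataclass
class SelfConsistencyReport:
    """Per-iteration self-consistency trace of the outer loop."""

    rmse_trace: list[float] = field(default_factory=list)
    theta: float = DEFAULT_THETA
    iterations_run: int = 0
    self_consistent: bool = False
    outlier_cells: list[int] = field(default_factory=list)


def self_consistency_mse(x_out: np.ndarray, f_x_out: np.ndarray) -> float:
    """Squared Frobenius norm of the difference divided by M*N."""
    a = np.asarray(x_out, dtype=float)
    b = np.asarray(f_x_out, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def self_consistency(x_out: np.ndarray, f_x_out: np.ndarray) -> float:
    """Root-mean-square difference between a matrix and its re-imputation."""
    return float(np.sqrt(self_consistency_mse(x_out, f_x_out)))


def shrink_smooth(x: np.ndarray) -> np.ndarray:
    """Gene-wise empirical-Bayes style shrinkage smoother (optional hook).

    Each entry is shrunk toward its gene mean with a gene-specific weight
    v_g / (v_g + s2), where v_g is the gene's across-cell variance and s2
    the median of those variances — a crude variance-stabilizing denoiser,
    not a substitute for a full expression-recovery model.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    v = x.var(axis=1, keepdims=True)
    s2 = float(np.median(v[v > 0])) if np.any(v > 0) else 0.0
    w = np.divide(v, v + s2, out=np.ones_like(v), where=(v + s2) > 0)
    return w * x + (1.0 - w) * mu


def iimpute(
    counts: ExpressionMatrix,
    *,
    n_neighbor: int = DEFAULT_N_NEIGHBOR,
    t: float = DEFAULT_THRESHOLD,
    lam: float | None = None,
    theta: float = DEFAULT_THETA,
    max_outer: int = DEFAULT_MAX_OUTER,
    pseudo: float = DEFAULT_PSEUDO,
    variance_kept: float = DEFAULT_VARIANCE_KEPT,
    normalize: bool = True,
    remove_outliers: bool = True,
    iteration: bool = True,
    presmooth: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[ImputedMatrix, SelfConsistencyReport]:
    """Run the full imputation pipeline on a raw count matrix.

    Parameters
    ----------
    counts
        Raw genes x cells counts (dropouts encoded as zeros).
    n_neighbor
        Affinity bandwidth neighbor rank n (capped at N - 1).
    t
        Dropout-probability threshold; entries with D >= t are imputed.
    lam
        L1 penalty; None selects it per cell (see ImputationConfig).
    theta
        Self-consistency threshold on the between-iteration RMSE.
    max_outer
        Iteration cap for the outer loop.
    normalize
        If False the input is treated as already processed (no library-size
        scaling, no log transform).
    iteration
        If False, run a single pass of the core (no outer loop).
    presmooth
        Optional hook applied to the processed matrix before the loop.

    Returns
    -------
    (ImputedMatrix, SelfConsistencyReport)
        The imputed matrix on the processed (log) scale over all input
        cells in input order — outlier cells pass through unimputed — and
        the iteration trace. ``self_consistent`` is True iff the final
        trace value is below theta.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    prep = preprocess(
        counts,
        pseudo=pseudo,
        variance_kept=variance_kept,
        normalize=normalize,
        remove_outliers=remove_outliers,
    )
    x = prep.x
    n_ret = x.n_cells
    n_eff = min(n_neighbor, n_ret - 1)
    if n_eff < n_neighbor:
        logger.warning("n_neighbor %d capped at N-1 = %d", n_neighbor, n_eff)
    low_threshold = float(np.log10(pseudo)) + 0.1

    cur = x.values
    if presmooth is not None:
        cur = np.maximum(np.asarray(presmooth(cur), dtype=float), 0.0)
        if cur.shape != x.values.shape:
            raise ValueError("presmooth hook changed the matrix shape")

    cfg = ImputationConfig(t=t, lam=lam)
    report = SelfConsistencyReport(theta=theta, outlier_cells=prep.outlier_cells)
    n_rounds = max_outer if iteration else 1
    best_val, best_vals, best_mask = np.inf, cur, np.zeros_like(cur, dtype=bool)
    for k in range(n_rounds):
        cur_mat = ExpressionMatrix(cur, list(x.gene_ids), list(x.cell_ids))
        fit = fit_mixture(cur, low_threshold=low_threshold)
        d = dropout_probability(cur_mat, fit)
        z = reduce_dimension(cur_mat, variance_kept)
        aff = build_affinity(z, n_eff)
        imp = cimpute(cur_mat, d, aff, cfg)
        val = self_consistency(cur, imp.values)
        report.rmse_trace.append(val)
        report.iterations_run = k + 1
        logger.info("iteration %d: self-consistency RMSE %.4f "
                    "(%d entries imputed)", k + 1, val, int(imp.imputed_mask.sum()))
        cur = imp.values
        if val < best_val:
            best_val, best_vals, best_mask = val, imp.values, imp.imputed_mask
        if val < theta:
            break
    report.self_consistent = report.rmse_trace[-1] < theta
    if not report.self_consistent:
        if iteration:
            logger.warning("no self-consistency after %d iterations "
                           "(best RMSE %.4f); returning best iterate",
                           report.iterations_run, best_val)
        final_vals, final_mask = best_vals, best_mask
    else:
        final_vals, final_mask = cur, imp.imputed_mask

    # reassemble over all input cells: outliers pass through unimputed
    full = prep.x_full.values.copy()
    mask_full = np.zeros_like(full, dtype=bool)
    ret = prep.retained_cells
    full[:, ret] = final_vals
    mask_full[:, ret] = final_mask
    out = ImputedMatrix(
        values=full, imputed_mask=mask_full,
        gene_ids=list(counts.gene_ids), cell_ids=list(counts.cell_ids),
    )
    return out, report
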