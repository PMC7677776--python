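"""Per-gene Gamma-Normal mixture model for dropout identification.

On the processed (log-scale) matrix, each gene's expression across cells is
modelled as a two-component mixture

    f(x) = pi * Gamma(x; alpha, beta) + (1 - pi) * Normal(x; mu, sigma)

where the Gamma component, concentrated near zero, absorbs dropout events
and the Normal component carries the actual expression level. A zero-
inflated negative binomial is not applicable here because the processed
matrix is no longer integer-valued. Parameters are estimated per gene by
an EM scheme in which the Gamma M-step uses responsibility-weighted method
of moments (alpha = m^2/v, beta = m/v) instead of the digamma root-find of
the exact MLE; an ascent guard rejects any update that would lower the
log-likelihood, so the recorded trace is non-decreasing by construction.

The dropout probability of entry (i, j) is the posterior weight of the
Gamma component at X_ij:

    D_ij = pi_i Gamma(X_ij) / f(X_ij)

Genes with too few values or near-constant expression are not fitted; their
dropout probabilities are set to zero (observed values treated as real).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .containers import ExpressionMatrix

__all__ = [
    "GeneMixtureParams",
    "MixtureFit",
    "mixture_density",
    "fit_gene_mixture",
    "fit_mixture",
    "dropout_probability",
]

EPS_X = 1e-6  # density evaluation floor: Gamma pdf diverges at 0 for alpha < 1
SIGMA_FLOOR = 1e-3
MIN_VALUES = 10
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100
_PARAM_LO, _PARAM_HI = 1e-3, 1e4


@dataclass
class GeneMixtureParams:
    """Fitted mixture parameters for one gene.

    ``pi`` is the dropout rate (Gamma component weight); ``alpha``/``beta``
    the Gamma shape and rate; ``mu``/``sigma`` the Normal mean and standard
    deviation. ``loglik_trace`` records the log-likelihood after each
    accepted EM iteration.
    """

    pi: float
    alpha: float
    beta: float
    mu: float
    sigma: float
    loglik: float = np.nan
    converged: bool = False
    fitted: bool = True
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class MixtureFit:
    """Vectorized per-gene parameters for a whole matrix (arrays of length M)."""

    pi: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    fitted: np.ndarray  # False where the gene was skipped (D row forced to 0)

    def gene(self, i: int) -> GeneMixtureParams:
        return GeneMixtureParams(
            pi=float(self.pi[i]),
            alpha=float(self.alpha[i]),
            beta=float(self.beta[i]),
            mu=float(self.mu[i]),
            sigma=float(self.sigma[i]),
            loglik=float(self.loglik[i]),
            converged=bool(self.converged[i]),
            fitted=bool(self.fitted[i]),
        )


def _gamma_logpdf(x: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return alpha * np.log(beta) - gammaln(alpha) + (alpha - 1.0) * np.log(x) - beta * x


def _normal_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def mixture_density(x: float, p: GeneMixtureParams) -> float:
    """Mixture pdf pi*Gamma + (1-pi)*Normal, evaluated at max(x, floor)."""
    xv = np.maximum(float(x), EPS_X)
    dens = 0.0
    if p.pi > 0:
        dens += p.pi * np.exp(_gamma_logpdf(xv, p.alpha, p.beta))
    if p.pi < 1:
        dens += (1.0 - p.pi) * np.exp(_normal_logpdf(xv, p.mu, p.sigma))
    return float(dens)


def _initial_params(x: np.ndarray, low_threshold: float):
    """Deterministic initialization: split values into a low and a high part.

    pi0 is the fraction of entries at or below ``low_threshold``; Gamma
    moments come from the lower half of the sorted values, Normal moments
    from the upper half, which separates the components even when the
    threshold captures nothing.
    """
    g, n = x.shape
    pi0 = np.clip((x <= low_threshold).mean(axis=1), 1e-3, 1.0 - 1e-3)
    xs = np.sort(x, axis=1)
    half = n // 2
    low, high = xs[:, :half], xs[:, half:]
    m_low = np.maximum(low.mean(axis=1), EPS_X)
    v_low = np.maximum(low.var(axis=1), 1e-4)
    alpha0 = np.clip(m_low**2 / v_low, _PARAM_LO, _PARAM_HI)
    beta0 = np.clip(m_low / v_low, _PARAM_LO, _PARAM_HI)
    mu0 = high.mean(axis=1)
    sigma0 = np.maximum(high.std(axis=1), SIGMA_FLOOR)
    return pi0, alpha0, beta0, mu0, sigma0


def _joint_logpdf(x, pi, alpha, beta, mu, sigma):
    """Stacked (2, G, N) component log joint densities log(w_k) + log f_k."""
    with np.errstate(divide="ignore"):
        lg = np.log(pi)[:, None] + _gamma_logpdf(x, alpha[:, None], beta[:, None])
        ln = np.log1p(-pi)[:, None] + _normal_logpdf(x, mu[:, None], sigma[:, None])
    return np.stack([lg, ln])


def fit_mixture(
    x: np.ndarray,
    low_threshold: float,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> MixtureFit:
    """Fit the Gamma-Normal mixture to every row (gene) of ``x`` by EM.

    ``x`` is the processed (G, N) matrix; all genes are fitted jointly with
    vectorized E/M steps. Genes with fewer than 10 cells or near-constant
    values are skipped (``fitted`` False, pi forced to 0).
    """
    x = np.asarray(x, dtype=float)
    g, n = x.shape
    xc = np.maximum(x, EPS_X)

    fitted = np.ones(g, dtype=bool)
    if n < MIN_VALUES:
        fitted[:] = False
    fitted &= x.std(axis=1) > 1e-6

    pi, alpha, beta, mu, sigma = _initial_params(xc, low_threshold)
    params = [pi, alpha, beta, mu, sigma]
    prev = [p.copy() for p in params]
    loglik = np.full(g, -np.inf)
    converged = np.zeros(g, dtype=bool)

    active = fitted.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        xa = xc[idx]
        lj = _joint_logpdf(xa, pi[idx], alpha[idx], beta[idx], mu[idx], sigma[idx])
        ltot = logsumexp(lj, axis=0)
        new_ll = ltot.sum(axis=1)
        resp = np.exp(lj[0] - ltot)  # responsibility of the Gamma component

        # ascent guard: the approximate Gamma M-step can in principle lower
        # the likelihood; such genes revert to the previous params and stop
        worse = new_ll < loglik[idx] - 1e-9
        if worse.any():
            w_idx = idx[worse]
            for cur, old in zip(params, prev):
                cur[w_idx] = old[w_idx]
            active[w_idx] = False
        done = ~worse & (np.abs(new_ll - loglik[idx]) < tol)
        loglik[idx[~worse]] = new_ll[~worse]
        converged[idx[done]] = True
        active[idx[done]] = False

        cont = ~worse & ~done
        upd = idx[cont]
        if upd.size == 0:
            continue
        for cur, old in zip(params, prev):
            old[upd] = cur[upd]
        r = resp[cont]
        xu = xc[upd]
        rsum = r.sum(axis=1)
        wsum = n - rsum
        new_pi = np.clip(rsum / n, 1e-4, 1.0 - 1e-4)
        # Normal M-step: responsibility-weighted mean / std
        safe_w = np.maximum(wsum, 1e-8)
        new_mu = ((1.0 - r) * xu).sum(axis=1) / safe_w
        new_var = ((1.0 - r) * (xu - new_mu[:, None]) ** 2).sum(axis=1) / safe_w
        new_sigma = np.maximum(np.sqrt(new_var), SIGMA_FLOOR)
        # Gamma M-step: weighted method of moments
        safe_r = np.maximum(rsum, 1e-8)
        m = np.maximum((r * xu).sum(axis=1) / safe_r, EPS_X)
        v = np.maximum((r * (xu - m[:, None]) ** 2).sum(axis=1) / safe_r, 1e-8)
        new_alpha = np.clip(m**2 / v, _PARAM_LO, _PARAM_HI)
        new_beta = np.clip(m / v, _PARAM_LO, _PARAM_HI)
        keep = rsum > 1e-6  # no mass on the Gamma component: keep its params
        pi[upd] = new_pi
        mu[upd] = new_mu
        sigma[upd] = new_sigma
        alpha[upd] = np.where(keep, new_alpha, alpha[upd])
        beta[upd] = np.where(keep, new_beta, beta[upd])

    pi[~fitted] = 0.0
    # separation guard: the dropout (Gamma) component must be concentrated
    # well below the expression (Normal) component — its mean in the lower
    # half of the expression scale; otherwise the two components are
    # splitting the same unimodal mass and no entry is a credible dropout
    pi[alpha / beta >= 0.5 * mu] = 0.0
    return MixtureFit(
        pi=pi, alpha=alpha, beta=beta, mu=mu, sigma=sigma,
        loglik=loglik, converged=converged, fitted=fitted,
    )


def fit_gene_mixture(
    values: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    low_threshold: float = np.log10(1.01) + 0.1,
) -> GeneMixtureParams:
    """Fit the mixture for a single gene, recording the log-likelihood trace.

    Identical model and updates as :func:`fit_mixture`, run one gene at a
    time so the per-iteration likelihood trace can be inspected.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n < MIN_VALUES or values.std() <= 1e-6:
        p = GeneMixtureParams(pi=0.0, alpha=1.0, beta=1.0,
                              mu=float(values.mean()) if n else 0.0,
                              sigma=SIGMA_FLOOR, converged=False, fitted=False)
        return p

    xc = np.maximum(values, EPS_X)[None, :]
    pi, alpha, beta, mu, sigma = _initial_params(xc, low_threshold)
    prev = (pi, alpha, beta, mu, sigma)
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        lj = _joint_logpdf(xc, pi, alpha, beta, mu, sigma)
        ltot = logsumexp(lj, axis=0)
        new_ll = float(ltot.sum())
        if new_ll < loglik - 1e-9:
            # the approximate Gamma M-step lowered the likelihood: revert
            pi, alpha, beta, mu, sigma = prev
            break
        trace.append(new_ll)
        if abs(new_ll - loglik) < tol:
            loglik = new_ll
            converged = True
            break
        loglik = new_ll
        prev = (pi, alpha, beta, mu, sigma)
        r = np.exp(lj[0] - ltot)[0]
        rsum = r.sum()
        pi = np.clip([rsum / n], 1e-4, 1.0 - 1e-4)
        w = 1.0 - r
        mu = np.array([(w * xc[0]).sum() / max(w.sum(), 1e-8)])
        var = (w * (xc[0] - mu[0]) ** 2).sum() / max(w.sum(), 1e-8)
        sigma = np.array([max(np.sqrt(var), SIGMA_FLOOR)])
        if rsum > 1e-6:
            m = max((r * xc[0]).sum() / rsum, EPS_X)
            v = max((r * (xc[0] - m) ** 2).sum() / rsum, 1e-8)
            alpha = np.clip([m**2 / v], _PARAM_LO, _PARAM_HI)
            beta = np.clip([m / v], _PARAM_LO, _PARAM_HI)
    pi_out = float(pi[0])
    if alpha[0] / beta[0] >= 0.5 * mu[0]:  # dropout component not separated
        pi_out = 0.0
    return GeneMixtureParams(
        pi=pi_out, alpha=float(alpha[0]), beta=float(beta[0]),
        mu=float(mu[0]), sigma=float(sigma[0]), loglik=loglik,
        converged=converged, fitted=True, loglik_trace=trace,
    )


def dropout_probability(x: ExpressionMatrix, fit: MixtureFit) -> np.ndarray:
    """Posterior probability that each entry is a dropout (Gamma component).

    Rows of unfitted genes or genes with pi = 0 are identically zero. Where
    the total density underflows to zero, the entry is resolved by the
    mixing weight alone (1 if pi > 0.5 else 0).
    """
    vals = np.maximum(x.values, EPS_X)
    d = np.zeros_like(vals)
    use = fit.fitted & (fit.pi > 0)
    if use.any():
        idx = np.flatnonzero(use)
        lj = _joint_logpdf(vals[idx], fit.pi[idx], fit.alpha[idx],
                           fit.beta[idx], fit.mu[idx], fit.sigma[idx])
        ltot = logsumexp(lj, axis=0)
        with np.errstate(invalid="ignore"):
            post = np.exp(lj[0] - ltot)
        bad = ~np.isfinite(ltot) | (ltot == -np.inf)
        if bad.any():
            fallback = (fit.pi[idx] > 0.5).astype(float)[:, None]
            post = np.where(bad, np.broadcast_to(fallback, post.shape), post)
        d[idx] = np.clip(post, 0.0, 1.0)
    return d
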