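import numpy as np
import pytest
from scipy import stats

from iimpute import (
    ExpressionMatrix,
    GeneMixtureParams,
    dropout_probability,
    fit_gene_mixture,
    fit_mixture,
    mixture_density,
)
from iimpute.dropout import EPS_X, MixtureFit


def _fit_from_params(plist):
    return MixtureFit(
        pi=np.array([p.pi for p in plist]),
        alpha=np.array([p.alpha for p in plist]),
        beta=np.array([p.beta for p in plist]),
        mu=np.array([p.mu for p in plist]),
        sigma=np.array([p.sigma for p in plist]),
        loglik=np.zeros(len(plist)),
        converged=np.ones(len(plist), bool),
        fitted=np.array([p.fitted for p in plist]),
    )


class TestMixtureDensity:
    def test_pure_normal(self):
        p = GeneMixtureParams(pi=0.0, alpha=2.0, beta=2.0, mu=1.5, sigma=0.5)
        assert mixture_density(1.0, p) == pytest.approx(
            stats.norm.pdf(1.0, 1.5, 0.5), rel=1e-12
        )

    def test_exponential_at_zero_uses_floor(self):
        p = GeneMixtureParams(pi=1.0, alpha=1.0, beta=1.0, mu=0.0, sigma=1.0)
        assert mixture_density(0.0, p) == pytest.approx(np.exp(-EPS_X), rel=1e-9)

    def test_matches_component_pdf_sum(self):
        p = GeneMixtureParams(pi=0.5, alpha=2.0, beta=2.0, mu=3.0, sigma=1.0)
        expect = 0.5 * stats.gamma.pdf(1.0, a=2.0, scale=0.5) + 0.5 * stats.norm.pdf(
            1.0, 3.0, 1.0
        )
        assert mixture_density(1.0, p) == pytest.approx(expect, rel=1e-10)

    def test_never_infinite_for_diverging_gamma(self):
        p = GeneMixtureParams(pi=1.0, alpha=0.5, beta=1.0, mu=0.0, sigma=1.0)
        assert np.isfinite(mixture_density(0.0, p))


class TestFitGeneMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n = 5000
        comp = rng.random(n) < 0.5
        vals = np.where(
            comp, rng.gamma(2.0, 1.0 / 4.0, n), rng.normal(4.0, 0.5, n)
        )
        p = fit_gene_mixture(vals)
        assert p.pi == pytest.approx(0.5, abs=0.05)
        assert p.mu == pytest.approx(4.0, abs=0.1)

    def test_no_low_mass_gives_tiny_pi(self):
        rng = np.random.default_rng(4)
        p = fit_gene_mixture(rng.normal(5.0, 0.3, 500))
        assert p.pi < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_trace_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.abs(rng.normal(1.0, 1.0, 200))
        p = fit_gene_mixture(vals)
        trace = np.array(p.loglik_trace)
        assert trace.size >= 1
        assert np.all(np.diff(trace) >= -1e-8)

    def test_short_or_constant_genes_unfitted(self):
        assert not fit_gene_mixture(np.ones(5)).fitted
        assert not fit_gene_mixture(np.full(50, 2.0)).fitted

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        vals = np.abs(rng.normal(1.0, 1.0, 300))
        a, b = fit_gene_mixture(vals), fit_gene_mixture(vals)
        assert (a.pi, a.alpha, a.beta, a.mu, a.sigma) == (
            b.pi, b.alpha, b.beta, b.mu, b.sigma
        )

    def test_batch_fit_matches_single_gene(self):
        rng = np.random.default_rng(12)
        x = np.abs(rng.normal(1.5, 1.0, size=(6, 120)))
        x[:, :40] = np.log10(1.01)  # a dropout-like low block
        batch = fit_mixture(x, low_threshold=np.log10(1.01) + 0.1)
        for i in range(6):
            single = fit_gene_mixture(x[i])
            assert batch.pi[i] == pytest.approx(single.pi, rel=1e-6, abs=1e-9)
            assert batch.mu[i] == pytest.approx(single.mu, rel=1e-6, abs=1e-9)


class TestDropoutProbability:
    def _matrix(self, vals):
        m, n = vals.shape
        return ExpressionMatrix(vals, [f"g{i}" for i in range(m)],
                                [f"c{j}" for j in range(n)])

    def test_pi_zero_gives_zero_row(self):
        p = GeneMixtureParams(pi=0.0, alpha=1.0, beta=1.0, mu=2.0, sigma=1.0)
        d = dropout_probability(self._matrix(np.ones((1, 5))), _fit_from_params([p]))
        np.testing.assert_array_equal(d, np.zeros((1, 5)))

    def test_pi_one_gives_one_row(self):
        p = GeneMixtureParams(pi=1.0, alpha=1.0, beta=1.0, mu=2.0, sigma=1.0)
        d = dropout_probability(self._matrix(np.ones((1, 5))), _fit_from_params([p]))
        np.testing.assert_allclose(d, np.ones((1, 5)))

    def test_posterior_half_where_pdfs_equal(self):
        # alpha=1,beta=1 Gamma is Exp(1); find x where Exp(1) pdf = Normal pdf
        from scipy.optimize import brentq
        mu, sigma = 2.0, 0.7
        f = lambda x: stats.gamma.pdf(x, a=1.0) - stats.norm.pdf(x, mu, sigma)
        x_eq = brentq(f, 0.1, 2.0)
        p = GeneMixtureParams(pi=0.5, alpha=1.0, beta=1.0, mu=mu, sigma=sigma)
        d = dropout_probability(
            self._matrix(np.array([[x_eq]])), _fit_from_params([p])
        )
        assert d[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_monotone_decreasing_in_expression(self):
        # Gamma shape <= 1 so the dropout component is decreasing from zero
        p = GeneMixtureParams(pi=0.4, alpha=1.0, beta=3.0, mu=3.0, sigma=0.6)
        xs = np.linspace(0.0, 3.0, 50)[None, :]
        d = dropout_probability(self._matrix(xs), _fit_from_params([p] * 1))
        assert np.all(np.diff(d[0]) <= 1e-12)

    def test_equals_estep_responsibility_at_fit(self):
        rng = np.random.default_rng(21)
        n = 400
        comp = rng.random(n) < 0.4
        vals = np.where(comp, rng.gamma(1.5, 0.2, n), rng.normal(3.0, 0.5, n))
        fit = fit_mixture(vals[None, :], low_threshold=np.log10(1.01) + 0.1)
        d = dropout_probability(self._matrix(vals[None, :]), fit)
        # independent posterior computation from the fitted parameters
        x = np.maximum(vals, EPS_X)
        g = fit.pi[0] * stats.gamma.pdf(x, a=fit.alpha[0], scale=1 / fit.beta[0])
        nrm = (1 - fit.pi[0]) * stats.norm.pdf(x, fit.mu[0], fit.sigma[0])
        np.testing.assert_allclose(d[0], g / (g + nrm), atol=1e-10)
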