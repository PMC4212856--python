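import itertools

import numpy as np
import pytest
from scipy.stats import beta as beta_dist, kstest

from aflpop.inbreeding import (
    InbreedingModel,
    InbreedingModelSpec,
    _loglik_terms,
    phenotype_prob,
    prior_sensitivity,
    run_chain,
)
from conftest import make_dataset


class TestPhenotypeProb:
    @pytest.mark.parametrize("q,fi,expected", [(0.5, 0.0, 0.25), (0.5, 1.0, 0.5)])
    def test_hand_values(self, q, fi, expected):
        assert phenotype_prob(q, fi) == pytest.approx(expected)

    def test_normalisation(self):
        rng = np.random.default_rng(0)
        q, fi = rng.random(100), rng.random(100)
        p0 = phenotype_prob(q, fi)
        assert np.all((p0 >= 0) & (p0 <= 1))

    def test_range_validation(self):
        with pytest.raises(ValueError):
            phenotype_prob(1.2, 0.0)


class TestChainCorrectness:
    def test_matches_brute_force_grid_posterior(self):
        """Exactness: posterior mean of mean(Fi) vs full grid integration on a
        3 x 2 dataset with uniform priors (fixed shapes, a = b = 1)."""
        pheno = np.array([[0, 1], [1, 1], [0, 0]])
        ds = make_dataset(pheno)
        G = 40
        grid = (np.arange(G) + 0.5) / G
        Z = pheno == 0
        q1, q2 = np.meshgrid(grid, grid, indexing="ij")
        num = den = 0.0
        for F in itertools.product(grid, repeat=3):
            f = np.array(F)
            lik = np.ones((G, G))
            for i in range(3):
                for l, qg in enumerate((q1, q2)):
                    p0 = qg**2 + f[i] * qg * (1 - qg)
                    lik = lik * (p0 if Z[i, l] else 1 - p0)
            w = lik.sum()
            num += w * f.mean()
            den += w
        exact = num / den
        spec = InbreedingModelSpec(
            n_steps=150_000, burn_in=15_000, thin=5,
            update_shapes=False, seed=9,
        )
        post = run_chain(ds, spec)
        assert post.f_mean == pytest.approx(exact, abs=0.01)

    def test_prior_recovery_constant_likelihood(self, empty_locus_dataset):
        """With no loci the likelihood is constant: the Fi marginal must match
        the Beta(2, 5) prior (Kolmogorov-Smirnov on pooled thinned draws)."""
        spec = InbreedingModelSpec(
            alpha=2, beta=5, n_steps=40_000, burn_in=5_000, thin=100,
            update_shapes=False, ridge_move=False, seed=3,
        )
        post = run_chain(empty_locus_dataset, spec, keep_fi_chain=True)
        draws = post.fi_chain.ravel()
        assert draws.size >= 10_000
        assert kstest(draws, beta_dist(2, 5).cdf).statistic < 0.02

    def test_prior_mean_identity_on_empty_data(self, empty_locus_dataset):
        """a = b fixes the prior mean F = a/(a+b) = 0.5; the chain on an empty
        dataset must reproduce it."""
        spec = InbreedingModelSpec(
            alpha=5, beta=5, n_steps=30_000, burn_in=3_000,
            update_shapes=False, seed=4,
        )
        post = run_chain(empty_locus_dataset, spec)
        assert post.f_mean == pytest.approx(0.5, abs=0.02)

    def test_bit_identical_reruns(self):
        rng = np.random.default_rng(10)
        ds = make_dataset((rng.random((20, 10)) < 0.6).astype(int))
        spec = InbreedingModelSpec(n_steps=2_000, burn_in=500, seed=123)
        p1 = run_chain(ds, spec)
        p2 = run_chain(ds, spec)
        np.testing.assert_array_equal(p1.f_chain, p2.f_chain)
        np.testing.assert_array_equal(p1.logl_chain, p2.logl_chain)

    def test_reported_quantities_finite_and_rates_in_unit_interval(self):
        rng = np.random.default_rng(11)
        ds = make_dataset((rng.random((25, 15)) < 0.7).astype(int))
        post = run_chain(ds, InbreedingModelSpec(n_steps=3_000, burn_in=600, seed=1))
        assert np.isfinite([post.f_mean, post.logl_mean, post.logl_sd]).all()
        assert 0 < post.accept_q < 1 and 0 < post.accept_f < 1
        assert post.f_ci[0] <= post.f_median <= post.f_ci[1]
        assert 0 <= post.f_mean <= 1

    def test_posterior_monotone_in_band_absence_excess_known_q(self):
        """With the allele frequency known, a larger band-absence count pulls
        the posterior of F upward (exact 1-D integration of the single-locus
        model; at a single locus with q unknown, F and q are confounded and
        no such gradient exists)."""
        from scipy import integrate

        q, n = 0.4, 40

        def post_mean_f(n_absent):
            def weight(f):
                p0 = phenotype_prob(q, f)
                return p0**n_absent * (1 - p0) ** (n - n_absent)

            num, _ = integrate.quad(lambda f: f * weight(f), 0, 1)
            den, _ = integrate.quad(weight, 0, 1)
            return num / den

        means = [post_mean_f(k) for k in (6, 12, 20, 30)]
        assert np.all(np.diff(means) > 0)


class TestModelInterface:
    def test_model_fit_summary_columns(self):
        rng = np.random.default_rng(12)
        ds = make_dataset((rng.random((15, 8)) < 0.6).astype(int))
        res = InbreedingModel(ds, alpha=1, beta=1).fit(
            n_steps=2_000, burn_in=400, seed=2
        )
        tab = res.summary()
        assert {"alpha", "beta", "F", "ci_lo", "ci_hi", "logL_mean"} <= set(tab.columns)

    def test_prior_sensitivity_default_three_rows(self, empty_locus_dataset):
        base = InbreedingModelSpec(
            n_steps=6_000, burn_in=1_000, update_shapes=False, seed=5
        )
        tab = prior_sensitivity(empty_locus_dataset, base_spec=base)
        assert list(tab["alpha"]) == [0.1, 1.0, 5.0]
        # empty data: every a = b prior recovers its mean 0.5
        assert np.allclose(tab["F"], 0.5, atol=0.03)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            InbreedingModelSpec(alpha=-1)
        with pytest.raises(ValueError):
            InbreedingModelSpec(n_steps=100, burn_in=100)
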