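import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from aflpop import simulate as sim
from aflpop.allele_freq import (
    InsufficientDataError,
    PriorSpec,
    UNIFORM_PRIOR,
    diversity,
    estimate_allele_freq,
    fit_phenotype_prior,
    hj_per_locus,
    moment_matched_prior,
    pairwise_fst,
    population_freq_table,
    posterior_null_freq,
)
from conftest import make_dataset


def quadrature_q(a, b, n, n0):
    """Independent oracle: E[sqrt(x)] under Beta(a + n0, b + n - n0)."""
    from scipy.stats import beta as beta_dist

    post = beta_dist(a + n0, b + n - n0)
    val, _ = integrate.quad(lambda x: np.sqrt(x) * post.pdf(x), 0, 1, limit=200)
    return val


class TestPriorFit:
    def test_moment_equations_hand_case(self):
        # m = 0.5, v = 0.05: k = 0.5*0.5/0.05 - 1 = 4 -> a = b = 2
        p = moment_matched_prior(0.5, 0.05)
        assert (p.a, p.b) == pytest.approx((2.0, 2.0))

    def test_degenerate_variance_falls_back_to_uniform(self):
        ds = make_dataset(np.tile([[0], [1]], (10, 5)))  # identical proportions
        p = fit_phenotype_prior(ds)
        assert (p.a, p.b, p.source) == (1.0, 1.0, "uniform")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.05, 0.95), st.floats(1e-4, 0.2))
    def test_fit_inverts_beta_moments(self, m, v):
        p = moment_matched_prior(m, v)
        if p.source == "uniform":
            assert v >= m * (1 - m) or v <= 1e-12
            return
        mean = p.a / (p.a + p.b)
        var = p.a * p.b / ((p.a + p.b) ** 2 * (p.a + p.b + 1))
        assert mean == pytest.approx(m, abs=1e-10)
        assert var == pytest.approx(v, abs=1e-10)

    def test_single_locus_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_phenotype_prior(make_dataset([[1], [0]]))

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(0.0, 1.0)


class TestBayesianNullFreq:
    def test_closed_form_single_absent_observation(self):
        # uniform prior, n = 1 all absent: q = int sqrt(x) 2x dx = 4/5
        assert posterior_null_freq(1, 1) == pytest.approx(0.8, abs=1e-12)

    def test_closed_form_all_absent_beta_identity(self):
        # B(alpha+1/2, 1)/B(alpha, 1) = alpha/(alpha+1/2) with alpha = 101
        assert posterior_null_freq(100, 100) == pytest.approx(101 / 101.5, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = rng.uniform(0.2, 5, 2)
            n = int(rng.integers(1, 200))
            n0 = int(rng.integers(0, n + 1))
            got = float(posterior_null_freq(n, n0, PriorSpec(a, b)))
            assert got == pytest.approx(quadrature_q(a, b, n, n0), abs=1e-8)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(2, 100))
    def test_monotone_in_absent_count(self, n):
        q = posterior_null_freq(np.full(n + 1, n), np.arange(n + 1))
        assert np.all(np.diff(q) > 0)

    def test_zero_sample_size_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_allele_freq(0, 0)


class TestDiversity:
    def test_plp_counts_minor_allele_frequencies(self):
        # engineered q values straddling the 5% criterion
        from aflpop.allele_freq import PopDiversity

        q = np.array([0.5, 0.04, 0.06])
        maf = np.minimum(q, 1 - q)
        assert np.mean(maf >= 0.05) == pytest.approx(2 / 3)

    def test_hj_limits(self):
        assert hj_per_locus(0.0, 50) == 0.0
        # q = 0.5, large n: approaches the biallelic maximum 0.5
        assert hj_per_locus(0.5, 10_000) == pytest.approx(0.5, abs=1e-4)
        # small-sample correction: 2q(1-q) * 2n/(2n-1)
        assert hj_per_locus(0.5, 5) == pytest.approx(0.5 * 10 / 9)

    def test_diversity_bounds_on_simulated_data(self):
        ds, _ = sim.gen_island(4, 12, 60, 0.05, seed=3)
        out = diversity(ds)
        assert len(out) == 4
        for d in out:
            n = d.n_individuals
            assert 0 <= d.plp <= 1
            assert 0 <= d.hj <= 0.5 * 2 * n / (2 * n - 1)

    def test_hj_invariant_under_locus_relabeling(self):
        ds, _ = sim.gen_unstructured(40, 30, seed=5)
        perm = np.random.default_rng(1).permutation(30)
        ds2 = ds.subset_loci(perm)
        h1 = {d.population_id: d.hj for d in diversity(ds)}
        h2 = {d.population_id: d.hj for d in diversity(ds2)}
        for k in h1:
            assert h1[k] == pytest.approx(h2[k], abs=1e-12)


class TestFst:
    def test_identical_frequencies_give_zero(self):
        import pandas as pd

        rows = []
        for pop in ("A", "B"):
            for l in range(20):
                rows.append((pop, f"L{l}", 0.2 + 0.02 * l, 30, 5))
        freqs = pd.DataFrame(rows, columns=["population_id", "locus_id", "q", "n", "n_absent"])
        tab, glob = pairwise_fst(freqs)
        # identical q: numerator is negative of the sampling correction -> truncated to 0
        assert tab["fst"].iloc[0] == 0.0
        assert glob.fst == 0.0

    def test_fixed_differences_approach_one(self):
        import pandas as pd

        rows = []
        for l in range(20):
            rows.append(("A", f"L{l}", 0.001, 500, 0))
            rows.append(("B", f"L{l}", 0.999, 500, 499))
        freqs = pd.DataFrame(rows, columns=["population_id", "locus_id", "q", "n", "n_absent"])
        tab, _ = pairwise_fst(freqs)
        assert tab["fst"].iloc[0] > 0.98

    def test_linearization_identity_and_monotone(self):
        f = np.linspace(0, 0.9, 50)
        lin = f / (1 - f)
        assert lin[0] == 0.0
        assert np.all(np.diff(lin) > 0)

    def test_island_model_recovery(self):
        ds, _ = sim.gen_island(10, 30, 200, 0.10, seed=1)
        tab, glob = pairwise_fst(population_freq_table(ds))
        assert 0.08 <= glob.fst <= 0.12

    def test_monomorphic_pair_warns_missing(self):
        import pandas as pd

        rows = [("A", "L0", 0.0, 30, 0), ("B", "L0", 0.0, 30, 0)]
        freqs = pd.DataFrame(rows, columns=["population_id", "locus_id", "q", "n", "n_absent"])
        with pytest.warns(UserWarning, match="undefined"):
            tab, _ = pairwise_fst(freqs)
        assert np.isnan(tab["fst"].iloc[0])
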