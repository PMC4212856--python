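import numpy as np
import pytest

from aflpop import simulate as sim
from aflpop.aflp_io import geo_distance_matrix
from aflpop.allele_freq import pooled_null_freqs
from aflpop.kinship import kinship_matrix
from aflpop.sgs import (
    autocorrelogram,
    build_distance_classes,
    mantel_test,
    regression_slope_sp,
    sp_index,
)


@pytest.fixture(scope="module")
def unstructured_sgs():
    ds, truth = sim.gen_unstructured(60, 40, seed=11)
    K = kinship_matrix(ds, pooled_null_freqs(ds))
    D = geo_distance_matrix(ds.samples)
    return ds, K, D


class TestDistanceClasses:
    def test_default_doubling_scheme(self):
        spec = build_distance_classes()
        assert list(spec.upper_edges[:-1]) == [10, 20, 40, 80, 160]
        assert np.isinf(spec.upper_edges[-1])

    @pytest.mark.parametrize(
        "d,klass", [(0.0, 0), (5.0, 1), (10.0, 1), (15.0, 2), (200.0, 6)]
    )
    def test_assignment(self, d, klass):
        spec = build_distance_classes()
        assert spec.assign(np.array([d]))[0] == klass

    def test_pair_counts_sum_to_all_pairs(self, unstructured_sgs):
        ds, K, D = unstructured_sgs
        res = autocorrelogram(K, D, n_perm=9, seed=0)
        n = ds.n_individuals
        assert res.n_pairs.sum() == n * (n - 1) // 2


class TestAutocorrelogram:
    def test_class_mean_matches_direct_loop(self, unstructured_sgs):
        ds, K, D = unstructured_sgs
        spec = build_distance_classes()
        res = autocorrelogram(K, D, spec, n_perm=9, seed=1)
        theta = K.theta
        d = D[K.pair_i, K.pair_j]
        labels = spec.assign(d)
        for k in range(spec.n_classes):
            sel = labels == k
            if sel.any():
                assert res.mean_kinship[k] == pytest.approx(theta[sel].mean())

    def test_jackknife_zero_when_loci_identical(self):
        # duplicate one locus 12 times: per-locus components identical
        rng = np.random.default_rng(2)
        col = (rng.random(30) < 0.75).astype(int)
        from conftest import make_dataset

        ds = make_dataset(np.tile(col[:, None], (1, 12)), patch_of=np.arange(30) % 5)
        K = kinship_matrix(ds, np.full(12, 0.5))
        D = geo_distance_matrix(ds.samples)
        res = autocorrelogram(K, D, n_perm=9, seed=2)
        ok = np.isfinite(res.jackknife_se)
        assert np.allclose(res.jackknife_se[ok], 0.0, atol=1e-12)

    def test_envelope_ordered_and_reproducible(self, unstructured_sgs):
        ds, K, D = unstructured_sgs
        r1 = autocorrelogram(K, D, n_perm=49, seed=7)
        r2 = autocorrelogram(K, D, n_perm=49, seed=7)
        np.testing.assert_array_equal(r1.env_lo, r2.env_lo)
        ok = np.isfinite(r1.env_lo)
        assert np.all(r1.env_lo[ok] <= r1.env_hi[ok])

    def test_label_permutation_flattens_profile(self):
        """Permuting locations leaves the kinship set intact but removes any
        distance association: the observed profile sits inside the envelope."""
        ds, _ = sim.gen_unstructured(80, 60, seed=21)
        K = kinship_matrix(ds, pooled_null_freqs(ds))
        D = geo_distance_matrix(ds.samples)
        perm = np.random.default_rng(3).permutation(ds.n_individuals)
        Dp = D[np.ix_(perm, perm)]
        res = autocorrelogram(K, Dp, n_perm=199, seed=4)
        ok = np.isfinite(res.mean_kinship)
        inside = (res.env_lo[ok] <= res.mean_kinship[ok]) & (
            res.mean_kinship[ok] <= res.env_hi[ok]
        )
        assert inside.mean() >= 0.8


class TestSp:
    def test_sp_worked_example(self):
        # slope -0.0015, first-class kinship 0.0386 -> 0.00156, i.e. 0.0016
        sp = sp_index(-0.0015, 0.0386)
        assert sp == pytest.approx(0.00156, abs=5e-6)
        assert float(f"{sp:.1e}") == pytest.approx(0.0016)

    def test_zero_slope_zero_sp(self):
        assert sp_index(0.0, 0.2) == 0.0

    def test_f1_at_one_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            sp_index(-0.001, 1.0)

    def test_regression_excludes_zero_distance_pairs(self, unstructured_sgs):
        ds, K, D = unstructured_sgs
        res = regression_slope_sp(K, D)
        d = D[K.pair_i, K.pair_j]
        assert res.n_pairs_regression == int(((d > 0) & np.isfinite(K.theta)).sum())
        assert np.isfinite(res.b1) and np.isfinite(res.se_b1) and np.isfinite(res.se_sp)

    def test_all_zero_distances_rejected(self):
        from conftest import make_dataset

        ds = make_dataset(np.tile([[0, 1], [1, 0]], (5, 1)), patch_of=np.zeros(10, int))
        K = kinship_matrix(ds, np.array([0.5, 0.5]))
        D = geo_distance_matrix(ds.samples)
        with pytest.raises(ValueError, match="positive distances"):
            regression_slope_sp(K, D)


class TestMantel:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 100, (6, 6))
        X = (X + X.T) / 2
        np.fill_diagonal(X, 0)
        G = np.log(np.where(X > 0, X, 1.0)) * 2.0  # proportional after the log
        res = mantel_test(G, X, n_perm=99, seed=1, log_geo=True)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_seeded_reproducibility_and_bounds(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 50, (8, 8)); X = (X + X.T) / 2; np.fill_diagonal(X, 0)
        G = rng.uniform(0, 1, (8, 8)); G = (G + G.T) / 2; np.fill_diagonal(G, 0)
        r1 = mantel_test(G, X, n_perm=199, seed=42)
        r2 = mantel_test(G, X, n_perm=199, seed=42)
        assert (r1.r, r1.p) == (r2.r, r2.p)
        assert -1 <= r1.r <= 1 and 0 < r1.p <= 1

    def test_constant_matrix_rejected(self):
        X = np.ones((5, 5)); np.fill_diagonal(X, 0)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(X, X, n_perm=9, seed=0, log_geo=False)

    def test_two_sided_p_at_least_one_sided_for_negative_r(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(1, 50, (7, 7)); X = (X + X.T) / 2; np.fill_diagonal(X, 0)
        G = -X + 60.0; np.fill_diagonal(G, 0)  # strong negative association
        one = mantel_test(G, X, n_perm=199, seed=3)
        two = mantel_test(G, X, n_perm=199, seed=3, two_sided=True)
        assert one.p > 0.5  # one-sided for positive association
        assert two.p < one.p
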