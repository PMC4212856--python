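"""Pairwise multilocus kinship between individuals from dominant phenotypes.

For a biallelic dominant locus with null-allele frequency q, the band-presence
phenotype Y is Bernoulli with P(Y=1) = p = 1 - q**2 under Hardy–Weinberg.  To
first order in the kinship coefficient theta of a non-inbred pair,

    cov(Y_i, Y_j) = 4 theta q p (1 - p) / (1 + q),

so the per-locus moment estimator is the centred cross-product
(Y_i - p)(Y_j - p) divided by the locus weight w = 4 q p (1 - p) / (1 + q),
and the multilocus estimator is the ratio of sums over usable loci,

    theta_hat_ij = sum_l (Y_il - p_l)(Y_jl - p_l) / sum_l w_l.

The estimator is exactly unbiased for relationship classes with no
double-IBD mode (unrelated pairs, parent–offspring); for full sibs the
double-IBD mode inflates the per-locus expectation to (1+3q)/(16q) per unit
weight (positive bias, documented, not corrected).

Per-pair, per-locus numerators are retained so that distance-class means and
regression slopes can be jackknifed over loci without re-estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aflp_io import Dataset

MIN_USABLE_LOCI = 10


def locus_weight(q: np.ndarray, f_adjust: float = 0.0) -> np.ndarray:
    """Covariance of the phenotype pair per unit kinship at one locus.

    With inbreeding adjustment F the band-absence probability becomes
    x = q**2 + F q (1-q) and the first-order covariance per unit theta is
    4 (q (F + (1-F) q)**2 - x**2); at F = 0 this reduces to the classic
    4 q p (1-p) / (1+q).
    """
    q = np.asarray(q, float)
    F = f_adjust
    x = q**2 + F * q * (1.0 - q)
    return 4.0 * (q * (F + (1.0 - F) * q) ** 2 - x**2)


def band_presence_prob(q: np.ndarray, f_adjust: float = 0.0) -> np.ndarray:
    """P(Y = 1) = 1 - q**2 - F q (1 - q)."""
    q = np.asarray(q, float)
    return 1.0 - q**2 - f_adjust * q * (1.0 - q)


def locus_kinship(y_i: int, y_j: int, q: float, f_adjust: float = 0.0):
    """Single-locus kinship components for one pair of phenotypes.

    Returns (numerator, weight) or None when the locus is uninformative
    (q at 0 or 1, zero weight).
    """
    if q <= 0.0 or q >= 1.0:
        return None
    p = float(band_presence_prob(q, f_adjust))
    w = float(locus_weight(q, f_adjust))
    if w <= 0.0:
        return None
    return (y_i - p) * (y_j - p), w


@dataclass
class KinshipMatrix:
    """Pairwise multilocus kinship with per-locus components retained.

    Pairs are stored in upper-triangle order (``pair_i[k] < pair_j[k]``).
    ``numerators`` is (n_pairs, n_loci) with zeros at unused entries;
    ``used`` marks pairwise-complete, informative loci; ``weights`` is the
    per-locus denominator contribution.
    """

    individual_ids: list[str]
    pair_i: np.ndarray
    pair_j: np.ndarray
    numerators: np.ndarray
    used: np.ndarray
    weights: np.ndarray
    locus_ids: list[str]

    @property
    def n_pairs(self) -> int:
        return self.pair_i.size

    @property
    def n_loci_used(self) -> np.ndarray:
        return self.used.sum(axis=1)

    @property
    def theta(self) -> np.ndarray:
        """Multilocus kinship per pair: ratio of sums over usable loci."""
        num = self.numerators.sum(axis=1)
        den = (self.used * self.weights).sum(axis=1)
        return np.divide(num, den, out=np.full(num.shape, np.nan), where=den > 0)

    @property
    def flagged_pairs(self) -> np.ndarray:
        """Pairs with fewer than MIN_USABLE_LOCI informative loci."""
        return self.n_loci_used < MIN_USABLE_LOCI

    def theta_leave_one_out(self) -> np.ndarray:
        """(n_pairs, n_loci) kinship recomputed with each locus deleted."""
        num_tot = self.numerators.sum(axis=1, keepdims=True)
        den_tot = (self.used * self.weights).sum(axis=1, keepdims=True)
        num = num_tot - self.numerators
        den = den_tot - self.used * self.weights
        return np.divide(num, den, out=np.full(num.shape, np.nan), where=den > 0)

    def square(self) -> pd.DataFrame:
        """Symmetric square kinship matrix (NaN diagonal)."""
        n = len(self.individual_ids)
        m = np.full((n, n), np.nan)
        th = self.theta
        m[self.pair_i, self.pair_j] = th
        m[self.pair_j, self.pair_i] = th
        return pd.DataFrame(m, index=self.individual_ids, columns=self.individual_ids)

    def long(self) -> pd.DataFrame:
        """Long-format pair list: i, j, theta, n_loci."""
        ids = np.asarray(self.individual_ids, dtype=object)
        return pd.DataFrame(
            {
                "i": ids[self.pair_i],
                "j": ids[self.pair_j],
                "theta": self.theta,
                "n_loci": self.n_loci_used,
            }
        )


def _components(Y: np.ndarray, q: np.ndarray, pair_i, pair_j, f_adjust: float):
    """Centred cross-products and usable-locus mask for the given pairs."""
    informative = (q > 0.0) & (q < 1.0)
    w = np.where(informative, locus_weight(q, f_adjust), 0.0)
    informative &= w > 0
    p = band_presence_prob(q, f_adjust)
    Yc = Y - p  # NaN propagates missing phenotypes
    num = Yc[pair_i] * Yc[pair_j]
    used = np.isfinite(num) & informative[None, :]
    num = np.where(used, num, 0.0)
    return num, used, w


def kinship_matrix(
    ds: Dataset, null_freqs: np.ndarray, f_adjust: float = 0.0
) -> KinshipMatrix:
    """All-pairs multilocus kinship for a dataset.

    ``null_freqs`` are the per-locus null-allele frequencies estimated on the
    pooled sample (the reference population).  Loci fixed in the reference and
    loci missing in either member of a pair are excluded pair-wise.
    Individuals with no scored phenotypes are excluded with a warning.
    """
    q = np.asarray(null_freqs, float)
    if q.size != ds.n_loci:
        raise ValueError("null_freqs length does not match locus count")
    Y = np.where(ds.matrix.mask, (ds.matrix.phenotypes == 1).astype(float), np.nan)
    keep_ind = ds.matrix.mask.any(axis=1)
    if not keep_ind.all():
        dropped = [i for i, k in zip(ds.matrix.individual_ids, keep_ind) if not k]
        warnings.warn(f"excluding all-missing individuals {dropped}", UserWarning)
    idx = np.flatnonzero(keep_ind)
    Y = Y[idx]
    ids = [ds.matrix.individual_ids[i] for i in idx]
    n = len(ids)
    pair_i, pair_j = np.triu_indices(n, k=1)
    num, used, w = _components(Y, q, pair_i, pair_j, f_adjust)
    return KinshipMatrix(ids, pair_i, pair_j, num, used, w, list(ds.matrix.locus_ids))


def kinship_pairs(
    ds: Dataset, null_freqs: np.ndarray, pairs: np.ndarray, f_adjust: float = 0.0
) -> np.ndarray:
    """Multilocus kinship for designated pairs only (rows of ``pairs``)."""
    q = np.asarray(null_freqs, float)
    pairs = np.asarray(pairs, int)
    Y = np.where(ds.matrix.mask, (ds.matrix.phenotypes == 1).astype(float), np.nan)
    num, used, w = _components(Y, q, pairs[:, 0], pairs[:, 1], f_adjust)
    den = (used * w).sum(axis=1)
    tot = num.sum(axis=1)
    return np.divide(tot, den, out=np.full(tot.shape, np.nan), where=den > 0)
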