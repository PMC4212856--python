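"""Bayesian allele-frequency estimation and summary statistics for dominant loci.

With complete dominance a biallelic locus is seen as band presence/absence
only: band absence is the recessive homozygote, so under Hardy–Weinberg the
band-absence phenotype frequency is x = q**2 where q is the recessive (null)
allele frequency.  Counting bands therefore does not count alleles.  The
estimator used here places a beta prior on x, updates it with the binomial
phenotype counts, and reports q as the posterior mean of sqrt(x):

    x | data ~ Beta(a + n_absent, b + n - n_absent)
    q_hat    = E[sqrt(x)] = B(a + n_absent + 1/2, b + n - n_absent) /
                            B(a + n_absent, b + n - n_absent)

The non-uniform prior is moment-matched to the across-locus spread of
band-absence proportions, anchoring the estimator on the frequency spectrum the
marker panel actually shows (the behaviour popularised for AFLP data by
Zhivotovsky-style estimators).

Diversity is summarised per population as the proportion of polymorphic loci
at a minor-allele-frequency criterion (PLP) and Nei's gene diversity Hj with a
small-sample correction; differentiation as a Weir–Cockerham-style moment FST
combined over loci as a ratio of sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln

from .aflp_io import Dataset


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Beta(a, b) prior on the band-absence phenotype frequency."""

    a: float
    b: float
    source: str = "uniform"  # "uniform" or "moment_matched"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("prior shapes must be finite")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior shapes must be positive")


UNIFORM_PRIOR = PriorSpec(1.0, 1.0, "uniform")


@dataclass
class LocusFreqEstimate:
    locus_id: str
    population_id: str
    q: float  # posterior-mean frequency of the band-absence (null) allele
    n: int  # non-missing sample size
    n_absent: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q outside [0, 1]")
        if self.n_absent > self.n:
            raise ValueError("n_absent exceeds n")


@dataclass
class PopDiversity:
    population_id: str
    n_loci: int
    n_individuals: int
    plp: float  # proportion of loci polymorphic at the MAF criterion
    hj: float  # Nei's gene diversity, averaged over loci
    hj_se: float  # across-locus standard error of Hj
    flagged_small: bool = False


@dataclass
class FstResult:
    label: str  # "popA|popB" or "global"
    fst: float  # moment estimate, truncated at 0
    linearized: float  # fst / (1 - fst)
    n_loci: int


def fit_phenotype_prior(ds: Dataset) -> PriorSpec:
    """Moment-match a beta prior to the across-locus band-absence proportions.

    With across-locus mean m and variance v of the observed band-absence
    proportions, the beta shapes are a = m(m(1-m)/v - 1) and
    b = (1-m)(m(1-m)/v - 1).  Falls back to the uniform prior when the
    variance is degenerate (v ~ 0) or over-dispersed (v >= m(1-m)).
    """
    if ds.n_loci < 2:
        raise InsufficientDataError("need at least 2 loci to fit a prior")
    absent = 1.0 - ds.matrix.band_presence_freq()
    m = float(np.mean(absent))
    v = float(np.var(absent, ddof=1))
    return moment_matched_prior(m, v)


def moment_matched_prior(m: float, v: float) -> PriorSpec:
    """Beta shapes from a mean/variance pair, with the uniform fallback."""
    if v <= 1e-12 or v >= m * (1.0 - m) or m <= 0.0 or m >= 1.0:
        return UNIFORM_PRIOR
    k = m * (1.0 - m) / v - 1.0
    return PriorSpec(m * k, (1.0 - m) * k, "moment_matched")


def posterior_null_freq(n, n_absent, prior: PriorSpec = UNIFORM_PRIOR) -> np.ndarray:
    """Vectorised posterior-mean null-allele frequency E[sqrt(x)].

    Uses the beta-function ratio in log space for numerical stability.
    """
    n = np.asarray(n, dtype=float)
    n0 = np.asarray(n_absent, dtype=float)
    if np.any(n < 1):
        raise InsufficientDataError("sample size must be >= 1")
    if np.any(n0 < 0) or np.any(n0 > n):
        raise ValueError("need 0 <= n_absent <= n")
    a_post = prior.a + n0
    b_post = prior.b + n - n0
    return np.exp(betaln(a_post + 0.5, b_post) - betaln(a_post, b_post))


def estimate_allele_freq(
    n: int, n_absent: int, prior: PriorSpec = UNIFORM_PRIOR,
    locus_id: str = "", population_id: str = "",
) -> LocusFreqEstimate:
    """Estimate the null-allele frequency q at one locus in one population."""
    q = float(posterior_null_freq(n, n_absent, prior))
    return LocusFreqEstimate(locus_id, population_id, q, int(n), int(n_absent))


def population_freq_table(
    ds: Dataset, prior: PriorSpec | None = None, per_population_prior: bool = True
) -> pd.DataFrame:
    """Per-locus, per-population q estimates as a tidy DataFrame.

    Columns: population_id, locus_id, q, n, n_absent.  When ``prior`` is None
    a moment-matched prior is fitted (per population if
    ``per_population_prior``, else once on the pooled sample).
    """
    rows = []
    pooled_prior = prior
    if prior is None and not per_population_prior:
        pooled_prior = fit_phenotype_prior(ds)
    for pid, idx in ds.by_population().items():
        sub = ds.matrix.phenotypes[idx]
        m = sub != -1
        n = m.sum(axis=0)
        n0 = np.where(m, sub == 0, False).sum(axis=0)
        if pooled_prior is None:
            # fit on this population's individuals only
            props = np.divide(n0, n, out=np.full(n.shape, np.nan), where=n > 0)
            props = props[~np.isnan(props)]
            p = moment_matched_prior(float(np.mean(props)), float(np.var(props, ddof=1))) \
                if props.size >= 2 else UNIFORM_PRIOR
        else:
            p = pooled_prior
        ok = n > 0
        q = np.full(ds.n_loci, np.nan)
        q[ok] = posterior_null_freq(n[ok], n0[ok], p)
        for j, lid in enumerate(ds.matrix.locus_ids):
            rows.append((pid, lid, q[j], int(n[j]), int(n0[j])))
    return pd.DataFrame(rows, columns=["population_id", "locus_id", "q", "n", "n_absent"])


def pooled_null_freqs(ds: Dataset, prior: PriorSpec | None = None) -> np.ndarray:
    """Per-locus q estimated on the pooled sample (reference for kinship)."""
    if prior is None:
        prior = fit_phenotype_prior(ds)
    m = ds.matrix.mask
    n = m.sum(axis=0)
    n0 = np.where(m, ds.matrix.phenotypes == 0, False).sum(axis=0)
    return posterior_null_freq(n, n0, prior)


def hj_per_locus(q: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Nei's gene diversity 2q(1-q) with the 2n/(2n-1) small-sample factor."""
    q = np.asarray(q, float)
    n = np.asarray(n, float)
    corr = np.divide(2.0 * n, 2.0 * n - 1.0, out=np.ones_like(n, dtype=float), where=n > 0.5)
    return 2.0 * q * (1.0 - q) * corr


def diversity(
    ds: Dataset, prior: PriorSpec | None = None, maf_threshold: float = 0.05
) -> list[PopDiversity]:
    """Per-population PLP and expected heterozygosity Hj.

    PLP counts loci whose minor *allele* frequency min(q, 1-q) meets the
    threshold; Hj averages the per-locus corrected gene diversity, with its
    across-locus standard error.
    """
    freqs = population_freq_table(ds, prior=prior)
    out = []
    for pid, grp in freqs.groupby("population_id", sort=False):
        grp = grp[grp["n"] > 0]
        q = grp["q"].to_numpy(float)
        n = grp["n"].to_numpy(float)
        maf = np.minimum(q, 1.0 - q)
        plp = float(np.mean(maf >= maf_threshold)) if q.size else float("nan")
        h = hj_per_locus(q, n)
        hj = float(np.mean(h)) if h.size else float("nan")
        se = float(np.std(h, ddof=1) / np.sqrt(h.size)) if h.size > 1 else float("nan")
        n_ind = int(ds.by_population()[pid].size)
        if n_ind < 2:
            warnings.warn(f"population {pid!r} has fewer than 2 individuals", UserWarning)
        out.append(PopDiversity(pid, int(q.size), n_ind, plp, hj, se, n_ind < 2))
    return out


def _fst_components(q: np.ndarray, n: np.ndarray):
    """Weir–Cockerham ANOVA components for one locus across r populations.

    ``q`` are per-population allele frequencies treated as observed from
    2n alleles.  Returns (numerator, denominator) of theta for ratio-of-sums
    combination; (nan, nan) when undefined (monomorphic across populations).
    """
    a = 2.0 * np.asarray(n, float)  # allele counts
    q = np.asarray(q, float)
    r = q.size
    asum = a.sum()
    pbar = float((a * q).sum() / asum)
    if pbar <= 0.0 or pbar >= 1.0 or r < 2 or np.any(a < 2):
        return np.nan, np.nan
    msp = float((a * (q - pbar) ** 2).sum() / (r - 1))
    msg = float((a * q * (1.0 - q)).sum() / (asum - r))
    nc = (asum - (a**2).sum() / asum) / (r - 1)
    num = msp - msg
    den = msp + (nc - 1.0) * msg
    return num, den


def pairwise_fst(
    freqs: pd.DataFrame, populations: list[str] | None = None
) -> tuple[pd.DataFrame, FstResult]:
    """Pairwise and global moment-estimator FST from a per-locus q table.

    ``freqs`` is the tidy table from :func:`population_freq_table`.  Per locus
    the Weir–Cockerham numerator and denominator are computed from the
    population allele frequencies (binomial allele-sampling correction via the
    within-population mean squares); loci are combined as a ratio of sums.
    Negative estimates are truncated at 0 and the linearised form
    FST/(1-FST) is attached.

    Returns (pairwise table with columns pop_a, pop_b, fst, linearized,
    n_loci) and the global :class:`FstResult` over all populations.
    """
    if populations is None:
        populations = list(pd.unique(freqs["population_id"]))
    if len(populations) < 2:
        raise InsufficientDataError("need at least two populations")
    piv_q = freqs.pivot_table(index="locus_id", columns="population_id", values="q", sort=False)
    piv_n = freqs.pivot_table(index="locus_id", columns="population_id", values="n", sort=False)

    def ratio_of_sums(pops: list[str]) -> tuple[float, int]:
        nums, dens = [], []
        for lid in piv_q.index:
            q = piv_q.loc[lid, pops].to_numpy(float)
            n = piv_n.loc[lid, pops].to_numpy(float)
            ok = np.isfinite(q) & (n > 0)
            if ok.sum() < 2:
                continue
            num, den = _fst_components(q[ok], n[ok])
            if np.isfinite(num) and np.isfinite(den):
                nums.append(num)
                dens.append(den)
        if not dens or sum(dens) == 0:
            return float("nan"), len(dens)
        return sum(nums) / sum(dens), len(dens)

    rows = []
    for i, pa in enumerate(populations):
        for pb in populations[i + 1:]:
            theta, nl = ratio_of_sums([pa, pb])
            if np.isnan(theta):
                warnings.warn(f"FST undefined for pair ({pa}, {pb})", UserWarning)
                rows.append((pa, pb, np.nan, np.nan, nl))
                continue
            fst = max(theta, 0.0)
            lin = fst / (1.0 - fst) if fst < 1.0 else np.inf
            rows.append((pa, pb, fst, lin, nl))
    pair_table = pd.DataFrame(rows, columns=["pop_a", "pop_b", "fst", "linearized", "n_loci"])

    g_theta, g_nl = ratio_of_sums(populations)
    g_fst = max(g_theta, 0.0) if np.isfinite(g_theta) else float("nan")
    g_lin = g_fst / (1.0 - g_fst) if np.isfinite(g_fst) and g_fst < 1.0 else float("nan")
    return pair_table, FstResult("global", g_fst, g_lin, g_nl)


def per_locus_he_fst(freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-locus total gene diversity He and multi-population FST.

    He is 2*qbar*(1-qbar) on the sample-size-weighted mean allele frequency
    (no small-sample factor, so He stays in [0, 0.5]); FST is the
    Weir–Cockerham ratio for that locus alone.  Used by the outlier scan.
    """
    rows = []
    for lid, grp in freqs.groupby("locus_id", sort=False):
        q = grp["q"].to_numpy(float)
        n = grp["n"].to_numpy(float)
        ok = np.isfinite(q) & (n > 0)
        q, n = q[ok], n[ok]
        if q.size < 2:
            rows.append((lid, np.nan, np.nan))
            continue
        qbar = float((n * q).sum() / n.sum())
        he = 2.0 * qbar * (1.0 - qbar)
        num, den = _fst_components(q, n)
        fst = num / den if np.isfinite(den) and den != 0 else np.nan
        rows.append((lid, he, fst))
    return pd.DataFrame(rows, columns=["locus_id", "he", "fst"])
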