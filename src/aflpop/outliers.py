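"""FST-outlier neutrality scan for dominant loci (FDist-style).

Loci under directional selection show more differentiation among populations
than drift alone produces; loci under stabilizing/balancing selection show
less.  The scan simulates a neutral null cloud of (He, FST) pairs under a
Balding–Nichols island model calibrated to the trimmed-mean FST of the
observed loci, with dominant phenotype sampling and re-estimation through the
same Bayesian allele-frequency machinery applied to the real data, then
places each observed locus on the empirical FST distribution of the simulated
points nearest in He.  Loci above the upper quantile cutoff (default 0.99)
are candidates for directional selection, below the lower cutoff (default
0.01) for stabilizing selection; the neutral remainder feeds the downstream
spatial and inbreeding analyses.

Dominant data are intrinsically biallelic, so the classical infinite-alleles
null is approximated by the biallelic Balding–Nichols draw, which reproduces
the conditional FST-versus-He null shape attainable for presence/absence
markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_freq import PriorSpec, UNIFORM_PRIOR, _fst_components, posterior_null_freq

DEFAULT_ITERATIONS = 50_000


@dataclass
class NullCloud:
    """Simulated neutral (He, FST) pairs conditional on the study design."""

    he: np.ndarray
    fst: np.ndarray
    target_fst: float
    sample_sizes: np.ndarray
    n_demes: int
    seed: int | None = None

    @property
    def iterations(self) -> int:
        return self.he.size

    def save(self, path: Path | str) -> None:
        np.savez_compressed(
            path, he=self.he, fst=self.fst, target_fst=self.target_fst,
            sample_sizes=self.sample_sizes, n_demes=self.n_demes,
        )

    @classmethod
    def load(cls, path: Path | str) -> "NullCloud":
        z = np.load(path)
        return cls(
            z["he"], z["fst"], float(z["target_fst"]), z["sample_sizes"],
            int(z["n_demes"]),
        )


def trimmed_mean_fst(fst: np.ndarray, central: float = 0.70) -> float:
    """Mean of the central ``central`` fraction of finite per-locus FSTs."""
    v = np.sort(np.asarray(fst, float)[np.isfinite(fst)])
    if v.size == 0:
        raise ValueError("no finite per-locus FST values")
    k = int(np.floor(v.size * (1.0 - central) / 2.0))
    core = v[k: v.size - k] if v.size - 2 * k > 0 else v
    return float(np.mean(core))


def simulate_null_cloud(
    target_fst: float,
    sample_sizes,
    n_demes: int = 100,
    iterations: int = DEFAULT_ITERATIONS,
    prior: PriorSpec = UNIFORM_PRIOR,
    seed: int | None = None,
    batch: int = 20_000,
) -> NullCloud:
    """Simulate the neutral (He, FST) cloud for one study design.

    Per iteration one locus is simulated: an ancestral band-absence frequency
    is drawn from the fitted prior and mapped to the allele scale
    (q = sqrt(x)); per-sampled-deme frequencies follow the Balding–Nichols
    draw Beta(q(1-F)/F, (1-q)(1-F)/F) (the infinite-island limit, so
    ``n_demes`` is nominal); dominant phenotypes are sampled binomially at
    the observed per-deme sample sizes; allele frequencies are re-estimated
    through the same Bayesian estimator as the data; He and single-locus FST
    use the same moment machinery.  Iterations yielding an undefined FST
    (samples monomorphic across demes) are discarded and replaced.
    """
    if not (0.0 < target_fst < 1.0):
        raise ValueError("target_fst must be in (0, 1)")
    n = np.asarray(sample_sizes, int)
    if n.size < 2 or np.any(n < 1):
        raise ValueError("need >= 2 demes with >= 1 individual each")
    rng = np.random.default_rng(seed)
    F = target_fst
    he_out: list[np.ndarray] = []
    fst_out: list[np.ndarray] = []
    got = 0
    while got < iterations:
        nb = min(batch, 2 * (iterations - got) + 1000)
        x_anc = rng.beta(prior.a, prior.b, size=nb)
        q_anc = np.clip(np.sqrt(x_anc), 1e-4, 1.0 - 1e-4)
        a = q_anc * (1.0 - F) / F
        b = (1.0 - q_anc) * (1.0 - F) / F
        q_d = rng.beta(a[:, None], b[:, None], size=(nb, n.size))
        n_absent = rng.binomial(n[None, :], q_d**2)
        q_hat = posterior_null_freq(
            np.broadcast_to(n[None, :], q_d.shape), n_absent, prior
        )
        he, fst = _he_fst_rows(q_hat, n)
        ok = np.isfinite(fst)
        he_out.append(he[ok])
        fst_out.append(fst[ok])
        got += int(ok.sum())
    he = np.concatenate(he_out)[:iterations]
    fst = np.concatenate(fst_out)[:iterations]
    return NullCloud(he, fst, target_fst, n, n_demes, seed)


def _he_fst_rows(q_hat: np.ndarray, n: np.ndarray):
    """Vectorised per-row He and Weir-Cockerham theta for (iter, demes) q."""
    a = 2.0 * n[None, :].astype(float)
    asum = a.sum()
    r = n.size
    pbar = (a * q_hat).sum(axis=1) / asum
    he = 2.0 * pbar * (1.0 - pbar)
    msp = (a * (q_hat - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (a * q_hat * (1.0 - q_hat)).sum(axis=1) / (asum - r)
    nc = (asum - (a**2).sum() / asum) / (r - 1)
    num = msp - msg
    den = msp + (nc - 1.0) * msg
    fst = np.divide(num, den, out=np.full(num.shape, np.nan), where=den != 0)
    bad = (pbar <= 0.0) | (pbar >= 1.0)
    fst[bad] = np.nan
    return he, fst


def calibrate_null_fst(
    observed_trimmed: float,
    sample_sizes,
    prior: PriorSpec = UNIFORM_PRIOR,
    seed: int | None = None,
    iterations: int = 4000,
    tol: float = 5e-4,
) -> float:
    """Find the island-model FST whose null cloud matches the data.

    The trimmed mean of per-locus FST estimates is strongly attenuated at
    small per-deme sample sizes (Bayesian shrinkage of the deme frequencies
    plus the skew of per-locus ratio estimates), but the attenuation is the
    same for real data and for clouds simulated through the identical
    machinery.  Calibration therefore solves, by bisection, for the
    simulation FST at which the cloud's trimmed-mean estimate equals the
    observed trimmed mean; simulating the production cloud at that value
    reproduces the data's neutral FST distribution.
    """
    lo, hi = 1e-3, 0.8
    rng = np.random.default_rng(seed)

    def cloud_stat(f: float) -> float:
        s = int(rng.integers(2**31))
        c = simulate_null_cloud(f, sample_sizes, iterations=iterations,
                                prior=prior, seed=s)
        return trimmed_mean_fst(c.fst)

    if observed_trimmed <= cloud_stat(lo):
        return lo
    if observed_trimmed >= cloud_stat(hi):
        return hi
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if cloud_stat(mid) < observed_trimmed:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def classify_loci(
    observed: pd.DataFrame,
    cloud: NullCloud,
    upper: float = 0.99,
    lower: float = 0.01,
    k_neighbors: int = 2000,
) -> pd.DataFrame:
    """Place each observed locus on the He-conditional null FST distribution.

    ``observed`` needs columns locus_id, he, fst (from
    :func:`aflpop.allele_freq.per_locus_he_fst`).  Each locus's quantile is
    the fraction of the ``k_neighbors`` simulated points nearest in He whose
    FST lies below the observed one (ties counted half).  Classification:
    quantile > ``upper`` -> directional; quantile < ``lower`` -> stabilizing;
    otherwise neutral.  Monomorphic loci (undefined FST or He ~ 0) are
    excluded from classification and returned with class ``excluded``.
    """
    if cloud.iterations == 0:
        raise ValueError("empty null cloud")
    k = min(k_neighbors, cloud.iterations)
    order = np.argsort(cloud.he, kind="stable")
    he_sorted = cloud.he[order]
    fst_sorted = cloud.fst[order]
    rows = []
    for rec in observed.itertuples(index=False):
        he_o, fst_o = float(rec.he), float(rec.fst) if np.isfinite(rec.fst) else np.nan
        if not np.isfinite(fst_o) or not np.isfinite(he_o) or he_o <= 1e-12:
            rows.append((rec.locus_id, he_o, fst_o, np.nan, "excluded"))
            continue
        # window of the k cloud points nearest in He, via the sorted order
        pos = np.searchsorted(he_sorted, he_o)
        lo = max(0, pos - k)
        hi = min(cloud.iterations, pos + k)
        cand = np.arange(lo, hi)
        dist = np.abs(he_sorted[cand] - he_o)
        nearest = cand[np.argpartition(dist, k - 1)[:k]]
        f = fst_sorted[nearest]
        quant = (np.count_nonzero(f < fst_o) + 0.5 * np.count_nonzero(f == fst_o)) / k
        if quant > upper:
            cls = "directional"
        elif quant < lower:
            cls = "stabilizing"
        else:
            cls = "neutral"
        rows.append((rec.locus_id, he_o, fst_o, quant, cls))
    return pd.DataFrame(rows, columns=["locus_id", "he", "fst", "quantile", "class"])


def neutral_loci(classified: pd.DataFrame) -> list[str]:
    """Locus ids retained for downstream analyses (flagged loci removed)."""
    keep = classified["class"].isin(["neutral", "excluded"])
    return classified.loc[keep, "locus_id"].tolist()
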