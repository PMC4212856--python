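"""Spatial genetic structure: correlograms, Sp statistic, and Mantel test.

Under isolation by distance at drift–dispersal equilibrium, pairwise kinship
declines approximately linearly with the logarithm of geographic distance.
This module bins pairwise kinship into doubling distance classes (the first
class reserved for within-patch pairs at distance 0), attaches permutation
envelopes under the null hypothesis of randomly distributed genotypes and
jackknife-over-loci standard errors, fits the log-linear regression of
kinship on ln(distance), and summarises the intensity of structure as

    Sp = -b1 / (1 - f1)

where b1 is the regression slope and f1 the mean kinship of the first
distance class.  A matrix-correlation (Mantel) permutation test between
population-level genetic and geographic distances is included for the
population-based view of the same question.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix


@dataclass(frozen=True)
class DistanceClassSpec:
    """Distance classes: {0}, (0, w], (w, 2w], (2w, 4w], ... , (last, inf).

    ``upper_edges`` excludes the reserved zero class and ends with inf.
    """

    upper_edges: tuple
    doubling: bool = True

    def __post_init__(self) -> None:
        e = np.asarray(self.upper_edges, float)
        if e.size < 1 or np.any(np.diff(e) <= 0):
            raise ValueError("class edges must be strictly increasing")
        if not np.isinf(e[-1]):
            raise ValueError("final class must be open-ended (inf)")

    @property
    def n_classes(self) -> int:
        return len(self.upper_edges) + 1  # + the zero class

    def labels(self) -> list[str]:
        lab = ["0 (within patch)"]
        lo = 0.0
        for up in self.upper_edges:
            lab.append(f"({lo:g}, {up:g}]" if np.isfinite(up) else f">{lo:g}")
            lo = up
        return lab

    def assign(self, d: np.ndarray) -> np.ndarray:
        """Class index per distance: 0 for d == 0, then interval membership."""
        d = np.asarray(d, float)
        edges = np.asarray(self.upper_edges, float)
        idx = np.searchsorted(edges, d, side="left") + 1
        idx[d == 0.0] = 0
        return idx


def build_distance_classes(first_width_km: float = 10.0, n_classes: int = 6) -> DistanceClassSpec:
    """Doubling distance classes; defaults give {0, 10, 20, 40, 80, 160, >160} km."""
    if first_width_km <= 0:
        raise ValueError("first_width_km must be positive")
    edges = [first_width_km * 2.0**k for k in range(n_classes - 1)]
    edges.append(np.inf)
    return DistanceClassSpec(tuple(edges))


@dataclass
class AutocorrResult:
    """Per-distance-class mean kinship with null envelope and jackknife SE."""

    classes: DistanceClassSpec
    mean_kinship: np.ndarray
    n_pairs: np.ndarray
    jackknife_se: np.ndarray
    env_lo: np.ndarray
    env_hi: np.ndarray
    n_permutations: int
    perm_means: np.ndarray | None = None  # (n_perm, n_classes), optional

    def to_frame(self) -> pd.DataFrame:
        lowers = np.concatenate([[0.0], [0.0], np.asarray(self.classes.upper_edges)[:-1]])
        uppers = np.concatenate([[0.0], np.asarray(self.classes.upper_edges)])
        return pd.DataFrame(
            {
                "class": self.classes.labels(),
                "class_lower_km": lowers,
                "class_upper_km": uppers,
                "n_pairs": self.n_pairs,
                "mean_kinship": self.mean_kinship,
                "jackknife_se": self.jackknife_se,
                "env_lo": self.env_lo,
                "env_hi": self.env_hi,
            }
        )


@dataclass
class SpResult:
    """Log-linear regression slope and the Sp intensity-of-structure index."""

    b1: float
    se_b1: float
    f1: float
    sp: float
    se_sp: float
    n_pairs_regression: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    two_sided: bool = False


def _pair_distances(K: KinshipMatrix, D: np.ndarray) -> np.ndarray:
    return D[K.pair_i, K.pair_j]


def _class_means(theta: np.ndarray, labels: np.ndarray, n_classes: int):
    counts = np.bincount(labels, minlength=n_classes)
    ok = np.isfinite(theta)
    sums = np.bincount(labels[ok], weights=theta[ok], minlength=n_classes)
    counts_ok = np.bincount(labels[ok], minlength=n_classes)
    means = np.divide(sums, counts_ok, out=np.full(n_classes, np.nan), where=counts_ok > 0)
    return means, counts


def autocorrelogram(
    K: KinshipMatrix,
    D: np.ndarray,
    classes: DistanceClassSpec | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
    keep_perm_means: bool = False,
) -> AutocorrResult:
    """Distance-class kinship means with permutation envelope and jackknife SE.

    The null envelope permutes individual spatial locations (a joint
    permutation of the rows and columns of ``D`` against the fixed kinship
    matrix); per-class 2.5th/97.5th percentiles of the permuted means form
    the 95% envelope.  Jackknife standard errors delete one locus at a time
    and recompute every pairwise kinship from the stored per-locus
    components: SE_k = sqrt((L-1)/L * sum_l (fbar_(-l),k - fbar_(.),k)^2).
    """
    if classes is None:
        classes = build_distance_classes()
    n = len(K.individual_ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix does not match kinship individuals")
    nc = classes.n_classes
    d = _pair_distances(K, D)
    labels = classes.assign(d)
    theta = K.theta
    means, counts = _class_means(theta, labels, nc)
    if (counts == 0).any():
        empty = [lab for lab, c in zip(classes.labels(), counts) if c == 0]
        warnings.warn(f"empty distance classes: {empty}", UserWarning)

    # jackknife over loci
    loo = K.theta_leave_one_out()  # (n_pairs, L)
    L = loo.shape[1]
    jk = np.full(nc, np.nan)
    if L > 1:
        cls_means_loo = np.full((L, nc), np.nan)
        for k in range(nc):
            in_k = labels == k
            if not in_k.any():
                continue
            block = loo[in_k]  # (n_k, L)
            cls_means_loo[:, k] = np.nanmean(block, axis=0)
        center = np.nanmean(cls_means_loo, axis=0)
        jk = np.sqrt((L - 1) / L * np.nansum((cls_means_loo - center) ** 2, axis=0))
        jk[counts == 0] = np.nan

    # permutation envelope
    rng = np.random.default_rng(seed)
    perm_means = np.full((n_perm, nc), np.nan)
    for t in range(n_perm):
        perm = rng.permutation(n)
        dp = D[perm[K.pair_i], perm[K.pair_j]]
        lab_p = classes.assign(dp)
        perm_means[t], _ = _class_means(theta, lab_p, nc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
        env_lo = np.nanpercentile(perm_means, 2.5, axis=0)
        env_hi = np.nanpercentile(perm_means, 97.5, axis=0)
    return AutocorrResult(
        classes, means, counts, jk, env_lo, env_hi, n_perm,
        perm_means if keep_perm_means else None,
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ y / (xc @ xc))


def regression_slope_sp(
    K: KinshipMatrix, D: np.ndarray, f1: float | None = None
) -> SpResult:
    """OLS slope of pairwise kinship on ln(distance) and the Sp index.

    Within-patch pairs (distance 0) are excluded from the regression
    (ln 0 undefined) but define f1, the first-class mean kinship, unless an
    ``f1`` value is supplied.  Standard errors for both the slope and Sp are
    jackknifed over loci.
    """
    d = _pair_distances(K, D)
    theta = K.theta
    pos = (d > 0) & np.isfinite(theta)
    if np.unique(d[pos]).size < 2:
        raise ValueError("need >= 2 distinct positive distances for the regression")
    x = np.log(d[pos])
    b1 = _ols_slope(x, theta[pos])
    if f1 is None:
        at0 = (d == 0) & np.isfinite(theta)
        f1 = float(theta[at0].mean()) if at0.any() else float("nan")
    sp = sp_index(b1, f1)

    loo = K.theta_leave_one_out()
    L = loo.shape[1]
    se_b1 = se_sp = float("nan")
    if L > 1:
        xc = x - x.mean()
        denom = xc @ xc
        b_loo = (xc @ loo[pos]) / denom  # (L,)
        se_b1 = float(np.sqrt((L - 1) / L * np.nansum((b_loo - np.nanmean(b_loo)) ** 2)))
        at0 = d == 0
        if at0.any():
            f1_loo = np.nanmean(loo[at0], axis=0)
        else:
            f1_loo = np.full(L, f1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sp_loo = -b_loo / (1.0 - f1_loo)
        se_sp = float(np.sqrt((L - 1) / L * np.nansum((sp_loo - np.nanmean(sp_loo)) ** 2)))
    return SpResult(b1, se_b1, float(f1), sp, se_sp, int(pos.sum()))


def sp_index(b1: float, f1: float) -> float:
    """Sp = -b1 / (1 - f1); undefined at f1 >= 1."""
    if f1 >= 1.0:
        raise ValueError("Sp undefined for first-class kinship >= 1")
    return -b1 / (1.0 - f1)


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    G: np.ndarray,
    X: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    log_geo: bool = True,
    two_sided: bool = False,
) -> MantelResult:
    """Permutation test of matrix correlation between distance matrices.

    ``G`` is the genetic distance matrix (conventionally linearised FST,
    FST/(1-FST)); ``X`` the geographic distances, log-transformed when
    ``log_geo``.  r is the Pearson correlation over off-diagonal
    upper-triangle entries; the p-value permutes the rows/columns of ``X``
    jointly, one-sided for positive association by default:
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    G = np.asarray(G, float)
    X = np.asarray(X, float)
    if G.shape != X.shape or G.shape[0] != G.shape[1] or G.shape[0] < 3:
        raise ValueError("need square matrices of equal dimension >= 3")
    if log_geo:
        with np.errstate(divide="ignore"):
            X = np.where(X > 0, np.log(X), np.nan)
            np.fill_diagonal(X, 0.0)
    g = _upper(G)
    x = _upper(X)
    ok = np.isfinite(g) & np.isfinite(x)
    g, keep = g[ok], ok
    if np.std(g) == 0 or np.std(x[keep]) == 0:
        raise ValueError("constant matrix: correlation undefined")
    r_obs = float(np.corrcoef(g, x[keep])[0, 1])

    n = G.shape[0]
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = X[perm[iu[0]], perm[iu[1]]]
        okp = np.isfinite(_upper(G)) & np.isfinite(xp)
        gp = _upper(G)[okp]
        xpp = xp[okp]
        if np.std(xpp) == 0:
            continue
        r_p = float(np.corrcoef(gp, xpp)[0, 1])
        if two_sided:
            count += abs(r_p) >= abs(r_obs)
        else:
            count += r_p >= r_obs
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, two_sided)
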