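"""Seeded generators of dominant-marker datasets with known truth.

Every generator returns a ``(Dataset, TruthRecord)`` pair: the dataset in the
same form as real data (band presence/absence phenotypes plus patch
coordinates), the truth record carrying whatever latent quantities the
generator controlled (allele frequencies, FST, pairwise kinship, individual
inbreeding coefficients, landscape parameters) so downstream estimators can
be validated against known values.

The generators emulate the sampling design of fungivorous-beetle AFLP
surveys: a few individuals (3–15) per habitat patch (sporocarp), patches
scattered over a ~300 x 300 km landscape, biallelic loci observed as dominant
phenotypes (band absent = homozygous null).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aflp_io import Dataset, DominantMatrix, SampleTable

_ORIGIN_LAT = 50.0
_ORIGIN_LON = 20.0
_KM_PER_DEG = 111.1949  # meridian km per degree at the mean Earth radius


@dataclass
class TruthRecord:
    """Latent truth serialised alongside every generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    q_loci: list | None = None  # per-locus null-allele frequencies
    q_demes: list | None = None  # per-deme per-locus frequencies
    target_fst: float | None = None
    pair_kinship: list | None = None  # [(id_i, id_j, theta), ...]
    fi: dict | None = None  # individual_id -> inbreeding coefficient

    def to_dict(self) -> dict:
        out = {"generator": self.generator, "seed": self.seed, "params": self.params}
        for k in ("q_loci", "q_demes", "target_fst", "pair_kinship", "fi"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def km_to_latlon(xy_km: np.ndarray) -> np.ndarray:
    """Map planar km offsets in a small region to (lat, lon) degrees."""
    lat = _ORIGIN_LAT + xy_km[:, 1] / _KM_PER_DEG
    lon = _ORIGIN_LON + xy_km[:, 0] / (_KM_PER_DEG * np.cos(np.radians(_ORIGIN_LAT)))
    return np.column_stack([lat, lon])


def _dataset_from_phenotypes(
    pheno: np.ndarray, patch_of: np.ndarray, patch_xy_km: np.ndarray
) -> Dataset:
    n, L = pheno.shape
    ind_ids = [f"I{i:05d}" for i in range(n)]
    locus_ids = [f"L{j:04d}" for j in range(L)]
    coords = km_to_latlon(patch_xy_km[patch_of])
    table = pd.DataFrame(
        {
            "individual_id": ind_ids,
            "patch_id": [f"P{p:03d}" for p in patch_of],
            "lat": coords[:, 0],
            "lon": coords[:, 1],
        }
    )
    return Dataset(DominantMatrix(ind_ids, locus_ids, pheno.astype(np.int8)), SampleTable(table))


def _hw_phenotypes(rng: np.random.Generator, q: np.ndarray, n: int) -> np.ndarray:
    """Band presence (1) / absence (0) under Hardy-Weinberg: P(absent) = q**2."""
    return (rng.random((n, q.size)) >= q[None, :] ** 2).astype(np.int8)


def gen_unstructured(
    n: int = 100,
    L: int = 100,
    q_dist: tuple[float, float] = (1.5, 1.5),
    seed: int = 0,
    n_patches: int = 15,
    extent_km: float = 300.0,
) -> tuple[Dataset, TruthRecord]:
    """Panmictic null model: one gene pool, random patch locations.

    Null-allele frequencies are Beta(*q_dist*) draws; genotypes are
    Hardy–Weinberg; individuals are assigned round-robin to ``n_patches``
    patches placed uniformly at random on an ``extent_km`` square.
    """
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 and L >= 1")
    rng = np.random.default_rng(seed)
    q = rng.beta(*q_dist, size=L)
    pheno = _hw_phenotypes(rng, q, n)
    patch_xy = rng.uniform(0, extent_km, size=(n_patches, 2))
    patch_of = np.arange(n) % n_patches
    ds = _dataset_from_phenotypes(pheno, patch_of, patch_xy)
    truth = TruthRecord(
        "gen_unstructured", seed,
        {"n": n, "L": L, "q_dist": list(q_dist), "n_patches": n_patches,
         "extent_km": extent_km},
        q_loci=q.tolist(), target_fst=0.0,
    )
    return ds, truth


def gen_island(
    n_demes: int = 10,
    n_per_deme: int = 30,
    L: int = 200,
    target_fst: float = 0.10,
    seed: int = 0,
    extent_km: float = 300.0,
) -> tuple[Dataset, TruthRecord]:
    """Island model via Balding–Nichols deme frequencies.

    Ancestral null-allele frequencies are U(0.1, 0.9); each deme draws
    q_d ~ Beta(q(1-F)/F, (1-q)(1-F)/F) with F = ``target_fst``, giving
    across-deme variance F q (1 - q); phenotypes are Hardy–Weinberg within
    demes.  Each deme is one patch at a random landscape position.
    """
    if not (0.0 < target_fst < 1.0):
        raise ValueError("target_fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    q_anc = rng.uniform(0.1, 0.9, size=L)
    F = target_fst
    a = q_anc * (1.0 - F) / F
    b = (1.0 - q_anc) * (1.0 - F) / F
    q_demes = rng.beta(a[None, :], b[None, :], size=(n_demes, L))
    phenos = [_hw_phenotypes(rng, q_demes[d], n_per_deme) for d in range(n_demes)]
    pheno = np.concatenate(phenos, axis=0)
    patch_of = np.repeat(np.arange(n_demes), n_per_deme)
    patch_xy = rng.uniform(0, extent_km, size=(n_demes, 2))
    ds = _dataset_from_phenotypes(pheno, patch_of, patch_xy)
    truth = TruthRecord(
        "gen_island", seed,
        {"n_demes": n_demes, "n_per_deme": n_per_deme, "L": L, "extent_km": extent_km},
        q_loci=q_anc.tolist(), q_demes=q_demes.tolist(), target_fst=target_fst,
    )
    return ds, truth


_TRUE_KINSHIP = {"unrelated": 0.0, "parent_offspring": 0.25, "full_sib": 0.25, "self": 0.5}


def gen_related_pairs(
    n_pairs: int,
    L: int = 100,
    relationship: str = "unrelated",
    seed: int = 0,
) -> tuple[Dataset, TruthRecord]:
    """Pairs of a fixed relationship class by Mendelian transmission.

    Null-allele frequencies are U(0.1, 0.9) shared by all pairs (one common
    gene pool); founders are Hardy–Weinberg and relatives are built by gamete
    draws.  The truth record lists each generated pair with its pedigree
    kinship (0, 0.25, 0.25, 0.5 for unrelated, parent–offspring, full-sib,
    self).
    """
    if relationship not in _TRUE_KINSHIP:
        raise ValueError(f"unknown relationship {relationship!r}")
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.1, 0.9, size=L)
    shape = (n_pairs, L)

    def draw_allele():  # 1 = null allele
        return (rng.random(shape) < q[None, :]).astype(np.int8)

    if relationship == "unrelated":
        g1 = draw_allele() + draw_allele()
        g2 = draw_allele() + draw_allele()
    elif relationship == "parent_offspring":
        pa, pb = draw_allele(), draw_allele()
        g1 = pa + pb  # the parent
        transmit = np.where(rng.random(shape) < 0.5, pa, pb)
        g2 = transmit + draw_allele()
    elif relationship == "full_sib":
        pa, pb = draw_allele(), draw_allele()  # parent 1
        ma, mb = draw_allele(), draw_allele()  # parent 2
        def gamete(x, y):
            return np.where(rng.random(shape) < 0.5, x, y)
        g1 = gamete(pa, pb) + gamete(ma, mb)
        g2 = gamete(pa, pb) + gamete(ma, mb)
    else:  # self: the same individual sampled twice
        g1 = draw_allele() + draw_allele()
        g2 = g1
    pheno = np.empty((2 * n_pairs, L), dtype=np.int8)
    pheno[0::2] = (g1 < 2).astype(np.int8)  # band present unless both alleles null
    pheno[1::2] = (g2 < 2).astype(np.int8)
    patch_of = np.arange(2 * n_pairs) // 2  # each pair its own patch
    patch_xy = rng.uniform(0, 300.0, size=(n_pairs, 2))
    ds = _dataset_from_phenotypes(pheno, patch_of, patch_xy)
    theta = _TRUE_KINSHIP[relationship]
    pairs = [(f"I{2*k:05d}", f"I{2*k+1:05d}", theta) for k in range(n_pairs)]
    truth = TruthRecord(
        "gen_related_pairs", seed,
        {"n_pairs": n_pairs, "L": L, "relationship": relationship},
        q_loci=q.tolist(), pair_kinship=pairs,
    )
    return ds, truth


def gen_inbred(
    n: int = 150,
    L: int = 80,
    f_mean: float = 0.15,
    f_shape: float = 10.0,
    seed: int = 0,
) -> tuple[Dataset, TruthRecord]:
    """Individuals with beta-distributed inbreeding coefficients.

    Fi ~ Beta(f_mean * f_shape, (1 - f_mean) * f_shape), so E[Fi] = f_mean and
    ``f_shape`` is the concentration.  Band absence occurs with probability
    q**2 + Fi q (1 - q) per locus; null-allele frequencies are U(0.1, 0.9).
    """
    if not (0.0 < f_mean < 1.0):
        raise ValueError("f_mean must be in (0, 1)")
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.1, 0.9, size=L)
    fi = rng.beta(f_mean * f_shape, (1.0 - f_mean) * f_shape, size=n)
    p_absent = q[None, :] ** 2 + fi[:, None] * q[None, :] * (1.0 - q[None, :])
    pheno = (rng.random((n, L)) >= p_absent).astype(np.int8)
    n_patches = max(1, n // 10)
    patch_of = np.arange(n) % n_patches
    patch_xy = rng.uniform(0, 300.0, size=(n_patches, 2))
    ds = _dataset_from_phenotypes(pheno, patch_of, patch_xy)
    truth = TruthRecord(
        "gen_inbred", seed,
        {"n": n, "L": L, "f_mean": f_mean, "f_shape": f_shape},
        q_loci=q.tolist(),
        fi={f"I{i:05d}": float(fi[i]) for i in range(n)},
    )
    return ds, truth


def gen_ibd_landscape(
    grid: int = 20,
    N_deme: int = 50,
    m: float = 0.01,
    generations: int = 200,
    L: int = 100,
    n_patches_sampled: int = 15,
    n_per_patch: int = 8,
    seed: int = 0,
    extent_km: float = 300.0,
) -> tuple[Dataset, TruthRecord]:
    """Forward-time stepping-stone drift–migration simulation on a lattice.

    A ``grid`` x ``grid`` torus of demes of ``N_deme`` diploids starts from a
    common ancestral pool (null-allele frequencies U(0.1, 0.9)).  Each
    generation a fraction ``m`` of each deme's gene pool is replaced by the
    mean of its four lattice neighbours, then binomial drift over 2N alleles
    applies.  ``m = 1`` is interpreted as unrestricted dispersal: the migrant
    pool is the lattice-wide mean (full mixing each generation, the panmictic
    control).  Sampled patches are lattice nodes mapped onto an
    ``extent_km`` square; individuals are Hardy–Weinberg within their deme.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must be in [0, 1]")
    if generations < 1:
        raise ValueError("need generations >= 1")
    rng = np.random.default_rng(seed)
    q = np.broadcast_to(rng.uniform(0.1, 0.9, size=L), (grid, grid, L)).copy()
    two_n = 2 * N_deme
    for _ in range(generations):
        # drift within demes, then migrant mixing forms the next gene pool
        # (so m = 1 yields a fully mixed pool at sampling: true panmixia)
        qd = rng.binomial(two_n, q) / two_n
        if m == 1.0:
            q = np.broadcast_to(qd.mean(axis=(0, 1)), q.shape).copy()
        else:
            nb = (
                np.roll(qd, 1, axis=0) + np.roll(qd, -1, axis=0)
                + np.roll(qd, 1, axis=1) + np.roll(qd, -1, axis=1)
            ) / 4.0
            q = (1.0 - m) * qd + m * nb

    nodes = rng.choice(grid * grid, size=n_patches_sampled, replace=False)
    node_ij = np.column_stack(np.unravel_index(nodes, (grid, grid)))
    spacing = extent_km / grid
    patch_xy = (node_ij + 0.5) * spacing
    phenos, patch_of = [], []
    for k, (i, j) in enumerate(node_ij):
        phenos.append(_hw_phenotypes(rng, q[i, j], n_per_patch))
        patch_of.extend([k] * n_per_patch)
    ds = _dataset_from_phenotypes(np.concatenate(phenos), np.asarray(patch_of), patch_xy)
    truth = TruthRecord(
        "gen_ibd_landscape", seed,
        {"grid": grid, "N_deme": N_deme, "m": m, "generations": generations,
         "L": L, "n_patches_sampled": n_patches_sampled, "n_per_patch": n_per_patch,
         "extent_km": extent_km, "sampled_nodes": node_ij.tolist()},
        q_demes=q[node_ij[:, 0], node_ij[:, 1]].tolist(),
    )
    return ds, truth
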