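"""Data model and I/O for dominant presence/absence marker datasets.

Dominant multilocus fingerprints (AFLPs and similar) score each individual at
each locus as band present (1) or band absent (0); band absence corresponds to
the homozygous recessive genotype, so the underlying allele frequencies are
latent.  This module defines the binary genotype matrix, the sample/geography
table, TSV readers and writers, the low/high-frequency locus filter, and
great-circle geographic distances between sampling patches.

File formats
------------
Genotype TSV: first column ``individual_id``, one column per locus, cells in
``{0, 1, ?}`` where ``?`` marks a missing (unscored) phenotype.  Sample TSV:
columns ``individual_id``, ``patch_id``, ``lat``, ``lon`` (decimal degrees,
WGS84).  Both files are UTF-8, tab-delimited; lines starting with ``#`` are
ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # internal code for an unscored phenotype
MISSING_SYMBOL = "?"

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


class FormatError(ValueError):
    """Raised when an input file violates the documented TSV dialect."""


class ConsistencyError(ValueError):
    """Raised when genotype and sample tables disagree or invariants fail."""


@dataclass
class DominantMatrix:
    """Individuals x loci band-presence phenotypes with a missing mask.

    ``phenotypes`` is an int8 array with values 1 (band present), 0 (band
    absent) and :data:`MISSING` (unscored).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        n, L = self.phenotypes.shape
        if len(self.individual_ids) != n or len(self.locus_ids) != L:
            raise ConsistencyError("phenotype matrix shape does not match id lists")
        if len(set(self.individual_ids)) != n:
            raise ConsistencyError("duplicate individual_id")
        if len(set(self.locus_ids)) != L:
            raise ConsistencyError("duplicate locus_id")
        bad = ~np.isin(self.phenotypes, [0, 1, MISSING])
        if bad.any():
            raise FormatError("phenotype codes must be 0, 1 or missing")
        if L and (self.phenotypes == MISSING).all(axis=0).any():
            raise ConsistencyError("locus with no non-missing entries")

    @property
    def n_individuals(self) -> int:
        return self.phenotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.phenotypes.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the phenotype was scored."""
        return self.phenotypes != MISSING

    def band_presence_freq(self) -> np.ndarray:
        """Per-locus frequency of band presence among non-missing entries."""
        m = self.mask
        pres = np.where(m, self.phenotypes == 1, False).sum(axis=0)
        return pres / m.sum(axis=0)


@dataclass
class SampleTable:
    """Per-individual patch membership and WGS84 coordinates.

    A *patch* (the sporocarp / habitat patch of the sampling design) is a
    single sampled point: all individuals sharing a ``patch_id`` must carry
    identical coordinates.
    """

    table: pd.DataFrame  # columns: individual_id, patch_id, lat, lon

    def __post_init__(self) -> None:
        req = ["individual_id", "patch_id", "lat", "lon"]
        missing_cols = [c for c in req if c not in self.table.columns]
        if missing_cols:
            raise FormatError(f"sample table missing columns {missing_cols}")
        self.table = self.table[req].reset_index(drop=True)
        if self.table["individual_id"].duplicated().any():
            raise ConsistencyError("duplicate individual_id in sample table")
        lat = self.table["lat"].to_numpy(float)
        lon = self.table["lon"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise FormatError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise FormatError("longitude outside [-180, 180]")
        for pid, grp in self.table.groupby("patch_id"):
            if grp[["lat", "lon"]].drop_duplicates().shape[0] > 1:
                raise ConsistencyError(
                    f"patch {pid!r} has individuals at different coordinates"
                )

    @property
    def individual_ids(self) -> list[str]:
        return self.table["individual_id"].tolist()

    @property
    def patch_ids(self) -> np.ndarray:
        return self.table["patch_id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lat, lon) in decimal degrees."""
        return self.table[["lat", "lon"]].to_numpy(float)


@dataclass
class Dataset:
    """A genotype matrix plus its sample table, row-aligned."""

    matrix: DominantMatrix
    samples: SampleTable
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples.individual_ids != self.matrix.individual_ids:
            raise ConsistencyError(
                "sample table row order does not match genotype matrix"
            )

    @property
    def n_individuals(self) -> int:
        return self.matrix.n_individuals

    @property
    def n_loci(self) -> int:
        return self.matrix.n_loci

    def subset_loci(self, keep: np.ndarray | list) -> "Dataset":
        """Return a new Dataset restricted to the given locus indices/mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        mat = DominantMatrix(
            individual_ids=list(self.matrix.individual_ids),
            locus_ids=[self.matrix.locus_ids[i] for i in keep],
            phenotypes=self.matrix.phenotypes[:, keep],
        )
        return Dataset(matrix=mat, samples=self.samples, meta=dict(self.meta))

    def by_population(self) -> dict[str, np.ndarray]:
        """Map patch_id -> row indices of its individuals."""
        out: dict[str, np.ndarray] = {}
        pids = self.samples.patch_ids
        for pid in pd.unique(pids):
            out[pid] = np.flatnonzero(pids == pid)
        return out


def _read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_dataset(genotype_path: Path | str, sample_path: Path | str) -> Dataset:
    """Read the genotype and sample TSVs and validate their invariants."""
    geno = _read_tsv(genotype_path)
    if geno.columns[0] != "individual_id":
        raise FormatError("genotype TSV must start with an individual_id column")
    ids = geno["individual_id"].tolist()
    if len(set(ids)) != len(ids):
        raise ConsistencyError("duplicate individual_id in genotype table")
    locus_ids = list(geno.columns[1:])
    cells = geno[locus_ids].to_numpy(str)
    pheno = np.empty(cells.shape, dtype=np.int8)
    for sym, code in (("0", 0), ("1", 1), (MISSING_SYMBOL, MISSING)):
        pheno[cells == sym] = code
    unknown = ~np.isin(cells, ["0", "1", MISSING_SYMBOL])
    if unknown.any():
        bad = sorted(set(cells[unknown].tolist()))
        raise FormatError(f"unknown genotype symbols {bad}")
    matrix = DominantMatrix(ids, locus_ids, pheno)

    samp = _read_tsv(sample_path)
    try:
        samp = samp.astype({"lat": float, "lon": float})
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad sample table: {exc}") from exc
    table = SampleTable(samp)

    geno_set, samp_set = set(ids), set(table.individual_ids)
    if geno_set != samp_set:
        raise ConsistencyError(
            f"individuals only in genotypes: {sorted(geno_set - samp_set)}; "
            f"only in samples: {sorted(samp_set - geno_set)}"
        )
    # align sample rows to genotype order
    aligned = table.table.set_index("individual_id").loc[ids].reset_index()
    return Dataset(matrix=matrix, samples=SampleTable(aligned))


def write_dataset(ds: Dataset, genotype_path: Path | str, sample_path: Path | str) -> None:
    """Write a Dataset back to the two-TSV on-disk form (round-trip safe)."""
    sym = np.empty(ds.matrix.phenotypes.shape, dtype=object)
    sym[ds.matrix.phenotypes == 0] = "0"
    sym[ds.matrix.phenotypes == 1] = "1"
    sym[ds.matrix.phenotypes == MISSING] = MISSING_SYMBOL
    geno = pd.DataFrame(sym, columns=ds.matrix.locus_ids)
    geno.insert(0, "individual_id", ds.matrix.individual_ids)
    geno.to_csv(genotype_path, sep="\t", index=False)
    ds.samples.table.to_csv(sample_path, sep="\t", index=False)


def filter_loci(ds: Dataset, lower: float = 0.03, upper: float = 0.97) -> Dataset:
    """Keep loci whose band-presence frequency f satisfies lower < f < upper.

    Frequencies are computed over non-missing entries only; the inequalities
    are strict, so a locus at exactly ``lower`` or ``upper`` is dropped.
    Dropped locus ids are recorded in ``meta['dropped_loci']``.
    """
    if not (0 <= lower < upper <= 1):
        raise ValueError("need 0 <= lower < upper <= 1")
    f = ds.matrix.band_presence_freq()
    keep = (f > lower) & (f < upper)
    dropped = [lid for lid, k in zip(ds.matrix.locus_ids, keep) if not k]
    if not keep.any():
        warnings.warn("all loci dropped by the frequency filter", UserWarning)
    out = ds.subset_loci(keep)
    out.meta["dropped_loci"] = dropped
    return out


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geo_distance_matrix(samples: SampleTable) -> np.ndarray:
    """Pairwise great-circle distances (km) between individuals.

    Individuals sharing a patch share coordinates, so same-patch pairs are at
    distance exactly 0.
    """
    c = samples.coords
    lat = c[:, 0][:, None]
    lon = c[:, 1][:, None]
    d = haversine_km(lat, lon, lat.T, lon.T)
    np.fill_diagonal(d, 0.0)
    # identical coordinates must give exactly 0, not rounding dust
    same = (lat == lat.T) & (lon == lon.T)
    d[same] = 0.0
    return d
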