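import numpy as np
import pandas as pd
import pytest

from aflpop.aflp_io import Dataset, DominantMatrix, SampleTable


def make_dataset(pheno, patch_of=None, coords=None, ids=None, locus_ids=None):
    """Build a Dataset from a phenotype array and optional geography."""
    pheno = np.asarray(pheno, dtype=np.int8)
    n, L = pheno.shape
    ids = ids or [f"I{i:03d}" for i in range(n)]
    locus_ids = locus_ids or [f"L{j:03d}" for j in range(L)]
    if patch_of is None:
        patch_of = np.zeros(n, int)
    patch_of = np.asarray(patch_of)
    if coords is None:
        coords = np.column_stack([50.0 + 0.1 * patch_of, 20.0 + 0.1 * patch_of])
    else:
        coords = np.asarray(coords, float)
    table = pd.DataFrame(
        {
            "individual_id": ids,
            "patch_id": [f"P{p}" for p in patch_of],
            "lat": coords[:, 0],
            "lon": coords[:, 1],
        }
    )
    return Dataset(DominantMatrix(ids, locus_ids, pheno), SampleTable(table))


@pytest.fixture
def tiny_dataset():
    """3 individuals x 2 loci, two patches, no missing data."""
    return make_dataset(
        [[1, 0], [0, 1], [1, 1]], patch_of=[0, 0, 1],
    )


@pytest.fixture
def empty_locus_dataset():
    """30 individuals, zero loci: the likelihood-free MCMC edge case."""
    return make_dataset(np.zeros((30, 0)))
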