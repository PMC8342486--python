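import numpy as np
import pytest

from episcan.genotype_io import GenotypeMatrix, PhenotypeVector, encode_cohorts


def random_dataset(rng, n_samples, n_snvs):
    """Random genotypes and labels with both cohorts guaranteed non-empty."""
    geno = rng.integers(0, 3, size=(n_samples, n_snvs), dtype=np.uint8)
    while True:
        labels = rng.integers(0, 2, size=n_samples, dtype=np.uint8)
        if 0 < labels.sum() < n_samples:
            break
    matrix = GenotypeMatrix(
        snv_ids=tuple(f"snv{i}" for i in range(n_snvs)), genotypes=geno
    )
    return matrix, PhenotypeVector(labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    """200 samples x 6 SNVs of random genotypes, mixed cohorts."""
    return random_dataset(rng, 200, 6)


@pytest.fixture
def small_cohorts(small_dataset):
    matrix, phenotype = small_dataset
    return encode_cohorts(matrix, phenotype)
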