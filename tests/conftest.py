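import numpy as np
import pytest

from snplp import CASE, CONTROL, MISSING, GenotypeDataset


@pytest.fixture
def five_by_two() -> GenotypeDataset:
    """Five samples x two SNPs with every genotype state observed."""
    return GenotypeDataset(
        sample_ids=["a", "b", "c", "d", "e"],
        snp_ids=["s1", "s2"],
        genotypes=np.array([[0, 1], [1, 2], [2, 0], [0, 1], [1, 2]]),
        phenotypes=np.array([CASE, CASE, CASE, CONTROL, CONTROL]),
    )


@pytest.fixture
def single_edge() -> GenotypeDataset:
    """One case, one control, one SNP; builds a two-edge path graph.

    Restricting labels to the case only gives the single-edge analytic
    fixture (control excluded from the graph by making its call missing).
    """
    return GenotypeDataset(
        sample_ids=["v"],
        snp_ids=["s1"],
        genotypes=np.array([[1]]),
        phenotypes=np.array([CASE]),
    )


def random_dataset(
    rng: np.random.Generator,
    n_samples: int = 8,
    n_snps: int = 4,
    missing_rate: float = 0.1,
) -> GenotypeDataset:
    """Random small genotype dataset with both classes present."""
    geno = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING
        geno[0] = np.abs(geno[0])  # keep sample 0 fully typed (no empty rows)
    ph = np.array([CASE, CONTROL] * (n_samples // 2) + [CASE] * (n_samples % 2))
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        snp_ids=[f"snp{j}" for j in range(n_snps)],
        genotypes=geno,
        phenotypes=ph[:n_samples].astype(np.int8),
    )
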