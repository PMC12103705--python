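import numpy as np
import pytest

from epiresponse import (
    SyntheticConfig,
    bin_length_matrix,
    generate_cohort,
    tpm_scale,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-gene null cohort reused by cheap structural tests."""
    return generate_cohort(SyntheticConfig(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def small_tpm(small_cohort):
    return tpm_scale(
        small_cohort.signal, bin_length_matrix(small_cohort.catalogue)
    )


def cohort_tpm_labels(config: SyntheticConfig):
    """Generate a cohort and return (tpm signal, planted labels)."""
    cohort = generate_cohort(config)
    tpm = tpm_scale(cohort.signal, bin_length_matrix(cohort.catalogue))
    return tpm, cohort.true_response_labels()


def random_gene_models(rng: np.random.Generator, n: int, min_len=200, max_len=50_000):
    from epiresponse import GeneModel

    genes = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(2000, 1_000_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"r{i:04d}", "chr1", strand, start, start + length))
    return genes
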