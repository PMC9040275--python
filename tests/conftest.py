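import numpy as np
import pytest

from denovoburden import synthetic_data as sd
from denovoburden.cnv_rate import covariate_table


@pytest.fixture(scope="session")
def toy_genome():
    """Small deterministic genome shared across tests."""
    return sd.make_genome(seed=42, n_genes=120)


@pytest.fixture(scope="session")
def toy_covariates(toy_genome):
    return covariate_table(
        toy_genome.genes, toy_genome.sd_pairs, toy_genome.chrom_lengths
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
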