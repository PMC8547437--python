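import numpy as np
import pytest

import genostream as gs


@pytest.fixture(scope="session")
def lgc_genome():
    """One mid-sized streamlined-profile genome with its gene table and truth."""
    genome, table, truth = gs.generate_genome(gs.LGC_PROFILE, 200, seed=101)
    return genome, table, truth


@pytest.fixture(scope="session")
def small_bundle():
    """Two-subclade dataset small enough for alignment-heavy end-to-end tests."""
    return gs.build_subclade_dataset(
        n_genomes=2, seed=7, n_genes=60, reads_per_unit_abundance=300,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
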