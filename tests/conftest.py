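import numpy as np
import pytest

import hbdest as h


@pytest.fixture(scope="session")
def easy_data():
    return h.fixture_easy()


@pytest.fixture(scope="session")
def easy_hybrid(easy_data):
    ds, _ = easy_data
    return h.hybrid_matrix(ds)


@pytest.fixture(scope="session")
def family_data():
    return h.fixture_family()


@pytest.fixture(scope="session")
def family_matrices(family_data):
    """(normalized local, gred, hybrid-at-defaults) for the hard fixture."""
    ds, _ = family_data
    local = h.hybrid_matrix(ds, feature="local")
    gred = h.gred_matrix(ds, 6)
    hybrid = h.combine(local, gred, h.HybridParams())
    return local, gred, hybrid


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 30-EST, 3-gene dataset for matrix-level unit tests."""
    cfg = h.SyntheticFamilyConfig(
        n_genes=3,
        gene_len=600,
        n_exons=0,
        shared_block_len=0,
        inter_gene_divergence=0.3,
        ests_per_gene=10,
        est_len_range=(120, 300),
        error_rate=0.002,
        seed=1234,
    )
    return h.simulate_family(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20120817)
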