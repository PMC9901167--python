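import numpy as np
import pytest

from dtibench import synthetic
from dtibench.io import BioactivityTable


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator config used by most integration tests."""
    return synthetic.SyntheticConfig(
        n_compound_families=6,
        compounds_per_family=5,
        n_protein_clusters=5,
        proteins_per_cluster=3,
        seq_length=60,
        density=0.4,
        assay_bias=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate(small_config)


@pytest.fixture
def toy_table():
    return BioactivityTable.from_pairs(
        [
            ("c1", "p1", 6.0),
            ("c1", "p2", 7.5),
            ("c2", "p1", 5.0),
            ("c2", "p2", 8.0),
            ("c3", "p3", 4.5),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
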