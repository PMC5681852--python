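import numpy as np
import pytest

from hgtsim.fixtures import FixtureSpec, generate_community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_community():
    """A small donor/recipient community shared by read-only tests."""
    spec = FixtureSpec(
        n_donor_genes=12,
        gene_length_codons=(60, 200),
        n_recipients=2,
        recipient_length=(60_000, 80_000),
        n_features=15,
        seed=42,
    )
    return generate_community(spec)
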