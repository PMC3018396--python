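import numpy as np
import pytest

from pinhub.synthetic_data import SyntheticConfig, generate_records


@pytest.fixture(scope="session")
def small_dataset():
    """In-memory synthetic dataset shared by pipeline-level tests."""
    config = SyntheticConfig(n_proteins=300, seed=11)
    records, labels, degrees, avg_pcc = generate_records(config)
    return config, records, labels, degrees, avg_pcc


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_sequences(rng):
    """100 random standard-residue sequences of length 2..50."""
    from pinhub.io_formats import AMINO_ACIDS

    out = []
    for _ in range(100):
        n = int(rng.integers(4, 51))
        out.append("".join(rng.choice(list(AMINO_ACIDS), size=n)))
    return out
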