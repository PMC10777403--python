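import numpy as np
import pytest

from dmpnn import fixtures as fx


@pytest.fixture(scope="session")
def small_molecules():
    """50 deterministic fixture molecules."""
    return fx.make_molecule_set(50, seed=11).smiles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
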