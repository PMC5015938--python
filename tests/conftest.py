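import numpy as np
import pytest

from ubisel.core_model import default_reference


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def small_ref():
    """A deterministic 30-codon insert for cheap alignment/counting tests."""
    return default_reference(n_codons=30, first_residue=1, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
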