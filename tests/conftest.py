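import numpy as np
import pytest

from dmsd.design import random_design
from dmsd import synthetic


@pytest.fixture(scope="session")
def toy_design():
    """Two kinases over a 6-residue domain -- enough structure, fast."""
    return random_design(n_kinases=2, n_positions=6, seed=101)


@pytest.fixture(scope="session")
def toy_library(toy_design):
    return synthetic.generate_library(toy_design, n_barcodes_per_variant=3, seed=102)


@pytest.fixture(scope="session")
def toy_truth(toy_design):
    return synthetic.TruthParameters.generate(toy_design, seed=103)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
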