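import numpy as np
import pytest

import ecoabc


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def scenarios():
    return ecoabc.load_scenarios()


@pytest.fixture(scope="session")
def priors():
    return ecoabc.load_priors()


@pytest.fixture(scope="session")
def toy_dataset():
    return ecoabc.make_toy_fixture(seed=5)


@pytest.fixture(scope="session")
def small_table():
    """Three-individual genotype table used across io tests."""
    genotypes = np.array(
        [
            [[101, 103], [110, 110]],
            [[101, 101], [0, 0]],
            [[105, 103], [112, 110]],
        ],
        dtype=np.int64,
    )
    return ecoabc.GenotypeTable(
        ["A_1", "A_2", "B_1"], ["A", "A", "B"], ["Rt5", "Rt6"], genotypes
    )
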