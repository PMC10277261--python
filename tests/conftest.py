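import numpy as np
import pytest

from divtime import fixture_factory as ff
from divtime.retrieval import FixtureBackend

FOUR_SPECIES = [
    "Passerina amoena",
    "Corythornis cristatus",
    "Chalcomitra amethystine",
    "Chrysococcyx cupreus",
]


@pytest.fixture(scope="session")
def backend():
    return FixtureBackend()


@pytest.fixture()
def table1():
    return ff.table1_fixture()


@pytest.fixture(scope="session")
def catharus_tree():
    return ff.packaged_tree("Catharus")


@pytest.fixture(scope="session")
def malurus_tree():
    return ff.packaged_tree("Malurus")


def random_symmetric_matrix(n: int, seed: int) -> np.ndarray:
    """A random symmetric nonnegative matrix with zero diagonal (not
    necessarily ultrametric) — enough structure for table round trips."""
    rng = np.random.default_rng(seed)
    v = np.round(rng.uniform(1.0, 100.0, size=(n, n)), 1)
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v
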