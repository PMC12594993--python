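import numpy as np
import pytest

from evoscreen import SurrogateBackend, load_library
from evoscreen.benchmark import generate_fixture_library


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Deterministic 4-reaction x 20x20 toy library files."""
    out = tmp_path_factory.mktemp("fixture_lib")
    return generate_fixture_library(out, n_reactions=4, n_per_position=20, seed=7)


@pytest.fixture(scope="session")
def library(fixture_paths):
    reactions, reagents = fixture_paths
    return load_library(reactions, reagents)


@pytest.fixture(scope="session")
def toy2_paths(tmp_path_factory):
    """2 reactions x 2 positions x 10 synthons -> 200 products."""
    out = tmp_path_factory.mktemp("toy2")
    return generate_fixture_library(out, n_reactions=2, n_per_position=10, seed=11)


@pytest.fixture(scope="session")
def toy2(toy2_paths):
    reactions, reagents = toy2_paths
    return load_library(reactions, reagents)


@pytest.fixture(scope="session")
def backend():
    return SurrogateBackend()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
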