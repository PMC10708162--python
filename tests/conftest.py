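import numpy as np
import pandas as pd
import pytest

from csrpipe import SyntheticConfig, degenerate_fixtures, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared across read-only tests."""
    return generate_dataset(SyntheticConfig(seed=11, n_species=20, n_elevations=4))


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the reference study conditions (80 species, 8 levels)."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def edge_fixtures():
    return degenerate_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def alien_table():
    """The shipped survey table of ten alien species (scores + labels)."""
    from importlib import resources
    with resources.as_file(
            resources.files("csrpipe.data").joinpath("reunion_aliens.csv")) as p:
        return pd.read_csv(p, comment="#")
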