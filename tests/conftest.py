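import numpy as np
import pandas as pd
import pytest

from responseguilds.data_io import AbundanceMatrix
from responseguilds.synthetic import CommunityConfig, simulate_community


@pytest.fixture(scope="session")
def small_community():
    """A compact guild-structured community reused across tests."""
    return simulate_community(
        CommunityConfig(
            n_species=20, n_years=30, n_guilds=4, within_guild_rho=0.8,
            missing_fraction=0.0, n_trees=5, tree_noise=0.1, seed=42,
        )
    )


@pytest.fixture()
def tiny_abundance():
    """3 species x 5 years with one missing cell."""
    data = pd.DataFrame(
        {
            2000: [1.0, 2.0, 0.5],
            2001: [1.5, 1.8, 0.7],
            2002: [np.nan, 2.2, 0.6],
            2003: [1.2, 2.5, 0.9],
            2004: [1.8, 2.1, 0.4],
        },
        index=["Alpha one", "Beta two", "Gamma three"],
    )
    return AbundanceMatrix(data)


def random_symmetric(n, rng, low=0.0, high=2.0):
    """Random symmetric matrix with zero diagonal (a distance-like matrix)."""
    a = rng.uniform(low, high, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a
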