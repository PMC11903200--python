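import numpy as np
import pytest

from fasdiet import SyntheticScenario, synth_prey_db


@pytest.fixture(scope="session")
def small_db():
    """5 species x 10 FAs, moderate separation; shared across tests."""
    db, truth = synth_prey_db(SyntheticScenario(
        n_species=5, n_individuals=8, n_fa=10, within_sd=0.12, seed=3))
    return db, truth


@pytest.fixture(scope="session")
def separated_db():
    """Well-separated 11 species x 39 FAs library (low within-species noise)."""
    db, truth = synth_prey_db(SyntheticScenario(
        n_species=11, n_individuals=10, n_fa=39, within_sd=0.05,
        separation=1.5, seed=42))
    return db, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_composition(rng, k):
    x = rng.dirichlet(np.ones(k))
    return x / x.sum()
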