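import numpy as np
import pytest

from crypsis import synthetic as syn


@pytest.fixture(scope="session")
def table1_table():
    """Synthetic two-group morphometric table at the published design size."""
    return syn.gen_morpho(syn.MorphoSimSpec(seed=11))


@pytest.fixture(scope="session")
def big_table():
    """Large synthetic table for Monte-Carlo checks."""
    return syn.gen_morpho(syn.MorphoSimSpec(n_nearctic=200, n_palearctic=200, seed=7))


@pytest.fixture(scope="session")
def niche_world():
    """Synthetic landscape with a known logistic suitability surface."""
    return syn.gen_niche(syn.NicheSimSpec(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
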