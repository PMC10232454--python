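import numpy as np
import pytest

from smilesrl import FixtureSpec, generate_fixture_corpus
from smilesrl.lm import SmilesGPT


@pytest.fixture(scope="session")
def corpus200():
    return generate_fixture_corpus(FixtureSpec(n_molecules=200, seed=11))


@pytest.fixture(scope="session")
def corpus5k():
    return generate_fixture_corpus(FixtureSpec(n_molecules=5000, seed=11))


@pytest.fixture(scope="session")
def tiny_lm(corpus200):
    """A small decoder trained just enough to have a non-degenerate policy."""
    return SmilesGPT(
        n_layers=2, n_heads=2, d_model=32, d_ff=64, max_len=32,
        epochs=2, batch_size=32, lr=1e-3, seed=5,
    ).fit(corpus200)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
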