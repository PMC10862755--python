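import numpy as np
import pytest

from sparsehmm.synthetic import make_profile, random_background_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def small_profile(rng):
    return make_profile(12, rng, name="small")


@pytest.fixture
def medium_profile(rng):
    return make_profile(50, rng, name="medium")


def random_pair(rng, m_max=3, n_max=3, m_min=1, n_min=1):
    """A random tiny (profile, sequence) pair for enumeration tests."""
    m = int(rng.integers(m_min, m_max + 1))
    n = int(rng.integers(n_min, n_max + 1))
    hmm = make_profile(m, rng)
    seq = random_background_sequence(n, rng)
    return hmm, seq
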