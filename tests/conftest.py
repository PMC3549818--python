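import numpy as np
import pytest

from lsanet.core import StandardSeries


def standardize_vector(values, label=""):
    """Population-standardize a raw vector into a StandardSeries."""
    v = np.asarray(values, dtype=float)
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    v = v / sd
    v = v - v.mean()
    return StandardSeries(v, label)


@pytest.fixture
def rng():
    return np.random.default_rng(20130121)


@pytest.fixture
def random_pair(rng):
    """Factory for random standardized pairs of a given length."""

    def make(n):
        return (
            standardize_vector(rng.standard_normal(n), "a"),
            standardize_vector(rng.standard_normal(n), "b"),
        )

    return make
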