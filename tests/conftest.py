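import numpy as np
import pytest

from rnastructclust import SynthFamilySpec, sample_family


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_family():
    """One 8-member synthetic family at the default study conditions."""
    return sample_family(SynthFamilySpec(n_sequences=8, seed=7))


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture
def random_rna_factory(rng):
    def make(n: int) -> str:
        return random_rna(rng, n)

    return make
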