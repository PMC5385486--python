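import numpy as np
import pytest

from gintools import SynthParams, generate_planted_genome, make_reference_set


@pytest.fixture(scope="session")
def refs():
    return make_reference_set()


@pytest.fixture(scope="session")
def planted(refs):
    """One default planted genome + truth, shared across tests."""
    return generate_planted_genome(SynthParams(seed=7), refs=refs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def random_protein(rng, n):
    return "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n - 1))
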