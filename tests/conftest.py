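import numpy as np
import pytest

from seedvote import IndexParams, ReferenceSet, build_index

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_ref():
    """5 kb two-sequence reference, N-free, fixed seed."""
    r = np.random.default_rng(1234)
    return ReferenceSet([("chrA", random_dna(r, 3000)), ("chrB", random_dna(r, 2000))])


@pytest.fixture(scope="session")
def small_index(small_ref):
    return build_index(small_ref, IndexParams())
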