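import numpy as np
import pytest

from persoma.core_model import ScaffoldSet

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    """One 20 kb scaffold of random sequence."""
    return ScaffoldSet({"chr1": random_seq(rng, 20_000)})


@pytest.fixture
def two_scaffold_genome(rng):
    return ScaffoldSet({"scafA": random_seq(rng, 8_000),
                        "scafB": random_seq(rng, 6_000)})
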