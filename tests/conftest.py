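import numpy as np
import pytest

from spatq import from_adjacency_pairs, row_standardize
from spatq import synthetic as syn


@pytest.fixture(scope="session")
def lattice6():
    return syn.make_lattice(6, 6)


@pytest.fixture(scope="session")
def lattice10():
    return syn.make_lattice(10, 10)


@pytest.fixture()
def path_w():
    """A-B-C path graph, row-standardized."""
    return row_standardize(from_adjacency_pairs([("A", "B"), ("B", "C")],
                                                ["A", "B", "C"]))


@pytest.fixture()
def cycle4():
    return row_standardize(
        from_adjacency_pairs([(0, 1), (1, 2), (2, 3), (3, 0)], [0, 1, 2, 3]))


def random_connected_weights(rng, n):
    """Random symmetric binary weights guaranteed connected (ring + extras)."""
    ids = list(range(n))
    pairs = [(i, (i + 1) % n) for i in range(n)]
    extra = rng.integers(0, n, size=(n, 2))
    pairs += [(int(a), int(b)) for a, b in extra if a != b]
    return from_adjacency_pairs(set(tuple(sorted(p)) for p in pairs), ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
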