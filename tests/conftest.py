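import numpy as np
import pytest

from rnamotifbench.core import BasePair


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_pair_set(rng, n, k):
    """k arbitrary pairs over 1..n (positions may repeat across pairs)."""
    pairs = set()
    guard = 0
    while len(pairs) < k and guard < 10 * k + 50:
        guard += 1
        i, j = sorted(rng.choice(np.arange(1, n + 1), size=2, replace=False))
        pairs.add(BasePair(int(i), int(j)))
    return frozenset(pairs)
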