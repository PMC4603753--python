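import numpy as np
import pytest

from hgtquartets.trees import parse_newick, random_binary_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def balanced4():
    return parse_newick("((a,b),(c,d));")


@pytest.fixture
def caterpillar5():
    return parse_newick("(a,(b,(c,(d,e))));")


def make_random_trees(labels, k, seed):
    rng = np.random.default_rng(seed)
    return [random_binary_tree(labels, rng) for _ in range(k)]
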