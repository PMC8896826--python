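import numpy as np
import pytest

import phylorep as pr
from phylorep.simulate import simulate_yule_tree


@pytest.fixture
def four_leaf_tree():
    """((A:1,B:2):1,(C:3,D:1):2); — the workhorse toy tree."""
    return pr.parse_newick("((A:1,B:2):1,(C:3,D:1):2);")


@pytest.fixture
def four_leaf_matrix(four_leaf_tree):
    return pr.patristic_matrix(four_leaf_tree)


@pytest.fixture
def cherry_pair_tree():
    """Two tight cherries far apart: ((A:1,B:1):5,(C:1,D:1):5);"""
    return pr.parse_newick("((A:1,B:1):5,(C:1,D:1):5);")


@pytest.fixture
def nada_table():
    return pr.load_nada_table()


@pytest.fixture
def ispg_table():
    return pr.load_ispg_table()


def random_trees(n_trees, min_leaves, max_leaves, seed0):
    """Deterministic batch of small Yule trees for oracle comparisons."""
    rng = np.random.default_rng(seed0)
    for i in range(n_trees):
        n = int(rng.integers(min_leaves, max_leaves + 1))
        yield simulate_yule_tree(n, seed=seed0 + i)
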