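import matplotlib
matplotlib.use("Agg")

import numpy as np
import pytest

from tedkit.timetree import TimeTree
from tedkit.clocks import effective_lengths_strict


@pytest.fixture
def balanced4():
    """((A:10,B:10):5,(C:10,D:10):5) -- root at 15 Ma."""
    return TimeTree.from_newick("((A:10,B:10):5,(C:10,D:10):5);")


@pytest.fixture
def caterpillar4():
    """(((A,B),C),D) with node ages 4, 7, 10."""
    return TimeTree.from_newick("(((A:4,B:4):3,C:7):3,D:10);")


@pytest.fixture
def three_tip():
    return TimeTree.from_newick("((A:5,B:5):5,C:10);")


@pytest.fixture
def fossil_tree():
    """((A, F):, B) with fossil F at 4 Ma."""
    return TimeTree.from_newick("((A:10,F:6):5,B:15);", fossil_ages={"F": 4})


@pytest.fixture
def rng():
    return np.random.default_rng(20160719)


@pytest.fixture
def strict_effects(three_tip):
    return effective_lengths_strict(three_tip, 0.1)
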