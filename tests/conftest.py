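import numpy as np
import pytest

from archorisk.simulate import SimConfig, simulate_bd_tree
from archorisk.trees import parse_newick, to_arrays


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def eight_tip_tree():
    tree, _ = simulate_bd_tree(SimConfig(lambda0=0.3, mu0=0.05, crown_age=10.0,
                                         seed=123))
    return tree


def random_bd_tree(seed, lam=0.25, mu=0.05, crown_age=12.0):
    tree, _ = simulate_bd_tree(SimConfig(lambda0=lam, mu0=mu,
                                         crown_age=crown_age, seed=seed))
    return tree


def tree_with_tips(lo, hi, seed, lam=0.13, mu=0.0, crown_age=25.0, **kw):
    """Resimulate with shifted seeds until the tip count lands in [lo, hi]."""
    s = seed
    while True:
        tree, log = simulate_bd_tree(SimConfig(lambda0=lam, mu0=mu,
                                               crown_age=crown_age, seed=s, **kw))
        arr = to_arrays(tree)
        if lo <= arr.n_tips <= hi:
            return tree, arr, log
        s += 1000


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_927)
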