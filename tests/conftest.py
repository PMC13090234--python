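import numpy as np
import pytest

from bdbias import parse_newick
from bdbias.params import BDParams
from bdbias.simulate import simulate_crown_tree


@pytest.fixture(scope="session")
def tree3():
    """Three-tip fixture: n=3, m=2, s=5, crown age 2, branching times [2, 1]."""
    return parse_newick("((B:1,C:1):1,A:2);")


@pytest.fixture(scope="session")
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def cherry10():
    """Cherry of crown age 10 (matches the kernel worked examples)."""
    return parse_newick("(A:10,B:10);")


@pytest.fixture(scope="session")
def tree4():
    """Four-tip balanced fixture: crown age 2, s = 6, times [2, 1.5, 1]."""
    return parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def yule_trees():
    """Fifty simulated pure-birth trees with n > 2 (lam=0.3, age 8)."""
    rng = np.random.default_rng(42)
    trees = []
    while len(trees) < 50:
        out = simulate_crown_tree(BDParams(0.3, 0.0), 8.0, rng)
        if out.status == "usable":
            trees.append(out.tree)
    return trees


@pytest.fixture(scope="session")
def bd_trees():
    """Simulated birth-death trees with n > 2 (lam=0.1, mu=0.05, age 10)."""
    rng = np.random.default_rng(7)
    trees = []
    while len(trees) < 30:
        out = simulate_crown_tree(BDParams(0.1, 0.05), 10.0, rng)
        if out.status == "usable":
            trees.append(out.tree)
    return trees
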