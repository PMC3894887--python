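import numpy as np
import pytest

from divtempo.chronogram import BranchingTimes, read_newick
from divtempo.simulate import encephalartos_like


@pytest.fixture
def three_tip_bt() -> BranchingTimes:
    """Branching times of ((A:1,B:1):1,C:2); — ages (2, 1)."""
    return BranchingTimes(ages=np.array([2.0, 1.0]), n=3)


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def cycad_tree():
    """One three-epoch cycad-like chronogram, fixed seed, shared across tests."""
    return encephalartos_like(123)


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary topology with random branch lengths (not ultrametric)."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.01, 5.0, size=2)
        merged = f"({a}:{la:.9f},{b}:{lb:.9f})"
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
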