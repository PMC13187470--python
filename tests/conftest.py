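import io

import numpy as np
import pytest
from skbio import TreeNode

from popspec.simulate import SimulationConfig, simulate_population_tree


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_populations=5, isolates_per_population=4, n_specialists=2, seed=11
    )


@pytest.fixture
def small_tree(small_config):
    return simulate_population_tree(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_tree(rng: np.random.Generator, names: list[str]) -> TreeNode:
    """Random binary tree with exponential branch lengths (test helper)."""
    nodes = [TreeNode(name=n, length=float(rng.exponential(1.0))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)))
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def tree_from_newick(nwk: str) -> TreeNode:
    return TreeNode.read(io.StringIO(nwk))
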