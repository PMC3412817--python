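import numpy as np
import pytest

from vrbench.synthetic_data import generate_reference_alignment


@pytest.fixture(scope="session")
def synth_small():
    """Small synthetic alignment + taxonomy shared by read-only tests."""
    return generate_reference_alignment(n_sequences=150, seed=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_binary_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths (skbio TreeNode)."""
    import skbio

    nodes = [skbio.TreeNode(name=f"L{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 0.5))
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = skbio.TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.05, 0.5))
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    root = skbio.TreeNode(children=nodes)
    root.length = None
    return root
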