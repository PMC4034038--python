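import numpy as np
import pytest

from ggfam.trees import GeneTree, Node, parse_newick


def random_binary_tree(labels, rng) -> GeneTree:
    """Uniform-ish random rooted binary tree by sequential random joins."""
    nodes = [Node(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=[a, b]))
    return GeneTree(root=nodes[0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def species_tree_5():
    return parse_newick("((A:1,B:1):1,((C:1,D:1):1,E:2):1);")


@pytest.fixture
def quartet_two_species():
    return parse_newick("((A_g1,B_g1),(A_g2,B_g2));")
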