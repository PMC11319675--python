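import numpy as np
import pytest

from phylosym.tree import PhyloTree


@pytest.fixture
def cherry():
    return PhyloTree.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def balanced_newick(depth: int, prefix: str = "t") -> str:
    """Fully balanced binary tree with 2**depth tips, unit branches."""
    counter = [0]

    def build(d):
        if d == 0:
            counter[0] += 1
            return f"{prefix}{counter[0]}:1"
        return f"({build(d - 1)},{build(d - 1)}):1"

    return build(depth) + ";"


@pytest.fixture
def balanced64():
    return PhyloTree.from_newick(balanced_newick(6))


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary topology with random branch lengths (for oracles)."""
    nodes = [f"x{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    return nodes[0].rsplit(":", 1)[0] + ";"
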