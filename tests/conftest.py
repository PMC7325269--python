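import random
from fractions import Fraction

import pytest
from hypothesis import settings

from rhoclock import MutationTree, datasets
from rhoclock.tree import TreeNode

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def five_lineage_tree() -> MutationTree:
    return datasets.load_five_lineage_tree()


@pytest.fixture
def worked_example_table():
    return datasets.load_worked_example_periods()


def random_mutation_tree(
    rng: random.Random, n_tips: int, max_mutations: int = 6
) -> MutationTree:
    """Random (possibly multifurcating) tree with integer mutation counts."""
    nodes: list[TreeNode] = [TreeNode(label=f"t{i + 1}") for i in range(n_tips)]
    while len(nodes) > 1:
        k = min(len(nodes), rng.choice([2, 2, 2, 3]))
        parent = TreeNode()
        for _ in range(k):
            child = nodes.pop(rng.randrange(len(nodes)))
            child.mutations = Fraction(rng.randint(0, max_mutations))
            child.parent = parent
            parent.children.append(child)
        nodes.append(parent)
    return MutationTree(nodes[0])


def shuffled_newick(tree: MutationTree, rng: random.Random) -> str:
    """The same tree serialized with every node's child order shuffled."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip:
            core = node.label or ""
        else:
            children = list(node.children)
            rng.shuffle(children)
            core = "(" + ",".join(fmt(c) for c in children) + ")"
        if node.mutations is not None:
            m = node.mutations
            core += f":{int(m)}" if m.denominator == 1 else f":{float(m)!r}"
        return core

    return fmt(tree.root) + ";"
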