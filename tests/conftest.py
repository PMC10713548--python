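import numpy as np
import pytest

from soe import chexpert_tree, cost_matrix, parse_hierarchy

TOY_DOC = {
    "name": "R",
    "children": [
        {"name": "A", "children": [{"name": "a1"}, {"name": "a2"}]},
        {"name": "B", "children": [{"name": "b1"}]},
    ],
}


@pytest.fixture
def toy_type2():
    """Five-label type-2 tree: R -> {A -> {a1, a2}, B -> {b1}}."""
    return parse_hierarchy(TOY_DOC, policy="type2")


@pytest.fixture
def toy_type1():
    """Same shape, leaves-only labels [a1, a2, b1]."""
    return parse_hierarchy(TOY_DOC, policy="type1")


@pytest.fixture
def toy_cost2(toy_type2):
    return cost_matrix(toy_type2)


@pytest.fixture
def toy_cost1(toy_type1):
    return cost_matrix(toy_type1)


@pytest.fixture(scope="session")
def chexpert():
    return chexpert_tree()


@pytest.fixture(scope="session")
def chexpert_cost():
    return cost_matrix(chexpert_tree())


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never reuse package internals)
# ---------------------------------------------------------------------------


def ancestor_chain(parent, root, node):
    """node..root path computed straight off the parent mapping."""
    chain = [node]
    while chain[-1] != root:
        chain.append(parent[chain[-1]])
    return chain


def brute_lca(parent, root, a, b):
    """Deepest common element of the two ancestor chains, by set scan."""
    bset = set(ancestor_chain(parent, root, b))
    for n in ancestor_chain(parent, root, a):
        if n in bset:
            return n
    return root


def brute_height(parent, root, node):
    """Max edge distance to a leaf, by recursive enumeration of children."""
    children = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)

    def h(n):
        kids = children.get(n, [])
        return 0 if not kids else 1 + max(h(k) for k in kids)

    return h(node)


def brute_cost_matrix(tree):
    """K x K LCA-height matrix via the naive chain oracles.

    Heights are cached per node (the recursion itself stays naive) so the
    oracle scales to the larger random trees in the property tests.
    """
    k = len(tree.labels)
    out = np.zeros((k, k))
    heights = {}
    for i, a in enumerate(tree.labels):
        for j, b in enumerate(tree.labels):
            if i != j:
                anc = brute_lca(tree.parent, tree.root, a, b)
                if anc not in heights:
                    heights[anc] = brute_height(tree.parent, tree.root, anc)
                out[i, j] = heights[anc]
    return out


def small_random_tree(rng, max_depth=5, max_branch=4, max_labels=60, policy="type1"):
    """Random tree within the stated depth/branching bounds, rejection-
    sampled down to a label count the quadratic oracles can afford."""
    from soe.synthetic import random_tree

    while True:
        depth = int(rng.integers(1, max_depth + 1))
        lo = int(rng.integers(1, max_branch))
        hi = int(rng.integers(lo, max_branch + 1))
        tree = random_tree(depth, (lo, hi), seed=int(rng.integers(2**31)), policy=policy)
        if len(tree.labels) <= max_labels:
            return tree


def brute_auroc(scores, truth):
    """Exhaustive positive-negative pair counting, ties worth 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    if not pos or not neg:
        return None
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
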