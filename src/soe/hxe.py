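"""Hierarchical cross-entropy (HXE): taxonomy-factorized log loss.

A distribution over the leaves of a taxonomy factorizes along each
root-to-leaf path into conditionals between consecutive levels::

    p(C) = prod_l p(C^(l) | C^(l+1)),
    p(child | parent) = subtree_mass(child) / subtree_mass(parent)

HXE scores a prediction by the weighted negative log of each conditional on
the target leaf's path, so a mistake high in the tree (committing mass to
the wrong branch) can be penalized differently from a mistake between
siblings.  With a flat tree and unit weights it reduces exactly to the
standard cross-entropy ``-log p(target)``.

Edge weights follow an exponential depth decay
``lambda(edge into node at depth d) = exp(-alpha * (H - d))`` with ``H`` the
tree height; ``alpha = 0`` gives uniform weights (the default), ``alpha > 0``
down-weights edges near the root.

Taxonomies where internal nodes are themselves labels (type-2) are handled
by :func:`augment_type2_tree`, which grafts a virtual leaf under every
labelled internal node to carry the "exactly this node, nothing more
specific" outcome; the loss is then evaluable with every label mapped to a
leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import InputError, NodeLookupError, StructureError
from .hierarchy import HierarchyTree

__all__ = [
    "LeafDistribution",
    "EdgeWeights",
    "subtree_probability",
    "conditional_probability",
    "path_probability",
    "hxe_loss",
    "exponential_weights",
    "augment_type2_tree",
]

#: Conditional probabilities are clamped to at least this before every log.
LOG_CLAMP = 1e-12


@dataclass(frozen=True)
class LeafDistribution:
    """A probability distribution over the leaves of a taxonomy."""

    tree: HierarchyTree
    p_leaves: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_leaves", dict(self.p_leaves))
        leaves = set(self.tree.leaves())
        for node, p in self.p_leaves.items():
            if node not in leaves:
                raise InputError(f"{node!r} is not a leaf of the tree")
            if p < 0:
                raise InputError(f"negative probability for {node!r}")
        total = sum(self.p_leaves.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"leaf probabilities sum to {total}, expected 1")


@dataclass(frozen=True)
class EdgeWeights:
    """Non-negative weight per (parent, child) tree edge."""

    weights: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        for edge, w in self.weights.items():
            if not math.isfinite(w):
                raise InputError(f"non-finite weight on edge {edge}")

    def __getitem__(self, edge: tuple[str, str]) -> float:
        try:
            return self.weights[edge]
        except KeyError:
            raise NodeLookupError(f"no weight for edge {edge}") from None


def subtree_probability(dist: LeafDistribution, node: str) -> float:
    """Total leaf mass of ``node``'s subtree; ~1 at the root."""
    dist.tree._check(node)
    return sum(dist.p_leaves.get(leaf, 0.0) for leaf in dist.tree.leaves(node))


def conditional_probability(dist: LeafDistribution, child: str, parent: str) -> float:
    """p(child | parent) = subtree mass ratio, in [0, 1].

    A zero-mass parent is clamped at :data:`LOG_CLAMP` in the denominator so
    the ratio stays defined (and ~0) instead of dividing by zero.
    """
    if child not in dist.tree.children(parent):
        raise StructureError(f"({parent!r}, {child!r}) is not a tree edge")
    num = subtree_probability(dist, child)
    den = subtree_probability(dist, parent)
    return num / max(den, LOG_CLAMP)


def _root_path(tree: HierarchyTree, leaf: str) -> list[tuple[str, str]]:
    """(parent, child) edges from the root down to ``leaf``."""
    path = tree.ancestors(leaf)  # leaf ... root
    return [(path[i + 1], path[i]) for i in range(len(path) - 1)][::-1]


def path_probability(dist: LeafDistribution, leaf: str) -> float:
    """Product of conditionals along the root-to-leaf path.

    Telescopes back to the leaf's own probability when the distribution is
    normalized.
    """
    if not dist.tree.is_leaf(leaf):
        raise InputError(f"{leaf!r} is not a leaf")
    prob = 1.0
    for parent, child in _root_path(dist.tree, leaf):
        prob *= conditional_probability(dist, child, parent)
    return prob


def hxe_loss(dist: LeafDistribution, target_leaf: str, weights: EdgeWeights) -> float:
    """Weighted negative log of each conditional on the target's root path.

    Probabilities are clamped at :data:`LOG_CLAMP` before the log; the loss
    is >= 0 whenever weights are, and 0 for a one-hot prediction on the
    target.
    """
    if not dist.tree.is_leaf(target_leaf):
        raise InputError(f"target {target_leaf!r} is not a leaf")
    loss = 0.0
    for parent, child in _root_path(dist.tree, target_leaf):
        q = max(conditional_probability(dist, child, parent), LOG_CLAMP)
        loss -= weights[(parent, child)] * math.log(q)
    return loss


def exponential_weights(tree: HierarchyTree, alpha: float = 0.0) -> EdgeWeights:
    """Exponential depth-decay edge weights.

    The edge into a node at depth ``d`` gets ``exp(-alpha * (H - d))`` where
    ``H`` is the tree height, so with ``alpha > 0`` edges near the root are
    down-weighted and the edge into a deepest leaf has weight 1.
    ``alpha = 0`` gives uniform unit weights.
    """
    if alpha < 0:
        raise InputError(f"alpha must be >= 0, got {alpha}")
    h = tree.height()
    weights = {
        (tree.parent[node], node): math.exp(-alpha * (h - tree.depth(node)))
        for node in tree.nodes
        if node != tree.root
    }
    return EdgeWeights(weights)


def augment_type2_tree(tree: HierarchyTree, suffix: str = "*") -> HierarchyTree:
    """Make a type-2 taxonomy HXE-evaluable by grafting virtual leaves.

    Every *labelled internal* node gains a child leaf (named by appending
    ``suffix``) that carries the "exactly this node" outcome.  The labels
    themselves are unchanged; the returned tree's :meth:`HierarchyTree.\
leaf_for_label` maps each label to its representative leaf.  A tree whose
    labels are already all leaves is returned unchanged.
    """
    internal_labels = [l for l in tree.labels if not tree.is_leaf(l)]
    if not internal_labels:
        return tree
    parent = dict(tree.parent)
    label_leaf: dict[str, str] = {}
    for lab in tree.labels:
        if tree.is_leaf(lab):
            label_leaf[lab] = lab
        else:
            virtual = lab + suffix
            while virtual in tree.nodes or virtual in parent:
                virtual += suffix
            parent[virtual] = lab
            label_leaf[lab] = virtual
    return HierarchyTree(
        parent=parent,
        root=tree.root,
        labels=tree.labels,
        policy="type2",
        label_leaf=label_leaf,
    )
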