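"""Label taxonomies, lowest common ancestors, and LCA-height cost matrices.

A classifier over a hierarchical label set pays a different price for
different mistakes: confusing two sibling findings is mild, confusing a lung
finding with "No Finding" is grave.  The natural currency for that price is
the height of the lowest common ancestor (LCA) of the predicted and true
labels in the taxonomy tree.  This module owns the tree representation and
is the sole source of LCA and node-height facts; everything downstream
(severity metrics, conditional-risk relabelling, hierarchical cross-entropy)
consumes the :class:`CostMatrix` built here.

Two labelling policies are supported, matching how hierarchies occur in
practice:

* **type-1** — only leaf nodes are class labels (tieredImageNet-style);
* **type-2** — internal nodes may themselves be labels, the common case in
  medical taxonomies such as CheXpert or ICD-10.

Trees can be read from a nested JSON document, a newick string with named
internal nodes, or a flat list of hierarchical code strings (ICD-10-style
prefix nesting).  A 14-label chest-radiograph taxonomy is packaged as a data
file and returned by :func:`chexpert_tree`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    FormatError,
    InputError,
    NodeLookupError,
    PolicyError,
    StructureError,
)

__all__ = [
    "HierarchyTree",
    "CostMatrix",
    "parse_hierarchy",
    "parse_newick",
    "build_from_codes",
    "lca",
    "node_height",
    "cost_matrix",
    "chexpert_tree",
]


@dataclass(frozen=True)
class HierarchyTree:
    """A rooted label taxonomy.

    Parameters
    ----------
    parent
        Mapping child node -> parent node; the root does not appear as a key.
    root
        Identifier of the unique root node.
    labels
        Ordered tuple of node identifiers used as class labels.  The order is
        canonical (document order of the input) and defines the row/column
        indices of every matrix and CSV built from this tree.
    policy
        ``"type1"`` (labels must be leaves) or ``"type2"`` (internal nodes
        may be labels).
    label_leaf
        Optional mapping label -> representative leaf, populated when a
        type-2 tree has been augmented with virtual leaves (see
        :func:`soe.hxe.augment_type2_tree`).  ``None`` otherwise.
    """

    parent: Mapping[str, str]
    root: str
    labels: tuple[str, ...]
    policy: str = "type2"
    label_leaf: Mapping[str, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.policy not in ("type1", "type2"):
            raise PolicyError(f"unknown policy {self.policy!r}")
        object.__setattr__(self, "parent", dict(self.parent))
        object.__setattr__(self, "labels", tuple(self.labels))
        nodes = set(self.parent) | set(self.parent.values()) | {self.root}
        object.__setattr__(self, "_nodes", frozenset(nodes))
        if self.root in self.parent:
            raise StructureError(f"root {self.root!r} has a parent")
        # Build children map and check single-rootedness / reachability.
        children: dict[str, list[str]] = {n: [] for n in nodes}
        for child, par in self.parent.items():
            if par not in nodes:
                raise StructureError(f"parent {par!r} is not a node")
            children[par].append(child)
        object.__setattr__(self, "_children", {k: tuple(v) for k, v in children.items()})
        reached = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in reached:
                raise StructureError("cycle detected in parent mapping")
            reached.add(n)
            stack.extend(children[n])
        if reached != nodes:
            orphans = sorted(nodes - reached)
            raise StructureError(
                f"nodes unreachable from root (multiple roots or cycle): {orphans}"
            )
        for lab in self.labels:
            if lab not in nodes:
                raise NodeLookupError(f"label {lab!r} is not a node")
        if self.policy == "type1":
            bad = [l for l in self.labels if self._children[l]]
            if bad:
                raise PolicyError(
                    f"type-1 policy requires leaf labels; internal labels: {bad}"
                )

    # -- basic structure ---------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return self._nodes  # type: ignore[attr-defined]

    def children(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return self._children[node]  # type: ignore[attr-defined]

    def is_leaf(self, node: str) -> bool:
        return not self.children(node)

    def leaves(self, node: str | None = None) -> tuple[str, ...]:
        """Leaves of the subtree rooted at ``node`` (default: whole tree),
        in stable depth-first order."""
        start = self.root if node is None else node
        self._check(start)
        out: list[str] = []
        stack = [start]
        while stack:
            n = stack.pop()
            ch = self._children[n]  # type: ignore[attr-defined]
            if ch:
                stack.extend(reversed(ch))
            else:
                out.append(n)
        return tuple(out)

    def ancestors(self, node: str) -> tuple[str, ...]:
        """Path from ``node`` up to the root, inclusive of both ends.

        A node is considered its own ancestor."""
        self._check(node)
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return tuple(path)

    def depth(self, node: str) -> int:
        """Number of edges from the root down to ``node``."""
        return len(self.ancestors(node)) - 1

    def height(self, node: str | None = None) -> int:
        """Max number of edges from ``node`` down to a leaf of its subtree.

        Leaves have height 0; ``height()`` with no argument is the height of
        the root, i.e. the height of the tree."""
        start = self.root if node is None else node
        self._check(start)
        return self._heights()[start]

    @lru_cache(maxsize=None)
    def _heights(self) -> dict[str, int]:
        h: dict[str, int] = {}
        # Post-order over an explicit stack; trees can be deep.
        stack: list[tuple[str, bool]] = [(self.root, False)]
        while stack:
            n, done = stack.pop()
            ch = self._children[n]  # type: ignore[attr-defined]
            if done or not ch:
                h[n] = 1 + max((h[c] for c in ch), default=-1)
            else:
                stack.append((n, True))
                stack.extend((c, False) for c in ch)
        return h

    def lca(self, a: str, b: str) -> str:
        """Deepest node that is an ancestor of both ``a`` and ``b``."""
        anc_a = self.ancestors(a)
        anc_b = set(self.ancestors(b))
        for n in anc_a:  # ancestors() starts at the node itself
            if n in anc_b:
                return n
        return self.root  # unreachable: root is a common ancestor

    def leaf_for_label(self, label: str) -> str:
        """Leaf node representing ``label`` (identity unless augmented)."""
        if label not in self.labels:
            raise NodeLookupError(f"{label!r} is not a label")
        if self.label_leaf is not None:
            return self.label_leaf[label]
        return label

    def _check(self, node: str) -> None:
        if node not in self._nodes:  # type: ignore[attr-defined]
            raise NodeLookupError(f"unknown node {node!r}")

    def __hash__(self) -> int:  # frozen dataclass with dict fields
        return hash((self.root, self.labels, tuple(sorted(self.parent.items()))))


@dataclass(frozen=True)
class CostMatrix:
    """K x K matrix of LCA heights between class labels.

    ``values[i, j]`` is the height of the lowest common ancestor of
    ``labels[i]`` and ``labels[j]`` — the severity incurred by predicting
    label *i* when the truth is label *j*.  The diagonal is identically zero
    (a correct prediction costs nothing, even for internal-node labels).
    The matrix is symmetric and ultrametric, with entries bounded by the
    height of the root.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        v = np.asarray(self.values)
        k = len(self.labels)
        if v.shape != (k, k):
            raise InputError(f"cost matrix shape {v.shape} != ({k}, {k})")
        v = v.astype(float)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def max_cost(self) -> float:
        """Largest entry: the worst severity a single mistake can incur."""
        return float(self.values.max())

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise NodeLookupError(f"unknown label {label!r}") from None

    def cost(self, predicted: str, truth: str) -> float:
        return float(self.values[self.index(predicted), self.index(truth)])


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def parse_hierarchy(spec: Mapping | str, policy: str = "type2") -> HierarchyTree:
    """Build a :class:`HierarchyTree` from a nested JSON tree document.

    ``spec`` is a mapping (or a JSON string) of the form
    ``{"name": str, "is_label": bool (optional), "children": [...]}``.
    Node names must be unique.  If no node carries an ``is_label`` flag the
    defaults apply: all leaves for ``type1``, all non-root nodes for
    ``type2``.  Labels are ordered by document (pre-order) position.
    """
    if isinstance(spec, str):
        spec = json.loads(spec)
    if not isinstance(spec, Mapping) or "name" not in spec:
        raise FormatError("hierarchy document must be a node object with a 'name'")

    parent: dict[str, str] = {}
    order: list[str] = []
    flagged: list[str] = []
    any_flag = False

    def visit(node: Mapping, par: str | None) -> None:
        nonlocal any_flag
        name = node.get("name")
        if not isinstance(name, str) or not name:
            raise FormatError("every node needs a non-empty string 'name'")
        if name in parent or (par is None and order and name == order[0]) or name in order:
            raise FormatError(f"duplicate node name {name!r}")
        order.append(name)
        if par is not None:
            parent[name] = par
        if "is_label" in node:
            any_flag = True
            if node["is_label"]:
                flagged.append(name)
        children = node.get("children", [])
        if not isinstance(children, list):
            raise FormatError(f"'children' of {name!r} must be a list")
        for ch in children:
            visit(ch, name)

    visit(spec, None)
    root = order[0]
    tree_nodes = set(order)
    children_of = {n: [] for n in tree_nodes}
    for c, p in parent.items():
        children_of[p].append(c)

    if any_flag:
        labels = flagged
    elif policy == "type1":
        labels = [n for n in order if not children_of[n]]
    else:
        labels = [n for n in order if n != root]
    return HierarchyTree(parent=parent, root=root, labels=tuple(labels), policy=policy)


def parse_newick(newick: str, policy: str = "type2") -> HierarchyTree:
    """Read a taxonomy from a newick string, e.g. ``"((a1,a2)A,(b1)B)R;"``.

    Internal nodes must be named (required for type-2 labelling and for LCA
    reporting).  The string is converted to the same nested structure as the
    JSON reader; default label flags follow the policy.
    """
    import dendropy

    try:
        t = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"invalid newick string: {exc}") from exc

    def name_of(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        raise FormatError("newick input requires every node to be named")

    def to_doc(node) -> dict:
        doc: dict = {"name": name_of(node)}
        kids = node.child_nodes()
        if kids:
            doc["children"] = [to_doc(k) for k in kids]
        return doc

    return parse_hierarchy(to_doc(t.seed_node), policy=policy)


def build_from_codes(
    codes: Sequence[str], level_cutpoints: Sequence[int], root_name: str = "root"
) -> HierarchyTree:
    """Build a type-2 tree from hierarchical code strings (ICD-10-style).

    Codes like ``J12.0`` nest by shared prefixes: with cutpoints ``[1, 3, 5]``
    the code hangs under ``J12``, which hangs under ``J``, which hangs under a
    synthetic root.  Every input code becomes a labelled node; intermediate
    prefixes that are not themselves codes are unlabelled structure.

    Parameters
    ----------
    codes
        Non-empty list of code strings; duplicates are collapsed.
    level_cutpoints
        Strictly increasing prefix lengths defining the levels.
    """
    if not codes:
        raise InputError("empty code list")
    cut = list(level_cutpoints)
    if cut != sorted(set(cut)) or any(c <= 0 for c in cut):
        raise InputError(f"cutpoints must be strictly increasing and positive: {cut}")

    seen: dict[str, None] = {}
    for code in codes:
        if len(code) < cut[0]:
            raise FormatError(
                f"code {code!r} shorter than the first cutpoint {cut[0]}"
            )
        seen.setdefault(code)

    parent: dict[str, str] = {}

    def chain(code: str) -> None:
        levels = [code[:c] for c in cut if c <= len(code)]
        if levels[-1] != code:  # code longer than the last cutpoint
            levels.append(code)
        prev = root_name
        for node in levels:
            if node in parent and parent[node] != prev:
                raise FormatError(f"code {node!r} nests inconsistently")
            if node != prev:
                parent.setdefault(node, prev)
                prev = node

    for code in seen:
        chain(code)
    return HierarchyTree(
        parent=parent, root=root_name, labels=tuple(seen), policy="type2"
    )


# ---------------------------------------------------------------------------
# LCA facts and the cost matrix
# ---------------------------------------------------------------------------


def lca(tree: HierarchyTree, a: str, b: str) -> str:
    """Lowest common ancestor of ``a`` and ``b`` (a node is its own ancestor)."""
    return tree.lca(a, b)


def node_height(tree: HierarchyTree, v: str) -> int:
    """Max edge-count from ``v`` to a leaf of its subtree; 0 for leaves."""
    return tree.height(v)


def cost_matrix(tree: HierarchyTree) -> CostMatrix:
    """LCA-height cost matrix over the tree's labels, in label order.

    Off-diagonal entry ``(i, j)`` is ``height(lca(label_i, label_j))``; the
    diagonal is forced to zero even for internal-node labels, since a correct
    prediction must incur no cost.
    """
    labs = tree.labels
    if not labs:
        raise InputError("tree has no labels")
    k = len(labs)
    anc = {l: tree.ancestors(l) for l in labs}
    anc_set = {l: set(a) for l, a in anc.items()}
    heights = {n: tree.height(n) for n in tree.nodes}
    values = np.zeros((k, k), dtype=float)
    for i, li in enumerate(labs):
        for j in range(i + 1, k):
            lj = labs[j]
            common = next(n for n in anc[li] if n in anc_set[lj])
            values[i, j] = values[j, i] = heights[common]
    return CostMatrix(labels=labs, values=values)


def chexpert_tree() -> HierarchyTree:
    """The packaged 14-label chest-radiograph taxonomy (type-2, height 2).

    Level 1 holds No Finding, Support Devices, Fracture, Enlarged
    Cardiomediastinum and Lung Opacity; Cardiomegaly sits under Enlarged
    Cardiomediastinum and the eight specific lung findings sit under Lung
    Opacity.  The tree ships as a JSON data file so users can substitute
    their own edge list without touching code.
    """
    doc = resources.files("soe.data").joinpath("chexpert.json").read_text("utf-8")
    return parse_hierarchy(json.loads(doc), policy="type2")
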