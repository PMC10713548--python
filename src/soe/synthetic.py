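"""Synthetic hierarchies and classifier outputs.

Real hierarchical-image datasets are large, access-restricted and need
trained networks before any severity question can be asked.  Everything this
package measures, however, lives in score space: a taxonomy, per-sample
scores, and ground truth.  This module generates exactly those, with
controllable calibration and — crucially — controllable *confusion
structure*: errors can be concentrated within a branch of the taxonomy
(low-severity mistakes) or across branches (high-severity mistakes), at an
equal error budget.  That is the knife-edge that separates severity from
plain error count.

All generators are pure functions of their arguments: one integer seed per
call, split into independent sub-streams with ``numpy.random.SeedSequence``
so outputs are reproducible and insensitive to internal draw order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .hierarchy import HierarchyTree
from .severity import MulticlassBatch, MultilabelBatch

__all__ = [
    "SimulationConfig",
    "random_tree",
    "simulate_multiclass",
    "simulate_multilabel",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study conditions.

    Defaults describe a modest medical-style taxonomy (two levels below the
    root, a handful of branches) with a moderately accurate, calibrated
    classifier and equal within/cross-branch corruption rates.
    """

    seed: int = 0
    tree_depth: int = 2
    branching: tuple[int, int] = (3, 5)
    n_samples: int = 5000
    concentration: float = 1.0
    temperature: float | None = None  # None = calibrated scores
    prevalence: float = 0.15
    within_flip: float = 0.15
    cross_flip: float = 0.15
    policy: str = "type2"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InputError("n_samples must be >= 1")
        for name in ("prevalence", "within_flip", "cross_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.temperature is not None and self.temperature <= 0:
            raise InputError("temperature must be > 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for sub-stream ``stream`` of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def random_tree(
    depth: int,
    branching_range: tuple[int, int],
    seed: int,
    policy: str = "type1",
) -> HierarchyTree:
    """Random rooted taxonomy of the given depth.

    Every internal node receives a child count drawn uniformly from
    ``branching_range``; nodes at ``depth`` are leaves, so the tree height
    never exceeds ``depth``.  Node names encode their path (``root/1/0``),
    labels follow document (pre-order) order.
    """
    lo, hi = branching_range
    if depth < 1:
        raise InputError("depth must be >= 1")
    if lo < 1 or hi < lo:
        raise InputError(f"impossible branching range {branching_range}")
    rng = _rng(seed, 0)
    parent: dict[str, str] = {}
    order = ["root"]

    def grow(node: str, d: int) -> None:
        if d == depth:
            return
        k = int(rng.integers(lo, hi + 1))
        for i in range(k):
            child = f"{node}/{i}"
            parent[child] = node
            order.append(child)
            grow(child, d + 1)

    grow("root", 0)
    children = set(parent.values())
    if policy == "type1":
        labels = tuple(n for n in order if n not in children)
    else:
        labels = tuple(order[1:])
    return HierarchyTree(parent=parent, root="root", labels=labels, policy=policy)


# ---------------------------------------------------------------------------
# Multiclass scores
# ---------------------------------------------------------------------------


def simulate_multiclass(
    tree: HierarchyTree,
    n: int,
    concentration: float = 1.0,
    temperature: float | None = None,
    seed: int = 0,
) -> MulticlassBatch:
    """Sample (scores, truth) pairs from a known joint distribution.

    Per sample a true conditional ``p`` is drawn from a symmetric Dirichlet
    with the given concentration, the true label is sampled from ``p``, and
    the reported scores are ``p`` itself (``temperature=None``: a perfectly
    calibrated classifier) or the tempered distortion
    ``p**(1/T) / sum`` (``T`` large flattens toward uniform).  Under the
    calibrated setting the CRM decision is Bayes-optimal for the LCA cost,
    which is what makes this generator the test bed for severity reduction.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if concentration <= 0:
        raise InputError("concentration must be > 0")
    if temperature is not None and temperature <= 0:
        raise InputError("temperature must be > 0")
    k = len(tree.labels)
    rng = _rng(seed, 1)
    conditionals = rng.dirichlet(np.full(k, concentration), size=n)
    cum = conditionals.cumsum(axis=1)
    u = rng.random(n)
    truth_idx = (u[:, None] > cum).sum(axis=1)
    scores = conditionals
    if temperature is not None:
        scores = conditionals ** (1.0 / temperature)
        scores /= scores.sum(axis=1, keepdims=True)
    return MulticlassBatch(
        sample_ids=tuple(range(n)),
        labels=tree.labels,
        scores=scores,
        true_labels=tuple(tree.labels[i] for i in truth_idx),
    )


# ---------------------------------------------------------------------------
# Multilabel scores
# ---------------------------------------------------------------------------


def _level1_ancestor(tree: HierarchyTree, node: str) -> str:
    """The node's ancestor that is a child of the root (itself if depth 1)."""
    path = tree.ancestors(node)  # node ... root
    return path[-2] if len(path) >= 2 else node


def simulate_multilabel(
    tree: HierarchyTree,
    n: int,
    prevalence: float = 0.15,
    within_flip: float = 0.0,
    cross_flip: float = 0.0,
    seed: int = 0,
) -> MultilabelBatch:
    """Hierarchy-consistent multilabel truths with branch-aware corruption.

    Truths: each label is drawn positive at ``prevalence`` and all labelled
    ancestors of a positive are switched on, so every true vector respects
    the taxonomy (child positive implies ancestors positive).

    Predictions: starting from the truth, each sample's *deepest* positive
    label is, with probability ``within_flip``, swapped for a different
    label under the same level-1 branch (a mild mistake), or, with
    probability ``cross_flip``, swapped for a label under a different
    level-1 branch (a severe mistake).  Working on the deepest positive and
    splitting by level-1 branch directly manipulates the LCA height of the
    induced error, so the two rates move the severity statistic — not just
    the error count.  Scores are the corrupted binary vectors smoothed into
    (0, 1) on either side of 0.5.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    for name, v in (("prevalence", prevalence), ("within_flip", within_flip), ("cross_flip", cross_flip)):
        if not 0.0 <= v <= 1.0:
            raise InputError(f"{name} must be in [0, 1], got {v}")
    if within_flip + cross_flip > 1.0:
        raise InputError("within_flip + cross_flip must be <= 1")

    labels = tree.labels
    k = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    depths = np.array([tree.depth(l) for l in labels])
    branch = [_level1_ancestor(tree, l) for l in labels]
    labelled_ancestors = [
        [idx[a] for a in tree.ancestors(l) if a in idx] for l in labels
    ]

    rng_truth = _rng(seed, 2)
    rng_flip = _rng(seed, 3)
    rng_noise = _rng(seed, 4)

    base = rng_truth.random((n, k)) < prevalence
    truth = np.zeros((n, k), dtype=np.int8)
    for i in range(n):
        for j in np.flatnonzero(base[i]):
            truth[i, labelled_ancestors[j]] = 1

    pred = truth.copy()
    u = rng_flip.random(n)
    for i in range(n):
        pos = np.flatnonzero(truth[i])
        if pos.size == 0:
            continue
        deepest = pos[np.argmax(depths[pos])]
        if u[i] < within_flip:
            cands = [
                j for j in range(k)
                if branch[j] == branch[deepest] and j != deepest and not truth[i, j]
            ]
        elif u[i] < within_flip + cross_flip:
            cands = [
                j for j in range(k)
                if branch[j] != branch[deepest] and not truth[i, j]
            ]
        else:
            continue
        if not cands:
            continue
        pred[i, deepest] = 0
        pred[i, cands[int(rng_flip.integers(len(cands)))]] = 1

    # Smooth the binary predictions into scores strictly inside (0, 1),
    # on the correct side of the 0.5 threshold.
    noise = rng_noise.uniform(0.05, 0.45, size=(n, k))
    scores = np.where(pred == 1, 1.0 - noise, noise)
    return MultilabelBatch(
        sample_ids=tuple(range(n)),
        labels=labels,
        scores=scores,
        true_vectors=truth,
    )
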