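"""Severity of Error (SoE) metrics for multiclass and multilabel classifiers.

The severity of a single prediction is the LCA-height cost between the
predicted and true labels; the severity of a classifier is the expectation
of that cost over samples.  For multilabel outputs the per-sample severity
averages, over the missed true labels (false negatives, the set ``J``), the
LCA costs to every spurious predicted label (false positives, the set
``I``)::

    S = (1 / |J|) * sum_{i in I} sum_{j in J} cost(i, j)

so a sample with predictions identical to the truth scores 0, and a sample
whose errors stay within one branch of the taxonomy scores lower than one
whose errors cross branches.  When ``J`` is empty the double sum is empty
and the severity is 0 — false-positive-only errors cost nothing under this
statistic, which callers should keep in mind when interpreting it.

Companion discrimination metrics (accuracy, AUROC, macro F1) are included so
reports can show that low error *count* and low error *severity* are
different axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .errors import FormatError, InputError, NodeLookupError
from .hierarchy import CostMatrix, HierarchyTree

logger = logging.getLogger(__name__)

__all__ = [
    "MulticlassBatch",
    "MultilabelBatch",
    "sample_severity",
    "classifier_severity",
    "multilabel_severity",
    "multilabel_classifier_severity",
    "per_label_severity",
    "collapse_multilabel_to_multiclass",
    "accuracy",
    "auroc",
    "macro_auroc",
    "macro_f1",
    "read_multiclass_csv",
    "read_multilabel_csv",
    "write_multiclass_csv",
    "write_multilabel_csv",
]


# ---------------------------------------------------------------------------
# Batches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MulticlassBatch:
    """Per-sample class-probability scores plus a single true label each.

    ``scores`` is N x K with columns in ``labels`` order (the cost matrix's
    label order); rows should sum to ~1.
    """

    sample_ids: tuple
    labels: tuple[str, ...]
    scores: np.ndarray
    true_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "true_labels", tuple(self.true_labels))
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != len(self.labels):
            raise InputError(f"scores shape {s.shape} does not match label count")
        if s.shape[0] != len(self.true_labels) or s.shape[0] != len(self.sample_ids):
            raise InputError("scores, sample_ids and true_labels disagree on N")
        if s.shape[0] < 1:
            raise InputError("empty batch")
        labset = set(self.labels)
        bad = [t for t in self.true_labels if t not in labset]
        if bad:
            raise NodeLookupError(f"true labels not in label set: {sorted(set(bad))}")
        s.setflags(write=False)
        object.__setattr__(self, "scores", s)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def argmax_labels(self) -> tuple[str, ...]:
        """Top-1 predictions; ties broken by lowest label index."""
        return tuple(self.labels[k] for k in self.scores.argmax(axis=1))


@dataclass(frozen=True)
class MultilabelBatch:
    """Per-sample independent per-label scores in [0, 1] plus binary truth."""

    sample_ids: tuple
    labels: tuple[str, ...]
    scores: np.ndarray
    true_vectors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        s = np.asarray(self.scores, dtype=float)
        t = np.asarray(self.true_vectors)
        k = len(self.labels)
        if s.ndim != 2 or s.shape[1] != k:
            raise InputError(f"scores shape {s.shape} does not match label count")
        if t.shape != s.shape or s.shape[0] != len(self.sample_ids):
            raise InputError("scores, truth and sample_ids disagree on shape")
        if s.shape[0] < 1:
            raise InputError("empty batch")
        if not np.isin(t, (0, 1)).all():
            raise InputError("true_vectors must be binary 0/1")
        t = t.astype(np.int8)
        s.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "true_vectors", t)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def binarized(self, threshold: float = 0.5) -> np.ndarray:
        """Predicted binary vectors: score >= threshold."""
        if not 0.0 < threshold < 1.0:
            raise InputError(f"threshold must be in (0, 1), got {threshold}")
        return (self.scores >= threshold).astype(np.int8)


def _check_alignment(batch_labels: Sequence[str], cost: CostMatrix) -> None:
    if tuple(batch_labels) != cost.labels:
        raise FormatError(
            "batch label order does not match the cost matrix; "
            "reorder the input explicitly (silent reordering is not done)"
        )


# ---------------------------------------------------------------------------
# Severity
# ---------------------------------------------------------------------------


def sample_severity(cost: CostMatrix, predicted: str, truth: str) -> float:
    """LCA-height severity of a single prediction; 0 iff correct."""
    return cost.cost(predicted, truth)


def classifier_severity(
    batch: MulticlassBatch,
    cost: CostMatrix,
    decision: str | Sequence[str] = "argmax",
) -> tuple[float, float]:
    """Mean and population std of per-sample severity over *all* samples.

    Correct predictions contribute 0, so the distribution is zero-inflated
    and the std typically exceeds the mean for accurate models.

    ``decision`` is ``"argmax"`` or an explicit sequence of predicted labels
    (e.g. the output of CRM relabelling).
    """
    _check_alignment(batch.labels, cost)
    if isinstance(decision, str):
        if decision != "argmax":
            raise InputError(f"unknown decision rule {decision!r}")
        predicted = batch.argmax_labels()
    else:
        predicted = tuple(decision)
        if len(predicted) != batch.n_samples:
            raise InputError("provided labels length does not match batch")
    sev = per_sample_severities(batch, cost, predicted)
    return float(sev.mean()), float(sev.std())


def per_sample_severities(
    batch: MulticlassBatch, cost: CostMatrix, predicted: Sequence[str]
) -> np.ndarray:
    """Vector of LCA severities for explicit predicted labels."""
    pi = np.array([cost.index(p) for p in predicted])
    ti = np.array([cost.index(t) for t in batch.true_labels])
    return cost.values[pi, ti]


def multilabel_severity(
    cost: CostMatrix,
    predicted_vector: Sequence[int] | np.ndarray,
    true_vector: Sequence[int] | np.ndarray,
) -> float:
    """Per-sample multilabel severity.

    Averages, over the missed true labels ``J``, the summed LCA costs to the
    spurious predicted labels ``I``.  Returns 0 when ``J`` is empty (the
    double sum is empty; note this means purely false-positive errors score
    0).  Bounded above by ``|I| * H`` where ``H`` is the tree height.
    """
    p = np.asarray(predicted_vector)
    t = np.asarray(true_vector)
    if p.shape != t.shape or p.ndim != 1:
        raise InputError(f"vector shapes disagree: {p.shape} vs {t.shape}")
    if p.shape[0] != cost.n_labels:
        raise InputError("vector length does not match cost matrix")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise InputError("severity vectors must be binary 0/1")
    fp = (p == 1) & (t == 0)  # I: predicted but not true
    fn = (t == 1) & (p == 0)  # J: true but not predicted
    n_fn = int(fn.sum())
    if n_fn == 0:
        return 0.0
    return float(cost.values[np.ix_(fp, fn)].sum() / n_fn)


def multilabel_classifier_severity(
    batch: MultilabelBatch, cost: CostMatrix, threshold: float = 0.5
) -> tuple[float, float]:
    """Mean and population std of per-sample multilabel severity after
    binarizing scores at ``threshold``."""
    _check_alignment(batch.labels, cost)
    pred = batch.binarized(threshold)
    sev = np.array(
        [
            multilabel_severity(cost, pred[i], batch.true_vectors[i])
            for i in range(batch.n_samples)
        ]
    )
    return float(sev.mean()), float(sev.std())


def per_label_severity(
    batch: MulticlassBatch | MultilabelBatch,
    cost: CostMatrix,
    mode: str = "multiclass",
    threshold: float = 0.5,
    include_correct: bool = False,
) -> tuple[dict[str, float], frozenset[str]]:
    """Mean severity per true label.

    Multiclass: for each label, the mean single-sample severity over the
    *misclassified* samples with that truth (set ``include_correct=True`` to
    average over all samples of that truth instead).  Multilabel: for each
    label, the mean cost from every false-positive label to it, over samples
    where the label was missed.

    Returns ``(mapping, no_error_labels)``: labels that never appear in an
    error get severity 0.0 and are listed in the flag set.
    """
    _check_alignment(batch.labels, cost)
    values: dict[str, float] = {}
    no_error: set[str] = set()
    if mode == "multiclass":
        if not isinstance(batch, MulticlassBatch):
            raise InputError("multiclass mode requires a MulticlassBatch")
        predicted = batch.argmax_labels()
        sev = per_sample_severities(batch, cost, predicted)
        truths = np.array(batch.true_labels)
        for lab in batch.labels:
            mask = truths == lab
            if include_correct:
                sel = sev[mask]
            else:
                sel = sev[mask & (sev > 0)]
            if sel.size == 0:
                values[lab] = 0.0
                no_error.add(lab)
            else:
                values[lab] = float(sel.mean())
    elif mode == "multilabel":
        if not isinstance(batch, MultilabelBatch):
            raise InputError("multilabel mode requires a MultilabelBatch")
        pred = batch.binarized(threshold)
        truth = batch.true_vectors
        fp = (pred == 1) & (truth == 0)
        fn = (truth == 1) & (pred == 0)
        for j, lab in enumerate(batch.labels):
            costs: list[float] = []
            rows = np.flatnonzero(fn[:, j])
            for r in rows:
                costs.extend(cost.values[np.flatnonzero(fp[r]), j])
            if not costs:
                values[lab] = 0.0
                no_error.add(lab)
            else:
                values[lab] = float(np.mean(costs))
    else:
        raise InputError(f"unknown mode {mode!r}")
    return values, frozenset(no_error)


# ---------------------------------------------------------------------------
# Multilabel -> multiclass collapse
# ---------------------------------------------------------------------------


def collapse_multilabel_to_multiclass(
    batch: MultilabelBatch,
    tree: HierarchyTree,
    policy: str = "deepest",
    seed: int | None = None,
) -> MulticlassBatch:
    """Reduce a multilabel batch to multiclass by keeping one positive label.

    Policies: ``deepest`` keeps the deepest positive label in the taxonomy
    (ties by label order), ``first`` keeps the first positive in label order,
    ``seeded-random`` picks uniformly with a reproducible generator.  Samples
    with no positive label are dropped (the count is logged).  Scores are
    carried over row-normalized to sum to 1 so the result is a valid
    class-probability batch.
    """
    if tuple(batch.labels) != tuple(tree.labels):
        raise FormatError("batch label order does not match the tree")
    if policy not in ("deepest", "first", "seeded-random"):
        raise InputError(f"unknown collapse policy {policy!r}")
    rng = np.random.default_rng(seed)
    depths = np.array([tree.depth(l) for l in batch.labels])

    keep_rows: list[int] = []
    truths: list[str] = []
    for i in range(batch.n_samples):
        pos = np.flatnonzero(batch.true_vectors[i])
        if pos.size == 0:
            continue
        if policy == "deepest":
            chosen = pos[np.argmax(depths[pos])]
        elif policy == "first":
            chosen = pos[0]
        else:
            chosen = rng.choice(pos)
        keep_rows.append(i)
        truths.append(batch.labels[chosen])
    dropped = batch.n_samples - len(keep_rows)
    if dropped:
        logger.info("collapse dropped %d samples with no positive label", dropped)
    if not keep_rows:
        raise InputError("no samples left after dropping label-free samples")

    scores = batch.scores[keep_rows].copy()
    row_sums = scores.sum(axis=1, keepdims=True)
    uniform = np.full(len(batch.labels), 1.0 / len(batch.labels))
    scores = np.where(row_sums > 0, scores / np.where(row_sums > 0, row_sums, 1.0), uniform)
    return MulticlassBatch(
        sample_ids=tuple(batch.sample_ids[i] for i in keep_rows),
        labels=batch.labels,
        scores=scores,
        true_labels=tuple(truths),
    )


# ---------------------------------------------------------------------------
# Companion metrics
# ---------------------------------------------------------------------------


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise InputError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise InputError("confusion counts sum to zero")
    return (tp + tn) / total


def auroc(scores: Sequence[float], binary_truth: Sequence[int]) -> float | None:
    """Area under the ROC curve: probability a random positive outranks a
    random negative, ties counted 1/2.

    Returns ``None`` when only one class is present (the statistic is
    undefined); callers exclude such labels from macro averages.
    """
    y = np.asarray(binary_truth)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise InputError("scores and truth must be 1-D and equal length")
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, s))


def macro_auroc(scores: np.ndarray, truth: np.ndarray) -> float | None:
    """Macro-average AUROC over label columns, skipping undefined labels."""
    vals = [auroc(scores[:, k], truth[:, k]) for k in range(scores.shape[1])]
    defined = [v for v in vals if v is not None]
    return float(np.mean(defined)) if defined else None


def macro_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    """Macro-averaged binary F1 over label columns."""
    return float(f1_score(truth, pred, average="macro", zero_division=0))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------
#
# Multiclass: header `sample_id,true_label,<label_1>,...` with score columns.
# Multilabel: two files sharing the header `sample_id,<label_1>,...` — one
# with scores, one with binary truth.  Column order must equal the
# hierarchy's label order; a mismatch is an error, never a silent reorder.


def _check_columns(found: Sequence[str], expected: Sequence[str], path) -> None:
    if list(found) != list(expected):
        raise FormatError(
            f"{path}: label columns {list(found)} do not match the expected "
            f"order {list(expected)}"
        )


def read_multiclass_csv(path, labels: Sequence[str]) -> MulticlassBatch:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["sample_id", "true_label"]:
        raise FormatError(f"{path}: expected leading columns sample_id,true_label")
    _check_columns(df.columns[2:], labels, path)
    return MulticlassBatch(
        sample_ids=tuple(df["sample_id"]),
        labels=tuple(labels),
        scores=df.iloc[:, 2:].to_numpy(dtype=float),
        true_labels=tuple(df["true_label"]),
    )


def write_multiclass_csv(batch: MulticlassBatch, path) -> None:
    df = pd.DataFrame(batch.scores, columns=list(batch.labels))
    df.insert(0, "true_label", list(batch.true_labels))
    df.insert(0, "sample_id", list(batch.sample_ids))
    df.to_csv(path, index=False)


def read_multilabel_csv(scores_path, truth_path, labels: Sequence[str]) -> MultilabelBatch:
    sdf = pd.read_csv(scores_path)
    tdf = pd.read_csv(truth_path)
    for df, path in ((sdf, scores_path), (tdf, truth_path)):
        if df.columns[0] != "sample_id":
            raise FormatError(f"{path}: first column must be sample_id")
        _check_columns(df.columns[1:], labels, path)
    if list(sdf["sample_id"]) != list(tdf["sample_id"]):
        raise FormatError("scores and truth files list different sample_ids")
    return MultilabelBatch(
        sample_ids=tuple(sdf["sample_id"]),
        labels=tuple(labels),
        scores=sdf.iloc[:, 1:].to_numpy(dtype=float),
        true_vectors=tdf.iloc[:, 1:].to_numpy(),
    )


def write_multilabel_csv(batch: MultilabelBatch, scores_path, truth_path) -> None:
    for arr, path in ((batch.scores, scores_path), (batch.true_vectors, truth_path)):
        df = pd.DataFrame(arr, columns=list(batch.labels))
        df.insert(0, "sample_id", list(batch.sample_ids))
        df.to_csv(path, index=False)
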