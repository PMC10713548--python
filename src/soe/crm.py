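"""Conditional Risk Minimization (CRM): cost-aware post-inference relabelling.

Given a predictive distribution ``p`` over labels and the LCA-height cost
matrix ``C``, the conditional risk of answering label *k* is the expected
cost ``R(k) = sum_j C[k, j] * p(j)``.  CRM replaces the usual arg-max
decision with the risk minimizer ``argmin_k R(k)``, which is the Bayes
decision rule for the LCA cost when ``p`` is the true conditional — the
premise that makes CRM a severity reducer in the multiclass setting.  The
same risks re-rank the top-k list.

For multilabel outputs the combinatorial space of label subsets makes exact
risk minimization intractable; instead the risk vector ``C @ p`` itself is
rescaled into [0, 1] and read as per-label *soft labels* (low risk = high
score), which downstream code binarizes at the usual threshold.  How to
rescale is the module's largest interpretive step; both a sum-normalized and
a per-sample min-max variant are provided (default ``minmax``, since raw
``C @ p`` is unbounded when the scores do not sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError
from .hierarchy import CostMatrix
from .severity import MulticlassBatch, MultilabelBatch

__all__ = [
    "RiskVector",
    "conditional_risk",
    "crm_predict",
    "crm_rerank_topk",
    "crm_soft_labels",
    "crm_relabel_batch",
    "crm_soft_label_batch",
]


@dataclass(frozen=True)
class RiskVector:
    """Expected LCA cost of committing to each label, in label order."""

    labels: tuple[str, ...]
    risks: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        r = np.asarray(self.risks, dtype=float)
        if r.shape != (len(self.labels),):
            raise InputError("risk vector length does not match labels")
        r.setflags(write=False)
        object.__setattr__(self, "risks", r)

    def argmin_label(self) -> str:
        """Minimum-risk label; ties broken by lowest label index."""
        return self.labels[int(np.argmin(self.risks))]


def _validate_scores(p: Sequence[float], cost: CostMatrix) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (cost.n_labels,):
        raise InputError(
            f"score vector length {arr.shape} does not match {cost.n_labels} labels"
        )
    if (arr < 0).any():
        raise InputError("scores must be non-negative")
    return arr


def conditional_risk(p: Sequence[float], cost: CostMatrix) -> RiskVector:
    """Expected cost of each label under ``p``: ``risks = C @ p``."""
    arr = _validate_scores(p, cost)
    return RiskVector(labels=cost.labels, risks=cost.values @ arr)


def crm_predict(p: Sequence[float], cost: CostMatrix) -> str:
    """Minimum-conditional-risk label (deterministic tie-break by index)."""
    return conditional_risk(p, cost).argmin_label()


def crm_rerank_topk(p: Sequence[float], cost: CostMatrix, k: int) -> list[str]:
    """Top-k labels by ascending conditional risk, ties by label index."""
    if not 1 <= k <= cost.n_labels:
        raise InputError(f"k must be in [1, {cost.n_labels}], got {k}")
    rv = conditional_risk(p, cost)
    order = np.argsort(rv.risks, kind="stable")
    return [rv.labels[i] for i in order[:k]]


def crm_soft_labels(
    p: Sequence[float], cost: CostMatrix, normalize: str = "minmax"
) -> np.ndarray:
    """Multilabel CRM: turn the risk vector ``C @ p`` into soft labels.

    ``normalize="sum"`` renormalizes ``p`` to sum to 1 first, so every risk
    lies in [0, H] (H = max cost), and returns ``1 - r / H``.
    ``normalize="minmax"`` uses the raw scores and rescales the risks to
    [0, 1] per sample before flipping.  Either way low risk maps to a high
    score and the output lies in [0, 1]; a constant risk vector maps to a
    uniform 0.5.
    """
    arr = _validate_scores(p, cost)
    total = arr.sum()
    if total == 0:
        raise InputError("all-zero score vector: soft-label normalization undefined")
    if normalize == "sum":
        r = cost.values @ (arr / total)
        h = cost.max_cost
        if h == 0:  # single-label degenerate tree
            return np.full_like(r, 0.5)
        return 1.0 - r / h
    if normalize == "minmax":
        r = cost.values @ arr
        lo, hi = r.min(), r.max()
        if hi == lo:
            return np.full_like(r, 0.5)
        return 1.0 - (r - lo) / (hi - lo)
    raise InputError(f"unknown normalization {normalize!r}")


# ---------------------------------------------------------------------------
# Batch conveniences
# ---------------------------------------------------------------------------


def crm_relabel_batch(batch: MulticlassBatch, cost: CostMatrix) -> tuple[str, ...]:
    """CRM decision for every sample of a multiclass batch."""
    if batch.labels != cost.labels:
        raise InputError("batch label order does not match the cost matrix")
    risks = batch.scores @ cost.values.T  # row i -> C @ p_i
    return tuple(cost.labels[int(k)] for k in risks.argmin(axis=1))


def crm_soft_label_batch(
    batch: MultilabelBatch, cost: CostMatrix, normalize: str = "minmax"
) -> MultilabelBatch:
    """Replace every sample's scores with CRM soft labels."""
    if batch.labels != cost.labels:
        raise InputError("batch label order does not match the cost matrix")
    soft = np.vstack(
        [crm_soft_labels(batch.scores[i], cost, normalize) for i in range(batch.n_samples)]
    )
    return MultilabelBatch(
        sample_ids=batch.sample_ids,
        labels=batch.labels,
        scores=soft,
        true_vectors=batch.true_vectors,
    )
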