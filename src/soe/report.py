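"""Assembling severity reports and paired-condition comparison tables.

:func:`evaluate` runs every metric (mean/std severity, per-label severity,
accuracy, macro AUROC, macro F1) on one batch under one decision rule and
returns a :class:`SeverityReport`.  :func:`compare` evaluates the *same*
batch under two rules (e.g. arg-max vs CRM relabelling, or raw scores vs
CRM soft labels) and reports the paired metrics with the signed severity
delta — the shape used to ask whether a severity-reduction framework
actually reduced severity.  :func:`auroc_vs_soe_table` collects many reports
into a tidy table for discrimination-vs-severity scatter plots.

Reports serialize to JSON (machine) and to aligned text with
``mean ± std`` fields at two decimals (human).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .crm import crm_relabel_batch, crm_soft_label_batch
from .errors import FormatError, InputError
from .hierarchy import HierarchyTree, cost_matrix
from .severity import (
    MulticlassBatch,
    MultilabelBatch,
    classifier_severity,
    macro_auroc,
    macro_f1,
    multilabel_classifier_severity,
    per_label_severity,
)

__all__ = ["SeverityReport", "ComparisonTable", "evaluate", "compare", "auroc_vs_soe_table"]


@dataclass(frozen=True)
class SeverityReport:
    """All severity and companion metrics for one batch under one rule."""

    mean_soe: float
    std_soe: float
    per_label_soe: Mapping[str, float]
    no_error_labels: frozenset[str]
    auroc: float | None
    f1: float
    accuracy: float
    n_samples: int
    decision: str = "argmax"

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_label_soe", dict(self.per_label_soe))
        object.__setattr__(self, "no_error_labels", frozenset(self.no_error_labels))
        if self.mean_soe < 0 or self.std_soe < 0:
            raise InputError("severity summaries must be non-negative")

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "n_samples": self.n_samples,
            "mean_soe": self.mean_soe,
            "std_soe": self.std_soe,
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "f1": self.f1,
            "per_label_soe": dict(self.per_label_soe),
            "no_error_labels": sorted(self.no_error_labels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SeverityReport":
        return cls(
            mean_soe=d["mean_soe"],
            std_soe=d["std_soe"],
            per_label_soe=d["per_label_soe"],
            no_error_labels=frozenset(d["no_error_labels"]),
            auroc=d["auroc"],
            f1=d["f1"],
            accuracy=d["accuracy"],
            n_samples=d["n_samples"],
            decision=d.get("decision", "argmax"),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_text(self) -> str:
        auroc = "undefined" if self.auroc is None else f"{self.auroc:.4f}"
        lines = [
            f"samples   : {self.n_samples}",
            f"decision  : {self.decision}",
            f"SoE       : {self.mean_soe:.2f} ± {self.std_soe:.2f}",
            f"accuracy  : {self.accuracy:.4f}",
            f"AUROC     : {auroc}",
            f"macro F1  : {self.f1:.4f}",
            "per-label SoE:",
        ]
        for lab, v in self.per_label_soe.items():
            flag = "  (no errors)" if lab in self.no_error_labels else ""
            lines.append(f"  {lab:<28s} {v:.2f}{flag}")
        return "\n".join(lines)


def evaluate(
    batch: MulticlassBatch | MultilabelBatch,
    tree: HierarchyTree,
    decision: str | Sequence[str] = "argmax",
    threshold: float = 0.5,
    include_correct_per_label: bool = False,
    soft_label_normalize: str = "minmax",
) -> SeverityReport:
    """Compute one full report for a batch over the tree's label set.

    Multiclass decisions: ``"argmax"``, ``"crm"`` (relabel by conditional
    risk), or an explicit sequence of predicted labels.  Multilabel
    decisions: ``"scores"`` (binarize raw scores at ``threshold``) or
    ``"crm-soft"`` (binarize CRM soft labels).
    """
    if tuple(batch.labels) != tuple(tree.labels):
        raise FormatError("batch label order does not match the hierarchy")
    cost = cost_matrix(tree)

    if isinstance(batch, MulticlassBatch):
        if isinstance(decision, str):
            if decision == "argmax":
                predicted = batch.argmax_labels()
            elif decision == "crm":
                predicted = crm_relabel_batch(batch, cost)
            else:
                raise InputError(f"unknown multiclass decision {decision!r}")
            decision_name = decision
        else:
            predicted = tuple(decision)
            decision_name = "provided-labels"
        mean, std = classifier_severity(batch, cost, decision=predicted)
        per_label, no_err = per_label_severity(
            batch, cost, mode="multiclass", include_correct=include_correct_per_label
        )
        truths = np.array(batch.true_labels)
        correct = int((np.array(predicted) == truths).sum())
        acc = correct / batch.n_samples
        onehot = (truths[:, None] == np.array(batch.labels)[None, :]).astype(int)
        auc = macro_auroc(batch.scores, onehot)
        f1 = float(
            f1_score(
                truths, np.array(predicted), labels=list(batch.labels),
                average="macro", zero_division=0,
            )
        )
    else:
        if decision == "scores":
            scored = batch
        elif decision == "crm-soft":
            scored = crm_soft_label_batch(batch, cost, normalize=soft_label_normalize)
        else:
            raise InputError(f"unknown multilabel decision {decision!r}")
        decision_name = decision  # type: ignore[assignment]
        mean, std = multilabel_classifier_severity(scored, cost, threshold)
        per_label, no_err = per_label_severity(
            scored, cost, mode="multilabel", threshold=threshold
        )
        pred = scored.binarized(threshold)
        truth = scored.true_vectors
        acc = float((pred == truth).mean())  # element-wise (TP+TN)/(all)
        auc = macro_auroc(scored.scores, truth)
        f1 = macro_f1(pred, truth)

    return SeverityReport(
        mean_soe=mean,
        std_soe=std,
        per_label_soe=per_label,
        no_error_labels=no_err,
        auroc=auc,
        f1=f1,
        accuracy=acc,
        n_samples=batch.n_samples,
        decision=str(decision_name),
    )


@dataclass(frozen=True)
class ComparisonTable:
    """Paired metrics for identical batches under two decision rules."""

    rows: tuple[tuple[str, SeverityReport, SeverityReport], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        for _, a, b in self.rows:
            if a.n_samples != b.n_samples:
                raise InputError("paired reports must cover the identical batch")

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable long layout, one row per scenario."""
        recs = []
        for name, a, b in self.rows:
            recs.append(
                {
                    "scenario": name,
                    "condition_a": a.decision,
                    "condition_b": b.decision,
                    "auroc_a": a.auroc,
                    "auroc_b": b.auroc,
                    "f1_a": a.f1,
                    "f1_b": b.f1,
                    "soe_mean_a": a.mean_soe,
                    "soe_std_a": a.std_soe,
                    "soe_mean_b": b.mean_soe,
                    "soe_std_b": b.std_soe,
                    "soe_delta": b.mean_soe - a.mean_soe,
                }
            )
        return pd.DataFrame.from_records(recs)

    def format_text(self) -> str:
        def pm(m: float, s: float) -> str:
            return f"{m:.2f} ± {s:.2f}"

        lines = [
            f"{'scenario':<16s} {'SoE (A)':>14s} {'SoE (B)':>14s} {'delta':>8s}"
        ]
        for name, a, b in self.rows:
            lines.append(
                f"{name:<16s} {pm(a.mean_soe, a.std_soe):>14s} "
                f"{pm(b.mean_soe, b.std_soe):>14s} {b.mean_soe - a.mean_soe:>+8.2f}"
            )
        return "\n".join(lines)


def compare(
    batch: MulticlassBatch | MultilabelBatch,
    tree: HierarchyTree,
    condition_a: str = "argmax",
    condition_b: str = "crm",
    scenario: str = "batch",
    **options,
) -> ComparisonTable:
    """Evaluate one batch under two decision rules, paired."""
    rep_a = evaluate(batch, tree, decision=condition_a, **options)
    rep_b = evaluate(batch, tree, decision=condition_b, **options)
    return ComparisonTable(rows=((scenario, rep_a, rep_b),))


def auroc_vs_soe_table(
    reports: Mapping[str, SeverityReport] | Sequence[SeverityReport],
) -> pd.DataFrame:
    """Tidy (identifier, auroc, soe) table for discrimination-vs-severity
    scatters; undefined AUROCs carry an explicit flag column."""
    if isinstance(reports, Mapping):
        items = list(reports.items())
    else:
        items = [(str(i), r) for i, r in enumerate(reports)]
    if not items:
        raise InputError("need at least one report")
    return pd.DataFrame.from_records(
        [
            {
                "identifier": name,
                "auroc": np.nan if r.auroc is None else r.auroc,
                "auroc_defined": r.auroc is not None,
                "soe": r.mean_soe,
                "soe_std": r.std_soe,
            }
            for name, r in items
        ]
    )
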