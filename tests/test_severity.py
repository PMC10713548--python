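"""Severity metrics: single-sample, classifier-level, multilabel, per-label."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soe import (
    MulticlassBatch,
    MultilabelBatch,
    accuracy,
    auroc,
    classifier_severity,
    collapse_multilabel_to_multiclass,
    cost_matrix,
    multilabel_classifier_severity,
    multilabel_severity,
    per_label_severity,
    sample_severity,
)
from soe.errors import FormatError, InputError
from soe.severity import read_multiclass_csv, read_multilabel_csv, write_multiclass_csv, write_multilabel_csv

from conftest import brute_auroc

TOY_LABELS = ("A", "a1", "a2", "B", "b1")


def mc_batch(labels, true_labels, scores=None):
    n, k = len(true_labels), len(labels)
    if scores is None:
        scores = np.full((n, k), 1.0 / k)
    return MulticlassBatch(
        sample_ids=tuple(range(n)), labels=labels, scores=scores, true_labels=true_labels
    )


class TestSampleSeverity:
    def test_chexpert_cases(self, chexpert_cost):
        assert sample_severity(chexpert_cost, "No Finding", "Pneumonia") == 2
        assert sample_severity(chexpert_cost, "Consolidation", "Pneumonia") == 1
        assert sample_severity(chexpert_cost, "Edema", "Edema") == 0

    def test_zero_iff_correct(self, toy_cost2):
        for a in toy_cost2.labels:
            for b in toy_cost2.labels:
                sev = sample_severity(toy_cost2, a, b)
                assert (sev == 0) == (a == b)


class TestClassifierSeverity:
    def test_population_moments_of_explicit_severities(self, toy_cost2, toy_type2):
        # severities [2, 0, 1, 1]: prediction b1 for truth a1, then correct,
        # then two within-branch confusions
        truths = ("a1", "a2", "a1", "a2")
        preds = ("b1", "a2", "a2", "a1")
        batch = mc_batch(toy_type2.labels, truths)
        mean, std = classifier_severity(batch, toy_cost2, decision=preds)
        assert mean == pytest.approx(1.0)
        assert std == pytest.approx(np.sqrt(0.5))  # population std of [2,0,1,1]

    def test_all_correct_and_single_sample(self, toy_cost2, toy_type2):
        batch = mc_batch(toy_type2.labels, ("a1", "b1"))
        assert classifier_severity(batch, toy_cost2, decision=("a1", "b1")) == (0.0, 0.0)
        single = mc_batch(toy_type2.labels, ("a1",))
        assert classifier_severity(single, toy_cost2, decision=("b1",)) == (2.0, 0.0)

    def test_mean_is_arithmetic_mean_of_sample_severities(self, toy_cost2, toy_type2):
        rng = np.random.default_rng(5)
        labels = toy_type2.labels
        truths = tuple(rng.choice(labels, size=40))
        preds = tuple(rng.choice(labels, size=40))
        batch = mc_batch(labels, truths)
        mean, _ = classifier_severity(batch, toy_cost2, decision=preds)
        explicit = [sample_severity(toy_cost2, p, t) for p, t in zip(preds, truths)]
        assert mean == pytest.approx(np.mean(explicit))

    def test_argmax_decision_and_label_mismatch_error(self, toy_cost2, toy_type2):
        scores = np.eye(5)[[1, 3]]
        batch = mc_batch(toy_type2.labels, ("a1", "B"), scores)
        assert classifier_severity(batch, toy_cost2) == (0.0, 0.0)
        shuffled = cost_matrix(toy_type2)
        bad = MulticlassBatch(
            sample_ids=(0,), labels=("a1", "A", "a2", "B", "b1"),
            scores=np.full((1, 5), 0.2), true_labels=("a1",),
        )
        with pytest.raises(FormatError):
            classifier_severity(bad, shuffled)


class TestMultilabelSeverity:
    def test_hand_computed_cases(self, toy_cost2):
        truth = np.array([1, 1, 0, 0, 0])  # {A, a1}
        pred_cross = np.array([0, 0, 0, 1, 1])  # {B, b1}
        assert multilabel_severity(toy_cost2, pred_cross, truth) == pytest.approx(4.0)
        pred_within = np.array([1, 0, 1, 0, 0])  # {A, a2}
        assert multilabel_severity(toy_cost2, pred_within, truth) == pytest.approx(1.0)
        assert multilabel_severity(toy_cost2, truth, truth) == 0.0

    def test_false_positive_only_errors_cost_zero(self, toy_cost2):
        # J empty, I non-empty: the double sum is empty by definition
        truth = np.array([1, 0, 0, 0, 0])
        pred = np.array([1, 1, 0, 1, 0])
        assert multilabel_severity(toy_cost2, pred, truth) == 0.0

    def test_non_binary_and_mismatched_inputs_rejected(self, toy_cost2):
        with pytest.raises(InputError):
            multilabel_severity(toy_cost2, [0.5, 0, 0, 0, 0], [1, 0, 0, 0, 0])
        with pytest.raises(InputError):
            multilabel_severity(toy_cost2, [1, 0, 0], [1, 0, 0, 0, 0])

    def test_onehot_disagreement_reduces_to_sample_severity(self, toy_cost2):
        k = toy_cost2.n_labels
        for i in range(k):
            for j in range(k):
                pred = np.eye(k, dtype=int)[i]
                truth = np.eye(k, dtype=int)[j]
                expected = sample_severity(toy_cost2, toy_cost2.labels[i], toy_cost2.labels[j])
                assert multilabel_severity(toy_cost2, pred, truth) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance_and_bound(self, seed):
        """Permuting labels in vectors and matrix together leaves the score
        unchanged; the score never exceeds |I| * max-cost."""
        from soe import parse_hierarchy
        from conftest import TOY_DOC
        cm = cost_matrix(parse_hierarchy(TOY_DOC, policy="type2"))
        rng = np.random.default_rng(seed)
        k = cm.n_labels
        pred = rng.integers(0, 2, size=k)
        truth = rng.integers(0, 2, size=k)
        s = multilabel_severity(cm, pred, truth)
        n_fp = int(((pred == 1) & (truth == 0)).sum())
        assert 0 <= s <= n_fp * cm.max_cost
        perm = rng.permutation(k)
        from soe.hierarchy import CostMatrix
        cm_p = CostMatrix(
            labels=tuple(cm.labels[i] for i in perm),
            values=cm.values[np.ix_(perm, perm)],
        )
        assert multilabel_severity(cm_p, pred[perm], truth[perm]) == pytest.approx(s)


class TestMultilabelClassifierSeverity:
    def test_mean_of_hand_computed_samples(self, toy_cost2):
        truth = np.array([[1, 1, 0, 0, 0]] * 3)
        scores = np.array(
            [[0.1, 0.2, 0.3, 0.9, 0.8],   # predicts {B, b1} -> 4.0
             [0.9, 0.1, 0.8, 0.2, 0.1],   # predicts {A, a2} -> 1.0
             [0.9, 0.9, 0.1, 0.1, 0.1]]   # predicts truth   -> 0.0
        )
        batch = MultilabelBatch(
            sample_ids=(0, 1, 2), labels=toy_cost2.labels,
            scores=scores, true_vectors=truth,
        )
        mean, std = multilabel_classifier_severity(batch, toy_cost2, 0.5)
        assert mean == pytest.approx(5.0 / 3.0)
        assert std == pytest.approx(np.std([4.0, 1.0, 0.0]))

    def test_threshold_rebinarization_is_monotone(self, toy_cost2):
        truth = np.array([[1, 0, 0, 0, 0]])
        scores = np.array([[0.45, 0.1, 0.1, 0.1, 0.1]])
        batch = MultilabelBatch((0,), toy_cost2.labels, scores, truth)
        miss, _ = multilabel_classifier_severity(batch, toy_cost2, 0.5)
        hit, _ = multilabel_classifier_severity(batch, toy_cost2, 0.4)
        assert hit == 0.0 and miss == 0.0  # FN with no FP still costs 0
        with pytest.raises(InputError):
            multilabel_classifier_severity(batch, toy_cost2, 1.5)


class TestPerLabelSeverity:
    def test_single_error_multiclass(self, toy_cost2, toy_type2):
        scores = np.eye(5)[[2, 3]]  # predict a2 (truth a1), B (truth B)
        batch = mc_batch(toy_type2.labels, ("a1", "B"), scores)
        values, no_err = per_label_severity(batch, toy_cost2, mode="multiclass")
        assert values["a1"] == pytest.approx(1.0)
        assert values["B"] == 0.0 and "B" in no_err and "a1" not in no_err

    def test_error_only_averaging_vs_all_samples(self, toy_cost2, toy_type2):
        # truth a1 twice: one correct, one cross-branch error (severity 2)
        scores = np.eye(5)[[1, 4]]
        batch = mc_batch(toy_type2.labels, ("a1", "a1"), scores)
        err_only, _ = per_label_severity(batch, toy_cost2, mode="multiclass")
        all_samples, _ = per_label_severity(
            batch, toy_cost2, mode="multiclass", include_correct=True
        )
        assert err_only["a1"] == pytest.approx(2.0)
        assert all_samples["a1"] == pytest.approx(1.0)

    def test_multilabel_mode_restricted_to_missed_labels(self, toy_cost2):
        truth = np.array([[0, 1, 0, 0, 0]])  # a1 true, missed
        scores = np.array([[0.1, 0.1, 0.9, 0.1, 0.1]])  # a2 false positive
        batch = MultilabelBatch((0,), toy_cost2.labels, scores, truth)
        values, no_err = per_label_severity(batch, toy_cost2, mode="multilabel")
        assert values["a1"] == pytest.approx(1.0)  # cost(a2, a1)
        assert values["B"] == 0.0 and "B" in no_err


class TestCollapse:
    def _batch(self, labels):
        truth = np.array([[0, 0, 0, 0, 0], [1, 1, 0, 0, 0], [0, 0, 0, 1, 1]])
        scores = np.full((3, 5), 0.2)
        return MultilabelBatch((0, 1, 2), labels, scores, truth)

    def test_deepest_policy_and_dropping(self, toy_type2):
        batch = self._batch(toy_type2.labels)
        mc = collapse_multilabel_to_multiclass(batch, toy_type2, policy="deepest")
        assert mc.n_samples == 2  # label-free sample dropped
        assert mc.true_labels == ("a1", "b1")

    def test_first_policy_single_positive(self, toy_type2):
        truth = np.array([[0, 0, 1, 0, 0]])
        batch = MultilabelBatch((0,), toy_type2.labels, np.full((1, 5), 0.2), truth)
        mc = collapse_multilabel_to_multiclass(batch, toy_type2, policy="first")
        assert mc.true_labels == ("a2",)

    def test_seeded_random_deterministic(self, toy_type2):
        batch = self._batch(toy_type2.labels)
        a = collapse_multilabel_to_multiclass(batch, toy_type2, "seeded-random", seed=9)
        b = collapse_multilabel_to_multiclass(batch, toy_type2, "seeded-random", seed=9)
        assert a.true_labels == b.true_labels

    def test_chexpert_deepest_prefers_level2(self, chexpert):
        k = len(chexpert.labels)
        truth = np.zeros((1, k), dtype=int)
        truth[0, chexpert.labels.index("Lung Opacity")] = 1
        truth[0, chexpert.labels.index("Pneumonia")] = 1
        batch = MultilabelBatch((0,), chexpert.labels, np.full((1, k), 0.2), truth)
        mc = collapse_multilabel_to_multiclass(batch, chexpert, policy="deepest")
        assert mc.true_labels == ("Pneumonia",)


class TestCompanionMetrics:
    @pytest.mark.parametrize(
        "counts,expected", [((1, 1, 1, 1), 0.5), ((10, 0, 0, 0), 1.0), ((0, 0, 5, 5), 0.0)]
    )
    def test_accuracy(self, counts, expected):
        assert accuracy(*counts) == expected

    def test_accuracy_degenerate(self):
        with pytest.raises(InputError):
            accuracy(0, 0, 0, 0)

    def test_auroc_known_values(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
        assert auroc([0.9, 0.2, 0.8, 0.3], [1, 0, 0, 1]) == 0.75
        assert auroc([0.5, 0.5], [1, 1]) is None  # single class: undefined

    def test_auroc_matches_pair_counting_oracle_exhaustively(self):
        """All score/truth combinations of n <= 8 over a tied score grid."""
        rng = np.random.default_rng(77)
        for _ in range(300):
            n = int(rng.integers(2, 9))
            scores = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=n)
            truth = rng.integers(0, 2, size=n)
            assert auroc(scores, truth) == pytest.approx(brute_auroc(scores, truth))


class TestCsvRoundTrip:
    def test_multiclass_roundtrip_and_column_order_enforced(self, toy_type1, tmp_path):
        labels = toy_type1.labels
        batch = MulticlassBatch(
            (0, 1), labels, np.array([[0.7, 0.2, 0.1], [0.2, 0.2, 0.6]]), ("a1", "b1")
        )
        path = tmp_path / "mc.csv"
        write_multiclass_csv(batch, path)
        back = read_multiclass_csv(path, labels)
        np.testing.assert_allclose(back.scores, batch.scores)
        assert back.true_labels == batch.true_labels
        with pytest.raises(FormatError):
            read_multiclass_csv(path, ("b1", "a1", "a2"))  # no silent reorder

    def test_multilabel_roundtrip(self, toy_type2, tmp_path):
        labels = toy_type2.labels
        batch = MultilabelBatch(
            (0,), labels, np.array([[0.9, 0.8, 0.1, 0.1, 0.2]]),
            np.array([[1, 1, 0, 0, 0]]),
        )
        write_multilabel_csv(batch, tmp_path / "s.csv", tmp_path / "t.csv")
        back = read_multilabel_csv(tmp_path / "s.csv", tmp_path / "t.csv", labels)
        np.testing.assert_allclose(back.scores, batch.scores)
        np.testing.assert_array_equal(back.true_vectors, batch.true_vectors)
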