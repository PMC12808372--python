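"""Metric formulas, aggregate statistics and LOSO protocol contracts."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score

from mieeg.baselines import BandpowerLDAPredictor
from mieeg.errors import ConfigurationError
from mieeg.evaluation import (
    ConfusionMatrix,
    LOSOReport,
    SubjectResult,
    accuracy,
    cohen_kappa,
    confusion_from_predictions,
    efficiency_index,
    improvement_deltas,
    improvement_from_means,
    loso_evaluate,
    macro_f1,
    paired_ttest,
    transfer_evaluate,
    variance_reduction,
)
from mieeg.preprocessing import SplitScheme


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]))
        assert accuracy(cm) == 100.0
        assert macro_f1(cm) == 1.0
        assert cohen_kappa(cm) == 1.0

    def test_worked_2x2_example(self):
        """counts [[40,10],[5,45]]: accuracy 85%, macro-F1 0.8496, kappa 0.70."""
        cm = ConfusionMatrix([[40, 10], [5, 45]])
        assert accuracy(cm) == 85.0
        f1_0 = 2 * 40 / (2 * 40 + 10 + 5)   # 0.8421
        f1_1 = 2 * 45 / (2 * 45 + 10 + 5)   # 0.8571
        np.testing.assert_allclose(macro_f1(cm), (f1_0 + f1_1) / 2, atol=1e-4)
        np.testing.assert_allclose(macro_f1(cm), 0.8496, atol=1e-4)
        np.testing.assert_allclose(cohen_kappa(cm), 0.70, atol=1e-10)

    def test_uniform_counts_give_zero_kappa(self):
        cm = ConfusionMatrix([[25, 25], [25, 25]])
        assert cohen_kappa(cm) == 0.0

    def test_agreement_with_sklearn_on_random_predictions(self, rng):
        y_true = rng.integers(0, 4, size=500)
        y_pred = rng.integers(0, 4, size=500)
        cm = confusion_from_predictions(y_true, y_pred, 4)
        np.testing.assert_allclose(
            cohen_kappa(cm), cohen_kappa_score(y_true, y_pred), atol=1e-12
        )
        np.testing.assert_allclose(
            macro_f1(cm), f1_score(y_true, y_pred, average="macro"), atol=1e-12
        )
        np.testing.assert_allclose(
            accuracy(cm), (y_true == y_pred).mean() * 100, atol=1e-12
        )

    def test_metric_coherence_from_shared_matrix(self, rng):
        """accuracy 100% <=> F1 1 <=> kappa 1 on any shared matrix."""
        y = rng.integers(0, 3, size=60)
        cm = confusion_from_predictions(y, y, 3)
        assert accuracy(cm) == 100.0 and macro_f1(cm) == 1.0 and cohen_kappa(cm) == 1.0

    def test_kappa_of_permuted_labels_near_zero(self, rng):
        """kappa under label permutation is 0 in expectation (200 draws)."""
        y_true = rng.integers(0, 2, size=200)
        kappas = []
        for _ in range(200):
            kappas.append(cohen_kappa(
                confusion_from_predictions(y_true, rng.permutation(y_true), 2)
            ))
        assert abs(np.mean(kappas)) < 0.02

    def test_empty_matrix_errors(self):
        with pytest.raises(ConfigurationError):
            accuracy(ConfusionMatrix(np.zeros((2, 2), dtype=int)))


class TestEfficiencyIndex:
    def test_baseline_iv2a_row(self):
        assert efficiency_index(0.7222, 1.35) == 0.535

    def test_tl_rows(self):
        assert efficiency_index(0.7944, 1.38) == 0.576
        assert efficiency_index(0.8385, 1.38) == 0.608

    def test_zero_accuracy(self):
        assert efficiency_index(0.0, 2.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            efficiency_index(0.5, 0.0)
        with pytest.raises(ConfigurationError):
            efficiency_index(1.5, 1.0)


class TestVarianceReduction:
    def test_reported_ratios(self):
        assert variance_reduction(20.49, 11.09) == 45.9
        assert variance_reduction(17.17, 10.30) == 40.0

    def test_no_change_is_zero(self):
        assert variance_reduction(12.0, 12.0) == 0.0

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ConfigurationError):
            variance_reduction(0.0, 1.0)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, df, p = paired_ttest([70, 75, 80], [70, 75, 80])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_closed_form_differences(self):
        """diffs (1..5): t = mean/(sd/sqrt(5)) = 4.2426, df 4, p ~ 0.0132."""
        a = np.array([71, 72, 73, 74, 75], dtype=float)
        b = a - np.array([1, 2, 3, 4, 5], dtype=float)
        t, df, p = paired_ttest(a, b)
        np.testing.assert_allclose(t, 3 / (np.std([1, 2, 3, 4, 5], ddof=1) / np.sqrt(5)),
                                   rtol=1e-6)
        np.testing.assert_allclose(t, 4.2426, atol=1e-4)
        assert df == 4
        np.testing.assert_allclose(p, 0.0132, atol=5e-4)

    def test_argument_swap_negates_t_preserves_p(self, rng):
        a = rng.normal(70, 5, size=9)
        b = rng.normal(75, 5, size=9)
        t1, _, p1 = paired_ttest(a, b)
        t2, _, p2 = paired_ttest(b, a)
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)

    def test_zero_variance_nonzero_mean_warns(self):
        with pytest.warns(UserWarning):
            t, df, p = paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert p == 0.0


class TestImprovementDeltas:
    def test_reported_iv2a_gain(self):
        d = improvement_from_means(72.22, 79.44)
        np.testing.assert_allclose(d.absolute_points, 7.22, atol=1e-10)
        np.testing.assert_allclose(d.relative_percent, 10.0, atol=0.05)

    def test_reported_iv2b_gain(self):
        d = improvement_from_means(75.10, 83.85, 17.17, 10.30)
        np.testing.assert_allclose(d.absolute_points, 8.75, atol=1e-10)
        np.testing.assert_allclose(d.relative_percent, 11.6, atol=0.1)
        assert d.delta_sigma == 40.0

    def test_equal_means_zero_deltas(self):
        d = improvement_from_means(80.0, 80.0)
        assert d.absolute_points == 0.0 and d.relative_percent == 0.0


def _report(accs):
    return LOSOReport(per_subject=[
        SubjectResult(i, a, a / 100, a / 100,
                      ConfusionMatrix(np.diag([1, 1])))
        for i, a in enumerate(accs)
    ])


def test_report_aggregates_consistent_with_per_subject():
    rep = _report([60.0, 70.0, 80.0])
    assert rep.mean_accuracy == 70.0
    np.testing.assert_allclose(rep.sd_accuracy, np.std([60, 70, 80], ddof=1))
    d = improvement_deltas(_report([60.0, 70.0]), _report([66.0, 77.0]))
    np.testing.assert_allclose(d.absolute_points, 6.5)


class _ConstantPredictor:
    """Always predicts class 0 (analytic chance level on balanced data)."""

    def fit(self, train_set, val_set, plan):
        return self

    def predict(self, ds):
        return np.zeros(ds.n_trials, dtype=int)


class _MemorizingPredictor:
    """Records what it saw in training; used by the leakage test."""

    seen: list = []

    def fit(self, train_set, val_set, plan):
        _MemorizingPredictor.seen.append(
            (train_set.subjects.copy(), val_set.subjects.copy())
        )
        return self

    def predict(self, ds):
        return np.zeros(ds.n_trials, dtype=int)


class TestLOSOProtocol:
    def test_each_subject_tested_exactly_once(self, small_dataset):
        report = loso_evaluate(_ConstantPredictor, small_dataset, None)
        subjects = sorted(r.subject for r in report.per_subject)
        assert subjects == sorted(small_dataset.subject_ids.tolist())

    def test_constant_classifier_scores_chance_with_zero_sd(self, small_dataset):
        report = loso_evaluate(_ConstantPredictor, small_dataset, None)
        for r in report.per_subject:
            assert r.accuracy == 50.0
        assert report.sd_accuracy == 0.0

    def test_held_out_subject_never_trains(self, small_dataset):
        _MemorizingPredictor.seen = []
        loso_evaluate(_MemorizingPredictor, small_dataset, None)
        held_order = small_dataset.subject_ids
        for held, (train_subj, val_subj) in zip(held_order, _MemorizingPredictor.seen):
            assert held not in train_subj
            assert held not in val_subj

    def test_perturbing_held_out_data_changes_only_that_fold(self, separable_dataset):
        base = loso_evaluate(BandpowerLDAPredictor, separable_dataset, None)
        tampered = separable_dataset.copy()
        victim = tampered.subject_ids[0]
        mask = tampered.subjects == victim
        rng = np.random.default_rng(0)
        tampered.data[mask] = rng.normal(size=tampered.data[mask].shape) * 40
        after = loso_evaluate(BandpowerLDAPredictor, tampered, None)
        for rb, ra in zip(base.per_subject[1:], after.per_subject[1:]):
            assert rb.accuracy == ra.accuracy

    def test_single_class_subject_errors(self, small_dataset):
        broken = small_dataset.copy()
        broken.labels[broken.subjects == 0] = 0
        with pytest.raises(ConfigurationError, match="0"):
            loso_evaluate(_ConstantPredictor, broken, None)

    def test_separable_data_bandpower_lda_beats_75(self, separable_dataset):
        report = loso_evaluate(BandpowerLDAPredictor, separable_dataset, None)
        assert report.mean_accuracy > 75.0


class TestTransferProtocol:
    def test_per_subject_splits_and_report_shape(self, small_dataset):
        calls = []

        def factory(subject, others):
            calls.append((subject, set(others.subjects.tolist())))
            return _ConstantPredictor()

        report = transfer_evaluate(
            small_dataset, SplitScheme.from_name("IV-2b"), factory, None
        )
        assert len(report.per_subject) == len(small_dataset.subject_ids)
        for subject, others in calls:
            assert subject not in others  # pool excludes the target subject


def test_report_json_roundtrip(tmp_path, small_dataset):
    report = loso_evaluate(_ConstantPredictor, small_dataset, None)
    path = report.save(tmp_path / "r.json")
    import json

    rebuilt = LOSOReport.from_dict(json.loads(path.read_text()))
    assert rebuilt.mean_accuracy == report.mean_accuracy
    assert rebuilt.per_subject[0].confusion.counts.tolist() == \
        report.per_subject[0].confusion.counts.tolist()
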