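"""Subject-wise evaluation and the study's metrics and statistics.

Two evaluation protocols coexist:

* :func:`loso_evaluate` - strict leave-one-subject-out: the held-out
  subject's trials appear in no training or validation batch of its fold;
  a built-in leakage assertion enforces this.
* :func:`transfer_evaluate` - the per-subject transfer protocol: the model
  is pretrained on the pooled other subjects, then fine-tuned on the held-out
  subject's own training split and tested on that subject's test split
  (the from-scratch arm simply skips pretraining).

Metrics are computed from confusion matrices so that accuracy, macro-F1 and
Cohen's kappa are mutually coherent by construction. Aggregate statistics:

* efficiency index  eta = A / P  (mean accuracy as a fraction per million
  trainable parameters),
* variance-reduction ratio  delta_sigma = (sigma_baseline - sigma_TL) /
  sigma_baseline * 100%,
* absolute / relative improvement deltas between two subject-wise reports,
* paired two-tailed t-tests across subject-level accuracies.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .data import EEGTrialSet
from .errors import ConfigurationError
from .preprocessing import (
    SplitScheme,
    apply_standardizer,
    fit_standardizer,
    stratified_holdout,
    stratified_split,
)

__all__ = [
    "ConfusionMatrix",
    "SubjectResult",
    "LOSOReport",
    "EfficiencyRecord",
    "ImprovementDeltas",
    "accuracy",
    "macro_f1",
    "cohen_kappa",
    "confusion_from_predictions",
    "efficiency_index",
    "variance_reduction",
    "paired_ttest",
    "improvement_deltas",
    "improvement_from_means",
    "loso_evaluate",
    "transfer_evaluate",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrices and per-matrix metrics
# ---------------------------------------------------------------------------
@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ConfigurationError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ConfigurationError("confusion matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return ConfusionMatrix(counts)


def _check_nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ConfigurationError("empty confusion matrix")


def accuracy(cm: ConfusionMatrix) -> float:
    """Correct fraction in percent: trace / total * 100."""
    _check_nonempty(cm)
    return float(np.trace(cm.counts) / cm.total * 100.0)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1 (a class with no predictions and no
    instances contributes F1 = 0)."""
    _check_nonempty(cm)
    c = cm.counts.astype(float)
    tp = np.diag(c)
    pred = c.sum(axis=0)
    true = c.sum(axis=1)
    denom = pred + true
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return float(f1.mean())


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e)."""
    _check_nonempty(cm)
    c = cm.counts.astype(float)
    n = c.sum()
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if p_e == 1.0:
        return 0.0  # degenerate single-cell agreement
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# aggregate statistics
# ---------------------------------------------------------------------------
@dataclass
class EfficiencyRecord:
    A: float  # mean accuracy as a fraction
    P: float  # trainable parameters in millions
    eta: float


def efficiency_index(A: float, P: float) -> float:
    """Accuracy fraction per million parameters, reported to 3 decimals."""
    if P <= 0:
        raise ConfigurationError("invalid value for field 'P': must be > 0")
    if not 0.0 <= A <= 1.0:
        raise ConfigurationError(
            "invalid value for field 'A': accuracy must be a fraction in [0, 1]"
        )
    return round(A / P, 3)


def variance_reduction(sd_baseline: float, sd_tl: float) -> float:
    """Percent reduction of across-subject SD, reported to 1 decimal."""
    if sd_baseline <= 0:
        raise ConfigurationError(
            "invalid value for field 'sd_baseline': must be > 0"
        )
    return round((sd_baseline - sd_tl) / sd_baseline * 100.0, 1)


def paired_ttest(acc_a, acc_b) -> tuple[float, int, float]:
    """Paired two-tailed t-test across subject-level accuracies."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ConfigurationError("paired vectors must have equal length >= 2")
    diff = a - b
    df = len(a) - 1
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, df, 1.0
        warnings.warn(
            "zero-variance nonzero-mean differences: p reported as 0",
            stacklevel=2,
        )
        return float(np.inf * np.sign(diff.mean())), df, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# subject-wise reports
# ---------------------------------------------------------------------------
@dataclass
class SubjectResult:
    subject: int
    accuracy: float  # percent
    macro_f1: float
    kappa: float
    confusion: ConfusionMatrix


@dataclass
class LOSOReport:
    """Per-subject and aggregate metrics for one subject-wise evaluation."""

    per_subject: list[SubjectResult]
    mean_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)
    mean_f1: float = field(init=False)
    mean_kappa: float = field(init=False)

    def __post_init__(self) -> None:
        accs = np.array([r.accuracy for r in self.per_subject])
        self.mean_accuracy = float(accs.mean())
        self.sd_accuracy = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
        self.mean_f1 = float(np.mean([r.macro_f1 for r in self.per_subject]))
        self.mean_kappa = float(np.mean([r.kappa for r in self.per_subject]))

    @property
    def subject_accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.per_subject])

    def to_dict(self) -> dict:
        return {
            "per_subject": [
                {
                    "subject": r.subject,
                    "accuracy": r.accuracy,
                    "macro_f1": r.macro_f1,
                    "kappa": r.kappa,
                    "confusion": r.confusion.counts.tolist(),
                }
                for r in self.per_subject
            ],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_f1": self.mean_f1,
            "mean_kappa": self.mean_kappa,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "LOSOReport":
        return cls(
            per_subject=[
                SubjectResult(
                    subject=r["subject"],
                    accuracy=r["accuracy"],
                    macro_f1=r["macro_f1"],
                    kappa=r["kappa"],
                    confusion=ConfusionMatrix(np.array(r["confusion"])),
                )
                for r in d["per_subject"]
            ]
        )


@dataclass
class ImprovementDeltas:
    """Gains of a transfer-learning report over a baseline report."""

    absolute_points: float
    relative_percent: float
    delta_sigma: float | None


def improvement_from_means(
    mean_base: float,
    mean_tl: float,
    sd_base: float | None = None,
    sd_tl: float | None = None,
) -> ImprovementDeltas:
    absolute = mean_tl - mean_base
    relative = absolute / mean_base * 100.0
    ds = (
        variance_reduction(sd_base, sd_tl)
        if sd_base is not None and sd_tl is not None and sd_base > 0
        else None  # undefined when the baseline shows no subject spread
    )
    return ImprovementDeltas(absolute, relative, ds)


def improvement_deltas(base: LOSOReport, tl: LOSOReport) -> ImprovementDeltas:
    if len(base.per_subject) != len(tl.per_subject):
        raise ConfigurationError("reports cover different subject counts")
    return improvement_from_means(
        base.mean_accuracy, tl.mean_accuracy, base.sd_accuracy, tl.sd_accuracy
    )


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------
def _subject_metrics(
    subject: int, y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> SubjectResult:
    cm = confusion_from_predictions(y_true, y_pred, n_classes)
    return SubjectResult(
        subject=int(subject),
        accuracy=accuracy(cm),
        macro_f1=macro_f1(cm),
        kappa=cohen_kappa(cm),
        confusion=cm,
    )


def _check_subject_classes(ds: EEGTrialSet) -> None:
    for s in ds.subject_ids:
        if len(np.unique(ds.labels[ds.subjects == s])) < 2:
            raise ConfigurationError(f"subject {int(s)} has a single class")


def loso_evaluate(
    model_factory,
    ds: EEGTrialSet,
    plan,
    val_fraction: float = 0.2,
    standardize: bool = True,
    seed: int = 0,
) -> LOSOReport:
    """Strict leave-one-subject-out evaluation.

    ``model_factory()`` must return an object with
    ``fit(train_set, val_set, plan)`` and ``predict(ds) -> labels``. Per
    fold, a stratified ``val_fraction`` of the training subjects' trials is
    carved out for validation; the held-out subject contributes only test
    trials (asserted). Standardization statistics are fitted on the training
    portion only.
    """
    subjects = ds.subject_ids
    if len(subjects) < 2:
        raise ConfigurationError("LOSO needs at least 2 subjects")
    _check_subject_classes(ds)
    results = []
    for fold, held in enumerate(subjects):
        test_idx = np.flatnonzero(ds.subjects == held)
        rest_idx = np.flatnonzero(ds.subjects != held)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(fold,)))
        kept, held_out = stratified_holdout(
            ds.labels[rest_idx], val_fraction, rng
        )
        train_idx = rest_idx[kept]
        val_idx = rest_idx[held_out]
        assert not np.intersect1d(test_idx, np.concatenate([train_idx, val_idx])).size, (
            "leakage: held-out subject present in training data"
        )
        train_set = ds.select(train_idx)
        val_set = ds.select(val_idx)
        test_set = ds.select(test_idx)
        if standardize:
            scaler = fit_standardizer(train_set)
            train_set = apply_standardizer(scaler, train_set)
            val_set = apply_standardizer(scaler, val_set)
            test_set = apply_standardizer(scaler, test_set)
        predictor = model_factory()
        predictor.fit(train_set, val_set, plan)
        y_pred = predictor.predict(test_set)
        results.append(
            _subject_metrics(held, test_set.labels, y_pred, ds.n_classes)
        )
    return LOSOReport(per_subject=results)


def transfer_evaluate(
    ds: EEGTrialSet,
    scheme: SplitScheme,
    predictor_for_subject,
    plan,
    standardize: bool = True,
) -> LOSOReport:
    """Per-subject transfer protocol.

    For each subject: split that subject's trials into train/val/test per
    ``scheme``; ``predictor_for_subject(subject, others)`` builds the
    predictor (typically pretrained on the pooled other subjects); the
    predictor is then fitted on the subject's training split and scored on
    its test split. Standardization is fitted per subject on the training
    split only.
    """
    _check_subject_classes(ds)
    plan_split = stratified_split(ds, scheme)
    results = []
    for subject in ds.subject_ids:
        split = plan_split.per_subject[int(subject)]
        others = ds.select(np.flatnonzero(ds.subjects != subject))
        train_set = ds.select(split.train_idx)
        val_set = ds.select(split.val_idx)
        test_set = ds.select(split.test_idx)
        if standardize:
            scaler = fit_standardizer(train_set)
            train_set = apply_standardizer(scaler, train_set)
            val_set = apply_standardizer(scaler, val_set)
            test_set = apply_standardizer(scaler, test_set)
        predictor = predictor_for_subject(int(subject), others)
        predictor.fit(train_set, val_set, plan)
        y_pred = predictor.predict(test_set)
        results.append(
            _subject_metrics(subject, test_set.labels, y_pred, ds.n_classes)
        )
    return LOSOReport(per_subject=results)
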