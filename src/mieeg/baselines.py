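"""Shallow comparators: CSP+LDA, flattened-trial RandomForest, bandpower+LDA.

The Common Spatial Patterns (CSP) implementation solves the generalized
eigenproblem of the trace-normalized class-mean covariances, yielding spatial
filters that simultaneously diagonalize both class covariances. In the
whitened convention the paired eigenvalues under the two classes sum to one;
``n_components / 2`` filters are taken from each spectral extreme and
per-trial log-variance of the projected signals forms the feature vector.

The RandomForest baseline flattens each trial into a channels x samples
feature vector with one subject-specific classifier (200 trees, depth 20).
The bandpower+LDA probe (log bandpower in the mu and beta bands per channel)
exists to validate that synthetic data carries the class structure a
sensorimotor-rhythm decoder expects; it is used in tests.

All three plug into the LOSO engine via the same fit/predict contract as the
deep models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

from .data import EEGTrialSet
from .errors import ConfigurationError

__all__ = [
    "CSPModel",
    "RFConfig",
    "csp_fit",
    "csp_transform",
    "CSPLDAPredictor",
    "random_forest_baseline",
    "RandomForestPredictor",
    "bandpower_features",
    "bandpower_lda_probe",
    "BandpowerLDAPredictor",
    "DEFAULT_BANDS",
]

log = logging.getLogger(__name__)

DEFAULT_BANDS = ((8.0, 12.0), (13.0, 30.0))
_RIDGE_EPS = 1e-10


@dataclass
class CSPModel:
    filters: np.ndarray  # (n_components, n_channels)
    n_components: int
    class_covariances: tuple[np.ndarray, np.ndarray]
    eigenvalues: np.ndarray  # whitened eigenvalues of class 0, descending filters


@dataclass(frozen=True)
class RFConfig:
    n_estimators: int = 200
    max_depth: int = 20
    seed: int = 0
    max_feature_cells: int = 200_000_000

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ConfigurationError(
                "invalid value for field 'n_estimators'/'max_depth'"
            )


def _class_covariance(trials: np.ndarray) -> np.ndarray:
    """Mean of trace-normalized per-trial covariances."""
    covs = []
    for x in trials:
        c = x @ x.T
        covs.append(c / np.trace(c))
    return np.mean(covs, axis=0)


def csp_fit(
    trials: np.ndarray, labels: np.ndarray, n_components: int = 4
) -> CSPModel:
    """Fit CSP filters for a binary problem on band-passed trials.

    ``trials``: (n_trials, n_channels, n_samples); exactly two classes.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ConfigurationError(
            f"CSP requires exactly 2 classes, got {len(classes)}"
        )
    if n_components % 2 or n_components < 2:
        raise ConfigurationError("invalid value for field 'n_components'")
    c0 = _class_covariance(trials[labels == classes[0]])
    c1 = _class_covariance(trials[labels == classes[1]])
    composite = c0 + c1
    # ridge-regularize a rank-deficient composite covariance
    if np.linalg.cond(composite) > 1e12:
        eps = _RIDGE_EPS * np.trace(composite)
        log.info("rank-deficient covariance: ridge epsilon %g applied", eps)
        composite = composite + eps * np.eye(len(composite))
    evals, evecs = linalg.eigh(c0, composite)
    order = np.argsort(evals)[::-1]  # descending: class-0-dominant first
    evals, evecs = evals[order], evecs[:, order]
    half = n_components // 2
    pick = np.concatenate([np.arange(half), np.arange(len(evals) - half, len(evals))])
    filters = evecs[:, pick].T
    return CSPModel(
        filters=filters,
        n_components=n_components,
        class_covariances=(c0, c1),
        eigenvalues=evals[pick],
    )


def csp_transform(model: CSPModel, trials: np.ndarray) -> np.ndarray:
    """Log-variance of the CSP-projected signals: (n_trials, n_components)."""
    projected = np.einsum("fc,ncs->nfs", model.filters, trials)
    return np.log(projected.var(axis=2, ddof=0) + 1e-30)


class CSPLDAPredictor:
    """CSP features + linear discriminant, via the LOSO fit/predict contract."""

    def __init__(self, n_components: int = 4):
        self.n_components = n_components
        self.csp: CSPModel | None = None
        self.lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)

    def fit(self, train_set: EEGTrialSet, val_set=None, plan=None):
        self.csp = csp_fit(train_set.data, train_set.labels, self.n_components)
        feats = csp_transform(self.csp, train_set.data)
        self.lda.fit(feats, train_set.labels)
        return self

    def predict(self, ds: EEGTrialSet) -> np.ndarray:
        return self.lda.predict(csp_transform(self.csp, ds.data))


# ---------------------------------------------------------------------------
# RandomForest baseline
# ---------------------------------------------------------------------------
def random_forest_baseline(
    train: EEGTrialSet, test: EEGTrialSet, cfg: RFConfig = RFConfig()
) -> dict[int, float]:
    """Subject-specific RandomForests on flattened trials.

    One classifier per subject present in both sets; returns per-subject test
    accuracy in percent.
    """
    n_cells = train.n_trials * train.n_channels * train.n_samples
    if n_cells > cfg.max_feature_cells:
        raise ConfigurationError(
            f"flattened feature matrix of {n_cells} cells exceeds the cap "
            f"({cfg.max_feature_cells}); reduce trials or samples"
        )
    accs: dict[int, float] = {}
    for subject in np.intersect1d(train.subject_ids, test.subject_ids):
        tr = train.for_subject(subject)
        te = test.for_subject(subject)
        clf = RandomForestClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
            random_state=cfg.seed,
        )
        clf.fit(tr.data.reshape(tr.n_trials, -1), tr.labels)
        pred = clf.predict(te.data.reshape(te.n_trials, -1))
        accs[int(subject)] = float((pred == te.labels).mean() * 100.0)
    return accs


class RandomForestPredictor:
    """Flattened-trial RandomForest via the LOSO fit/predict contract."""

    def __init__(self, cfg: RFConfig = RFConfig()):
        self.cfg = cfg
        self.clf: RandomForestClassifier | None = None

    def fit(self, train_set: EEGTrialSet, val_set=None, plan=None):
        self.clf = RandomForestClassifier(
            n_estimators=self.cfg.n_estimators,
            max_depth=self.cfg.max_depth,
            random_state=self.cfg.seed,
        )
        self.clf.fit(
            train_set.data.reshape(train_set.n_trials, -1), train_set.labels
        )
        return self

    def predict(self, ds: EEGTrialSet) -> np.ndarray:
        return self.clf.predict(ds.data.reshape(ds.n_trials, -1))


# ---------------------------------------------------------------------------
# bandpower + LDA probe
# ---------------------------------------------------------------------------
def bandpower_features(
    ds: EEGTrialSet, bands=DEFAULT_BANDS
) -> np.ndarray:
    """Per-trial log bandpower per channel per band via Welch periodograms."""
    nperseg = min(ds.n_samples, int(ds.fs))
    freqs, psd = signal.welch(ds.data, fs=ds.fs, nperseg=nperseg, axis=-1)
    feats = []
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs <= hi)
        power = np.trapezoid(psd[..., mask], freqs[mask], axis=-1)
        feats.append(np.log(power + 1e-30))
    return np.concatenate(feats, axis=1)


def bandpower_lda_probe(
    train: EEGTrialSet, test: EEGTrialSet, bands=DEFAULT_BANDS
) -> float:
    """Test accuracy (fraction) of an LDA on log-bandpower features."""
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
    lda.fit(bandpower_features(train, bands), train.labels)
    pred = lda.predict(bandpower_features(test, bands))
    return float((pred == test.labels).mean())


class BandpowerLDAPredictor:
    """Bandpower + LDA via the LOSO fit/predict contract."""

    def __init__(self, bands=DEFAULT_BANDS):
        self.bands = bands
        self.lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)

    def fit(self, train_set: EEGTrialSet, val_set=None, plan=None):
        self.lda.fit(bandpower_features(train_set, self.bands), train_set.labels)
        return self

    def predict(self, ds: EEGTrialSet) -> np.ndarray:
        return self.lda.predict(bandpower_features(ds, self.bands))
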