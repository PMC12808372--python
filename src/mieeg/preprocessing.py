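"""Preprocessing pipeline: CAR, epoching, EOG screening, filtering, splits.

The fixed pipeline order is: common-average re-reference -> epoching ->
EOG-threshold trial rejection -> zero-phase Butterworth band-pass ->
stratified splitting -> per-subject standardization fitted on training data
only. EOG rejection deliberately precedes filtering so that artifact
screening sees raw amplitudes, and standardization parameters never touch
validation or test trials (no leakage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import EEGTrialSet
from .errors import ConfigurationError, GeometryError

__all__ = [
    "FilterSpec",
    "SplitScheme",
    "SplitPlan",
    "SubjectSplit",
    "Standardizer",
    "car_reference",
    "epoch",
    "reject_eog_trials",
    "bandpass",
    "fit_standardizer",
    "apply_standardizer",
    "stratified_split",
    "stratified_holdout",
    "PIPELINE_ORDER",
]

log = logging.getLogger(__name__)

PIPELINE_ORDER = (
    "car_reference",
    "epoch",
    "reject_eog_trials",
    "bandpass",
    "stratified_split",
    "standardize",
)


# ---------------------------------------------------------------------------
# filter
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter parameters: 8-30 Hz, 4th order, zero phase."""

    low_hz: float = 8.0
    high_hz: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError("invalid value for field 'low_hz'/'high_hz'")
        if self.high_hz >= fs / 2:
            raise ConfigurationError(
                f"invalid value for field 'high_hz': {self.high_hz} Hz is at or "
                f"above Nyquist ({fs / 2} Hz)"
            )
        if self.order < 1:
            raise ConfigurationError("invalid value for field 'order'")


def bandpass(ds: EEGTrialSet, spec: FilterSpec = FilterSpec()) -> EEGTrialSet:
    """Zero-phase Butterworth band-pass of every trial.

    Forward-backward filtering gives a net zero phase response with squared
    magnitude |H|^2. Edge transients are handled with Gustafsson's
    initial-condition method, which makes the operation exactly symmetric
    under time reversal (mirror padding leaves residual edge asymmetry that
    would violate the zero-phase reversal identity on short epochs).
    """
    spec.validate(ds.fs)
    b, a = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=ds.fs
    )
    min_len = 6 * (spec.order + 1)
    if ds.n_samples <= min_len:
        raise GeometryError(
            f"trials of {ds.n_samples} samples are too short to filter "
            f"(need > {min_len})"
        )
    if spec.zero_phase:
        out = signal.filtfilt(b, a, ds.data, axis=-1, method="gust")
    else:
        out = signal.lfilter(b, a, ds.data, axis=-1)
    return ds.replace_data(out)


# ---------------------------------------------------------------------------
# referencing and epoching
# ---------------------------------------------------------------------------
def car_reference(ds: EEGTrialSet) -> EEGTrialSet:
    """Common-average re-reference: subtract the cross-channel mean per sample."""
    if ds.n_channels < 2:
        raise GeometryError("common-average reference needs at least 2 channels")
    return ds.replace_data(ds.data - ds.data.mean(axis=1, keepdims=True))


def epoch(
    continuous: np.ndarray,
    cue_samples,
    window: tuple[float, float],
    fs: float,
    labels=None,
    subject: int = 0,
    channel_names: list[str] | None = None,
) -> tuple[EEGTrialSet, list[int]]:
    """Slice cue-locked epochs out of a continuous ``(channels, samples)`` record.

    Each epoch covers the half-open sample interval starting at
    ``cue + round(window[0] * fs)`` with length ``round((end - start) * fs)``.
    Cues whose window falls outside the recording are skipped with a log
    message; their positions are returned so callers can audit the loss.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise GeometryError("continuous signal must be (channels, samples)")
    cue_samples = [int(c) for c in np.atleast_1d(cue_samples)]
    n_len = int(round((window[1] - window[0]) * fs))
    start_off = int(round(window[0] * fs))
    n_rec = continuous.shape[1]

    epochs, kept, skipped = [], [], []
    for i, cue in enumerate(cue_samples):
        a = cue + start_off
        if a < 0 or a + n_len > n_rec:
            log.warning(
                "cue %d at sample %d skipped: window [%d, %d) exceeds recording "
                "of %d samples",
                i,
                cue,
                a,
                a + n_len,
                n_rec,
            )
            skipped.append(i)
            continue
        epochs.append(continuous[:, a : a + n_len])
        kept.append(i)

    n_ch = continuous.shape[0]
    data = (
        np.stack(epochs) if epochs else np.empty((0, n_ch, n_len))
    )
    if labels is None:
        lab = np.zeros(len(kept), dtype=np.int64)
    else:
        lab = np.asarray(labels, dtype=np.int64)[kept]
    ds = EEGTrialSet(
        data=data,
        labels=lab,
        subjects=np.full(len(kept), subject, dtype=np.int64),
        channel_names=channel_names or [f"EEG{i:02d}" for i in range(n_ch)],
        fs=fs,
        window=window,
    )
    return ds, skipped


def reject_eog_trials(
    ds: EEGTrialSet, threshold_uv: float = 100.0
) -> tuple[EEGTrialSet, np.ndarray]:
    """Drop trials whose EOG magnitude strictly exceeds ``threshold_uv``.

    A trial peaking at exactly the threshold is retained. Datasets without an
    EOG block pass through unchanged with a warning, since EOG screening is
    impossible rather than wrong for them.
    """
    if ds.eog is None:
        log.warning("no EOG channels present; EOG rejection skipped")
        return ds, np.array([], dtype=np.int64)
    peak = np.abs(ds.eog).max(axis=(1, 2))
    rejected = np.flatnonzero(peak > threshold_uv)
    kept = np.flatnonzero(peak <= threshold_uv)
    return ds.select(kept), rejected


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------
@dataclass
class Standardizer:
    """Per-channel z-scoring fitted on training trials only.

    Statistics pool all trials and samples of the fitted set per channel;
    channels whose spread falls below ``sd_floor`` are clamped (a constant
    channel maps to all zeros).
    """

    mean: np.ndarray
    sd: np.ndarray
    sd_floor: float = 1e-6


def fit_standardizer(train: EEGTrialSet, sd_floor: float = 1e-6) -> Standardizer:
    if train.n_trials == 0:
        raise ConfigurationError("cannot fit a standardizer on an empty train set")
    mean = train.data.mean(axis=(0, 2))
    sd = train.data.std(axis=(0, 2))
    if np.any(sd < sd_floor):
        log.warning(
            "constant channel(s) %s: sd floored at %g",
            np.flatnonzero(sd < sd_floor).tolist(),
            sd_floor,
        )
        sd = np.maximum(sd, sd_floor)
    return Standardizer(mean=mean, sd=sd, sd_floor=sd_floor)


def apply_standardizer(s: Standardizer, ds: EEGTrialSet) -> EEGTrialSet:
    out = (ds.data - s.mean[None, :, None]) / s.sd[None, :, None]
    return ds.replace_data(out)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SplitScheme:
    """Named per-subject splitting proportions.

    ``IV-2a``: 20% test, then 25% of the remainder for validation.
    ``IV-2b``: 15% test, then 18% of the remainder for validation.
    """

    name: str = "IV-2a"
    test_fraction: float = 0.20
    val_fraction_of_remainder: float = 0.25
    stratified: bool = True
    seed: int = 0

    @classmethod
    def from_name(cls, name: str, seed: int = 0) -> "SplitScheme":
        presets = {
            "IV-2a": (0.20, 0.25),
            "IV-2b": (0.15, 0.18),
        }
        if name not in presets:
            raise ConfigurationError(
                f"unknown split scheme '{name}'; choose from {sorted(presets)}"
            )
        test, val = presets[name]
        return cls(name=name, test_fraction=test, val_fraction_of_remainder=val, seed=seed)

    def __post_init__(self) -> None:
        for f_name in ("test_fraction", "val_fraction_of_remainder"):
            v = getattr(self, f_name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"invalid value for field '{f_name}'")


@dataclass
class SubjectSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class SplitPlan:
    """Disjoint, exhaustive per-subject train/val/test index sets."""

    per_subject: dict[int, SubjectSplit] = field(default_factory=dict)

    def _gather(self, part: str) -> np.ndarray:
        chunks = [getattr(s, part) for s in self.per_subject.values()]
        return np.sort(np.concatenate(chunks)) if chunks else np.array([], dtype=np.int64)

    @property
    def train_idx(self) -> np.ndarray:
        return self._gather("train_idx")

    @property
    def val_idx(self) -> np.ndarray:
        return self._gather("val_idx")

    @property
    def test_idx(self) -> np.ndarray:
        return self._gather("test_idx")


def _round_half_even(x: float) -> int:
    return int(round(x))


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total``, proportional to ``targets``."""
    base = np.floor(targets).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        remainders = targets - base
        # deterministic tie-break: larger remainder first, then lower class id
        order = np.lexsort((np.arange(len(targets)), -remainders))
        base[order[:short]] += 1
    elif short < 0:
        order = np.lexsort((np.arange(len(targets)), targets - base))
        for i in order:
            if short == 0:
                break
            if base[i] > 0:
                base[i] -= 1
                short += 1
    return base


def _allocate(labels: np.ndarray, n_take: int, n_classes: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    quota = n_take * counts / counts.sum()
    return _largest_remainder(quota, n_take)


def stratified_split(ds: EEGTrialSet, scheme: SplitScheme) -> SplitPlan:
    """Per-subject stratified train/val/test split.

    Per subject with ``n`` trials, ``round(test_fraction * n)`` go to test and
    ``round(val_fraction_of_remainder * (n - n_test))`` to validation
    (round-half-to-even), apportioned to classes by largest remainder so that
    per-class counts stay within one of exact proportionality. Deterministic
    under ``scheme.seed``.
    """
    plan = SplitPlan()
    for subject in ds.subject_ids:
        s_idx = np.flatnonzero(ds.subjects == subject)
        s_labels = ds.labels[s_idx]
        n_classes = ds.n_classes
        counts = np.bincount(s_labels, minlength=n_classes)
        if np.any(counts[np.unique(s_labels)] < 2):
            raise ConfigurationError(
                f"subject {subject} has a class with fewer than 2 trials"
            )
        n = len(s_idx)
        n_test = _round_half_even(scheme.test_fraction * n)
        n_val = _round_half_even(
            scheme.val_fraction_of_remainder * (n - n_test)
        )
        test_quota = _allocate(s_labels, n_test, n_classes)

        rng = np.random.default_rng(
            np.random.SeedSequence(scheme.seed, spawn_key=(int(subject),))
        )
        test_parts, val_parts, train_parts = [], [], []
        remaining_labels = []
        remaining_pools: dict[int, np.ndarray] = {}
        for k in range(n_classes):
            pool = s_idx[s_labels == k]
            pool = rng.permutation(pool)
            take = int(test_quota[k])
            test_parts.append(pool[:take])
            remaining_pools[k] = pool[take:]
            remaining_labels.extend([k] * len(pool[take:]))
        val_quota = _allocate(
            np.asarray(remaining_labels, dtype=np.int64), n_val, n_classes
        ) if remaining_labels else np.zeros(n_classes, dtype=np.int64)
        for k in range(n_classes):
            pool = remaining_pools[k]
            take = int(val_quota[k])
            val_parts.append(pool[:take])
            train_parts.append(pool[take:])

        split = SubjectSplit(
            train_idx=np.sort(np.concatenate(train_parts)),
            val_idx=np.sort(np.concatenate(val_parts)),
            test_idx=np.sort(np.concatenate(test_parts)),
        )
        present = np.flatnonzero(counts > 0)
        for part_name, part in (
            ("train", split.train_idx),
            ("val", split.val_idx),
            ("test", split.test_idx),
        ):
            part_counts = np.bincount(ds.labels[part], minlength=n_classes)
            missing = [int(k) for k in present if part_counts[k] == 0]
            if missing:
                raise ConfigurationError(
                    f"subject {subject}: class(es) {missing} received no trials "
                    f"in the {part_name} split"
                )
        plan.per_subject[int(subject)] = split
    return plan


def stratified_holdout(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified two-way split of ``range(len(labels))``: (kept, held_out)."""
    labels = np.asarray(labels, dtype=np.int64)
    n_classes = int(labels.max()) + 1
    n_take = _round_half_even(fraction * len(labels))
    quota = _allocate(labels, n_take, n_classes)
    held, kept = [], []
    for k in range(n_classes):
        pool = rng.permutation(np.flatnonzero(labels == k))
        take = int(quota[k])
        held.append(pool[:take])
        kept.append(pool[take:])
    return np.sort(np.concatenate(kept)), np.sort(np.concatenate(held))
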