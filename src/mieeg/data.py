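"""The epoched-trial container exchanged between every pipeline stage.

An :class:`EEGTrialSet` holds epoched multichannel EEG in microvolts, shaped
``(n_trials, n_channels, n_samples)``, together with integer class labels,
integer subject identifiers, channel names, the sampling rate and the epoch
window relative to the cue. Optional electrooculogram (EOG) traces ride along
for artifact screening; they are never model inputs.

Datasets round-trip through a single-file array bundle (NumPy ``.npz``) so
that synthetic corpora, intermediate pipeline products and CLI artifacts all
share one format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import GeometryError

__all__ = ["EEGTrialSet", "save_dataset", "load_dataset"]


@dataclass
class EEGTrialSet:
    """Epoched EEG trials with labels and subject identifiers.

    Parameters
    ----------
    data:
        ``(n_trials, n_channels, n_samples)`` float array, microvolts.
    labels:
        ``(n_trials,)`` integer array with values ``0 .. K-1``.
    subjects:
        ``(n_trials,)`` integer array of subject identifiers.
    channel_names:
        One name per EEG channel.
    fs:
        Sampling rate in Hz.
    window:
        ``(start, end)`` of the epoch in seconds relative to the cue.
    eog:
        Optional ``(n_trials, n_eog, n_samples)`` EOG traces, microvolts.
    """

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    channel_names: list[str]
    fs: float
    window: tuple[float, float] = (-0.5, 4.0)
    eog: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=np.int64)
        if self.eog is not None:
            self.eog = np.asarray(self.eog, dtype=np.float64)
        self.window = (float(self.window[0]), float(self.window[1]))
        self.channel_names = list(self.channel_names)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise GeometryError("data must be (n_trials, n_channels, n_samples)")
        n = self.data.shape[0]
        if self.labels.shape != (n,) or self.subjects.shape != (n,):
            raise GeometryError(
                "data, labels and subjects must share the first dimension"
            )
        if n and self.labels.min() < 0:
            raise GeometryError("labels must be non-negative integers")
        if len(self.channel_names) != self.data.shape[1]:
            raise GeometryError("channel_names length must equal n_channels")
        if self.fs <= 0:
            raise GeometryError("fs must be positive")
        if self.window[0] >= self.window[1]:
            raise GeometryError("window start must precede window end")
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != expected:
            raise GeometryError(
                f"n_samples={self.data.shape[2]} inconsistent with window/fs "
                f"(expected {expected})"
            )
        if not np.isfinite(self.data).all():
            raise GeometryError("data contains non-finite values")
        if self.eog is not None:
            if self.eog.ndim != 3 or self.eog.shape[0] != n:
                raise GeometryError("eog must be (n_trials, n_eog, n_samples)")
            if not np.isfinite(self.eog).all():
                raise GeometryError("eog contains non-finite values")

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_trials else 0

    @property
    def subject_ids(self) -> np.ndarray:
        return np.unique(self.subjects)

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the cue."""
        start = int(round(self.window[0] * self.fs))
        return (start + np.arange(self.n_samples)) / self.fs

    def select(self, idx) -> "EEGTrialSet":
        """Return a copy restricted to the given trial indices."""
        idx = np.asarray(idx, dtype=np.int64)
        return EEGTrialSet(
            data=self.data[idx].copy(),
            labels=self.labels[idx].copy(),
            subjects=self.subjects[idx].copy(),
            channel_names=list(self.channel_names),
            fs=self.fs,
            window=self.window,
            eog=None if self.eog is None else self.eog[idx].copy(),
            meta=dict(self.meta),
        )

    def copy(self) -> "EEGTrialSet":
        return self.select(np.arange(self.n_trials))

    def replace_data(self, data: np.ndarray) -> "EEGTrialSet":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def for_subject(self, subject: int) -> "EEGTrialSet":
        return self.select(np.flatnonzero(self.subjects == subject))

    def equals(self, other: "EEGTrialSet") -> bool:
        """Bit-identical comparison (used by determinism contracts)."""
        same = (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subjects, other.subjects)
            and self.channel_names == other.channel_names
            and self.fs == other.fs
            and self.window == other.window
        )
        if not same:
            return False
        if (self.eog is None) != (other.eog is None):
            return False
        return self.eog is None or np.array_equal(self.eog, other.eog)


def save_dataset(ds: EEGTrialSet, path: str | Path) -> Path:
    """Write a dataset as a compressed single-file array bundle."""
    path = Path(path)
    header = {
        "channel_names": ds.channel_names,
        "fs": ds.fs,
        "window": list(ds.window),
        "meta": ds.meta,
    }
    arrays = {
        "data": ds.data,
        "labels": ds.labels,
        "subjects": ds.subjects,
        "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    }
    if ds.eog is not None:
        arrays["eog"] = ds.eog
    np.savez_compressed(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_dataset(path: str | Path) -> EEGTrialSet:
    """Read a dataset bundle written by :func:`save_dataset`."""
    with np.load(path) as bundle:
        header = json.loads(bytes(bundle["header"]).decode())
        return EEGTrialSet(
            data=bundle["data"],
            labels=bundle["labels"],
            subjects=bundle["subjects"],
            channel_names=header["channel_names"],
            fs=header["fs"],
            window=tuple(header["window"]),
            eog=bundle["eog"] if "eog" in bundle.files else None,
            meta=header.get("meta", {}),
        )
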