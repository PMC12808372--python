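"""Synthetic motor-imagery EEG with ERD/ERS structure.

The generator emulates the statistical features a sensorimotor-rhythm decoder
relies on, so that every downstream stage (filtering, splitting, training,
LOSO evaluation) can be exercised without downloading real recordings:

* a 1/f^alpha broadband background per channel,
* band-limited mu (8-12 Hz) and beta (13-30 Hz) rhythms built from
  band-passed white noise (not sinusoids, so class information lives in
  bandpower rather than phase),
* event-related desynchronization: in the channel assigned to a trial's
  class, the rhythm amplitude is attenuated by ``(1 - erd_depth)`` during the
  post-cue interval (t >= 0); the pre-cue segment stays at baseline,
* a per-subject multiplicative log-normal gain modelling inter-subject
  amplitude variability,
* optional large slow EOG deflections (half-sine, 0.5 s) on a configurable
  fraction of trials, mirroring ocular artifacts that threshold-based
  screening is meant to catch.

Class-to-channel lateralization is round-robin: class ``k`` modulates channel
``(k * (n_channels - 1)) // max(K - 1, 1)`` so that for the canonical
3-channel (C3, Cz, C4) binary layout class 0 maps to C3 and class 1 to C4.

Identical :class:`SynthSpec` values (including ``seed``) produce bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import EEGTrialSet
from .errors import ConfigurationError

__all__ = [
    "SynthSpec",
    "generate_dataset",
    "inject_eog_artifacts",
    "pink_noise",
    "band_limited_noise",
    "lateralization_map",
]

MU_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)
#: baseline broadband RMS in microvolts; rhythm amplitude = snr * this
BACKGROUND_RMS_UV = 10.0
#: mu carries twice the rhythm energy of beta (mu-dominant sensorimotor idling)
MU_BETA_ENERGY_SPLIT = (2.0, 1.0)
EOG_BACKGROUND_RMS_UV = 3.0
ARTIFACT_DURATION_S = 0.5


@dataclass(frozen=True)
class SynthSpec:
    """Full parameterization of one synthetic corpus.

    Defaults mirror the canonical bipolar-montage binary paradigm: 9 subjects,
    3 channels (C3, Cz, C4), 250 Hz, epochs from 0.5 s before to 4 s after the
    cue, a moderate ERD of 0.5 and a rhythm-to-background amplitude ratio of 2.
    """

    n_subjects: int = 9
    n_trials_per_class: int = 20
    n_classes: int = 2
    n_channels: int = 3
    fs: float = 250.0
    epoch_window: tuple[float, float] = (-0.5, 4.0)
    erd_depth: float = 0.5
    background_exponent: float = 1.0
    snr: float = 2.0
    subject_gain_sd: float = 0.2
    artifact_fraction: float = 0.1
    artifact_amplitude: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_subjects", self.n_subjects >= 1),
            ("n_trials_per_class", self.n_trials_per_class >= 1),
            ("n_classes", self.n_classes in (2, 4)),
            ("n_channels", self.n_channels >= 1),
            ("fs", self.fs > 0),
            ("epoch_window", self.epoch_window[0] < self.epoch_window[1]),
            ("erd_depth", 0.0 <= self.erd_depth <= 1.0),
            ("snr", self.snr >= 0),
            ("subject_gain_sd", self.subject_gain_sd >= 0),
            ("artifact_fraction", 0.0 <= self.artifact_fraction <= 1.0),
            ("artifact_amplitude", self.artifact_amplitude >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(f"invalid value for field '{name}'")
        if self.n_channels < self.n_classes and self.n_channels > 1:
            # round-robin still works but classes share channels; allowed.
            pass

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.fs))


def lateralization_map(n_classes: int, n_channels: int) -> np.ndarray:
    """Class -> modulated channel assignment (round-robin over channels).

    For 3 channels / 2 classes this yields (0, 2): class 0 modulates "C3",
    class 1 modulates "C4", matching contralateral hand-imagery physiology.
    """
    if n_channels == 1:
        return np.zeros(n_classes, dtype=np.int64)
    span = max(n_classes - 1, 1)
    return np.array(
        [(k * (n_channels - 1)) // span for k in range(n_classes)], dtype=np.int64
    )


def pink_noise(
    n_samples: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^exponent noise with unit RMS, synthesized in the frequency domain."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros(n_freq)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    coeff = amp * (
        rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    )
    coeff[0] = 0.0
    x = np.fft.irfft(coeff, n=n_samples)
    return x / np.sqrt(np.mean(x**2))


def band_limited_noise(
    band: tuple[float, float],
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS noise band-passed into ``band`` (4th-order Butterworth)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # generous warm-up so filter transients never enter the epoch
    pad = int(2 * fs)
    x = signal.sosfilt(sos, rng.standard_normal(n_samples + pad))[pad:]
    return x / np.sqrt(np.mean(x**2))


def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.pi * np.arange(n) / max(n - 1, 1))


def _default_channel_names(n: int) -> list[str]:
    if n == 3:
        return ["C3", "Cz", "C4"]
    return [f"EEG{i:02d}" for i in range(n)]


def generate_dataset(spec: SynthSpec) -> EEGTrialSet:
    """Generate one synthetic corpus according to ``spec``.

    Trials are balanced per class within each subject. Labels, subject gains,
    rhythm waveforms and artifact placement are all drawn from a generator
    seeded by ``spec.seed``, so equal specs give bit-identical datasets.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_samples = spec.n_samples
    times = (
        int(round(spec.epoch_window[0] * spec.fs)) + np.arange(n_samples)
    ) / spec.fs
    post_cue = times >= 0.0
    lat = lateralization_map(spec.n_classes, spec.n_channels)
    mu_w, beta_w = MU_BETA_ENERGY_SPLIT
    total = mu_w + beta_w
    mu_rms = spec.snr * BACKGROUND_RMS_UV * np.sqrt(mu_w / total)
    beta_rms = spec.snr * BACKGROUND_RMS_UV * np.sqrt(beta_w / total)

    n_per_subj = spec.n_trials_per_class * spec.n_classes
    n_total = n_per_subj * spec.n_subjects
    data = np.empty((n_total, spec.n_channels, n_samples))
    eog = np.empty((n_total, 1, n_samples))
    labels = np.empty(n_total, dtype=np.int64)
    subjects = np.empty(n_total, dtype=np.int64)

    t = 0
    for s in range(spec.n_subjects):
        gain = float(np.exp(rng.normal(0.0, spec.subject_gain_sd)))
        subj_labels = np.repeat(np.arange(spec.n_classes), spec.n_trials_per_class)
        rng.shuffle(subj_labels)
        n_artifact = int(round(spec.artifact_fraction * n_per_subj))
        artifact_trials = set(
            rng.choice(n_per_subj, size=n_artifact, replace=False).tolist()
        )
        for i in range(n_per_subj):
            label = int(subj_labels[i])
            erd_channel = int(lat[label])
            for c in range(spec.n_channels):
                bg = BACKGROUND_RMS_UV * pink_noise(
                    n_samples, spec.fs, spec.background_exponent, rng
                )
                mu = mu_rms * band_limited_noise(MU_BAND, n_samples, spec.fs, rng)
                beta = beta_rms * band_limited_noise(
                    BETA_BAND, n_samples, spec.fs, rng
                )
                rhythm = mu + beta
                if c == erd_channel and spec.erd_depth > 0:
                    envelope = np.where(post_cue, 1.0 - spec.erd_depth, 1.0)
                    rhythm = rhythm * envelope
                data[t, c] = gain * (bg + rhythm)
            trace = EOG_BACKGROUND_RMS_UV * pink_noise(n_samples, spec.fs, 2.0, rng)
            if i in artifact_trials and spec.artifact_amplitude > 0:
                trace = _add_deflection(
                    trace, spec.artifact_amplitude, spec.fs, rng
                )
            eog[t, 0] = trace
            labels[t] = label
            subjects[t] = s
            t += 1

    return EEGTrialSet(
        data=data,
        labels=labels,
        subjects=subjects,
        channel_names=_default_channel_names(spec.n_channels),
        fs=spec.fs,
        window=spec.epoch_window,
        eog=eog,
        meta={"generator": "mieeg.synth", "seed": spec.seed},
    )


def _add_deflection(
    trace: np.ndarray, amplitude: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Add one half-sine ocular deflection whose peak reaches |amplitude|.

    The deflection sign follows the existing sample value at the peak, so the
    summed trace is guaranteed to reach at least ``amplitude`` in magnitude.
    A zero amplitude is a numerical no-op.
    """
    n = len(trace)
    width = min(int(round(ARTIFACT_DURATION_S * fs)), n)
    onset = int(rng.integers(0, n - width + 1))
    shape = _half_sine(width)
    peak_idx = onset + int(np.argmax(shape))
    sign = 1.0 if trace[peak_idx] >= 0 else -1.0
    out = trace.copy()
    out[onset : onset + width] += sign * amplitude * shape
    return out


def inject_eog_artifacts(
    ds: EEGTrialSet,
    indices: list[int] | np.ndarray,
    amplitude: float,
    seed: int = 0,
) -> EEGTrialSet:
    """Return a copy of ``ds`` with ocular deflections added at ``indices``.

    Each listed trial's EOG trace receives a half-sine deflection of 0.5 s
    whose peak magnitude reaches at least ``amplitude`` microvolts; all other
    trials are untouched. Requires an EOG block.
    """
    if ds.eog is None:
        raise ConfigurationError("dataset has no field 'eog' to inject into")
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size and (indices.min() < 0 or indices.max() >= ds.n_trials):
        raise ConfigurationError("invalid value for field 'indices'")
    out = ds.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for i in indices:
        for ch in range(out.eog.shape[1]):
            out.eog[i, ch] = _add_deflection(out.eog[i, ch], amplitude, ds.fs, rng)
    return out
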