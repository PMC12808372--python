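"""Optional GDF ingestion adapter.

Maps a GDF recording plus its event table onto an :class:`EEGTrialSet`, for
users who hold the benchmark motor-imagery competition recordings locally.
Requires the optional ``mne`` dependency; nothing else in the package (and
no test) depends on this module.
"""

from __future__ import annotations

from .data import EEGTrialSet
from .preprocessing import epoch

__all__ = ["read_gdf_trials"]


def read_gdf_trials(
    path: str,
    event_to_label: dict[str, int],
    window: tuple[float, float] = (-0.5, 4.0),
    subject: int = 0,
    eog_prefix: str = "EOG",
) -> EEGTrialSet:
    """Epoch a GDF recording into trials.

    Parameters
    ----------
    path:
        GDF file path.
    event_to_label:
        Mapping from annotation description (e.g. ``"769"``) to class label.
    window:
        Epoch window in seconds relative to each cue.
    subject:
        Subject identifier to stamp on every trial.
    eog_prefix:
        Channels whose name starts with this prefix become the EOG block.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "GDF ingestion requires the optional 'mne' dependency "
            "(pip install mieeg[gdf])"
        ) from exc

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    names = raw.ch_names
    eog_idx = [i for i, n in enumerate(names) if n.upper().startswith(eog_prefix)]
    eeg_idx = [i for i in range(len(names)) if i not in eog_idx]
    signal_uv = raw.get_data() * 1e6  # volts -> microvolts

    onsets, labels = [], []
    for ann in raw.annotations:
        desc = str(ann["description"])
        if desc in event_to_label:
            onsets.append(int(round(ann["onset"] * fs)))
            labels.append(event_to_label[desc])

    ds, _ = epoch(
        signal_uv[eeg_idx],
        onsets,
        window,
        fs,
        labels=labels,
        subject=subject,
        channel_names=[names[i] for i in eeg_idx],
    )
    if eog_idx:
        eog_ds, _ = epoch(signal_uv[eog_idx], onsets, window, fs, labels=labels)
        ds.eog = eog_ds.data
    return ds
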