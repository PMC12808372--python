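"""Generate a synthetic motor-imagery corpus and inspect its structure.

The generator builds 1/f background plus band-limited mu (8-12 Hz) and beta
(13-30 Hz) rhythms; in each trial's class-assigned contralateral channel the
rhythm amplitude drops by erd_depth after the cue (event-related
desynchronization). The printed bandpower contrast is the physical signature
a motor-imagery decoder learns from.
"""

import numpy as np
from scipy import signal

from mieeg import SynthSpec, generate_dataset

spec = SynthSpec(
    n_subjects=3,
    n_trials_per_class=20,
    n_classes=2,
    n_channels=3,          # C3, Cz, C4
    epoch_window=(-0.5, 4.0),
    erd_depth=0.5,
    snr=2.0,
    artifact_fraction=0.1,
    seed=0,
)
ds = generate_dataset(spec)
print(f"trials: {ds.data.shape} (trials x channels x samples) at {ds.fs} Hz")
print(f"subjects: {ds.subject_ids.tolist()}, classes: {ds.n_classes}")

# mu-band log power in the post-cue window, per class, at C3 (channel 0)
post = ds.times() >= 0
freqs, psd = signal.welch(ds.data[:, :, post], fs=ds.fs, nperseg=256, axis=-1)
mu = (freqs >= 8) & (freqs <= 12)
bp = np.log(np.trapezoid(psd[..., mu], freqs[mu], axis=-1))
for k in range(2):
    print(f"class {k}: mean mu log-power at C3 = {bp[ds.labels == k, 0].mean():.3f}")
print("class 0 (left-hand imagery) suppresses C3 mu power relative to class 1;")
print("that difference is the discriminative signal.")
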