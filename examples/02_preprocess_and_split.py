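"""The standard preprocessing pipeline on a synthetic corpus.

Order: common-average reference -> EOG-threshold trial rejection (trials
whose ocular channel exceeds +/-100 uV are dropped before filtering) ->
zero-phase 8-30 Hz Butterworth band-pass -> stratified per-subject split ->
standardization fitted on the training portion only.
"""

import numpy as np

from mieeg import (
    FilterSpec,
    SplitScheme,
    SynthSpec,
    apply_standardizer,
    bandpass,
    car_reference,
    fit_standardizer,
    generate_dataset,
    reject_eog_trials,
    stratified_split,
)

ds = generate_dataset(
    SynthSpec(n_subjects=2, n_trials_per_class=20, artifact_fraction=0.15, seed=1)
)
print(f"raw: {ds.n_trials} trials")

ds = car_reference(ds)
ds, rejected = reject_eog_trials(ds, threshold_uv=100.0)
print(f"EOG screening rejected {len(rejected)} trials (ocular peak > 100 uV)")

ds = bandpass(ds, FilterSpec(low_hz=8, high_hz=30, order=4))
plan = stratified_split(ds, SplitScheme.from_name("IV-2b", seed=0))
train = ds.select(plan.train_idx)
test = ds.select(plan.test_idx)
print(f"split: {train.n_trials} train / {len(plan.val_idx)} val / {test.n_trials} test")

scaler = fit_standardizer(train)
train_z = apply_standardizer(scaler, train)
test_z = apply_standardizer(scaler, test)
print(f"train channel means after standardization: "
      f"{np.round(train_z.data.mean(axis=(0, 2)), 6).tolist()}")
print("test trials reuse the training statistics - no leakage into the fit.")
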