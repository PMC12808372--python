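"""Pretrain on pooled source subjects, then fine-tune conservatively.

Demonstrates the two-stage transfer recipe at desk scale: a scratch stage on
the pooled source subjects (Adam, lr 1e-3), then a reduced fine-tuning stage
on the target subject's training split (lr 5e-5) with the lower half of the
transformer frozen to protect the general temporal representations. Epoch
budgets are cut far below the full 150/75 schedule to stay CPU-friendly.
"""

import dataclasses

import numpy as np

from mieeg import SynthSpec, bandpass, car_reference, generate_dataset
from mieeg.model import ModelConfig
from mieeg.training import plan_for_regime, pretrain_then_finetune

ds = bandpass(car_reference(generate_dataset(SynthSpec(
    n_subjects=3, n_trials_per_class=8, epoch_window=(-0.5, 1.0),
    erd_depth=0.6, snr=2.0, artifact_fraction=0.0, seed=2,
))))
target_subject = 2
source = ds.select(np.flatnonzero(ds.subjects != target_subject))
target = ds.select(np.flatnonzero(ds.subjects == target_subject))

cfg = ModelConfig(
    variant_name="desk", n_channels=3, n_samples=ds.n_samples, n_classes=2,
    deep_block_filters=(8, 16), shallow_spatial_filters=16,
    shallow_temporal_kernel_t=11, fusion_dim=32, transformer_ff_dim=64,
    bilstm_hidden=16, mlp_hidden=32, n_transformer_layers=2, bilstm_layers=1,
)
pre = dataclasses.replace(plan_for_regime("scratch", seed=0), epochs=4)
ft = dataclasses.replace(plan_for_regime("finetune_reduced", seed=0), epochs=3)

model, prov = pretrain_then_finetune(cfg, (source, None), (target, None), pre, ft)
print(f"pretrain: {prov['pre_history'].epochs_run} epochs at lr "
      f"{prov['pre_plan']['learning_rate']}")
print(f"finetune: {prov['ft_history'].epochs_run} epochs at lr "
      f"{prov['ft_plan']['learning_rate']} "
      f"(frozen transformer layers: {prov['ft_plan']['transformer_frozen_layers']})")
print(f"final fine-tuning train loss: {prov['ft_history'].train_loss[-1]:.4f}")
print("the reduced regime moves weights gently - the point of conservative")
print("adaptation is to avoid catastrophic forgetting of the pretrained features.")
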