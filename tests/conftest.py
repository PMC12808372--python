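"""Shared fixtures: small synthetic corpora and tiny model configurations."""

import numpy as np
import pytest

from mieeg.model import ModelConfig
from mieeg.synth import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Short-epoch, separable 2-class corpus: 3 subjects, 8 trials/class."""
    return SynthSpec(
        n_subjects=3,
        n_trials_per_class=8,
        n_classes=2,
        n_channels=3,
        epoch_window=(-0.5, 1.5),
        erd_depth=0.6,
        snr=2.0,
        artifact_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def separable_dataset():
    """Larger separable corpus for classifier sanity checks."""
    return generate_dataset(
        SynthSpec(
            n_subjects=4,
            n_trials_per_class=15,
            n_classes=2,
            n_channels=3,
            epoch_window=(-0.5, 1.5),
            erd_depth=0.6,
            snr=2.0,
            artifact_fraction=0.0,
            seed=11,
        )
    )


def tiny_model_config(
    n_samples: int = 256,
    n_channels: int = 3,
    n_classes: int = 2,
    **overrides,
) -> ModelConfig:
    """A CPU-friendly decoder configuration used across the model tests."""
    base = dict(
        variant_name="tiny",
        n_channels=n_channels,
        n_samples=n_samples,
        n_classes=n_classes,
        deep_block_filters=(4, 8),
        shallow_spatial_filters=8,
        shallow_temporal_kernel_t=11,
        fusion_dim=16,
        transformer_ff_dim=32,
        bilstm_hidden=8,
        mlp_hidden=16,
        n_transformer_layers=2,
        bilstm_layers=1,
        positional_encoding=True,
    )
    base.update(overrides)
    return ModelConfig(**base)
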