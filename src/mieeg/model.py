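"""The hybrid CNN-Transformer-BiLSTM motor-imagery decoder.

Dataflow (input ``(B, 1, n_samples, n_channels)`` -> logits ``(B, K)``):

* **deep branch** - two blocks of [2-D convolution -> batch norm ->
  activation -> temporal max-pool -> dropout 0.4]. The first kernel spans
  all channels jointly with a temporal extent, so the branch emits
  ``(B, F_deep, T', 1)``.
* **shallow branch** - a spatial convolution whose kernel spans all channels,
  a temporal convolution, batch norm, activation, temporal average-pool and
  dropout 0.4, emitting ``(B, F_shallow, T', 1)``.
* both branches share ``T' = n_samples // pool_product`` (deep: two pools of
  stride ``sqrt(pool_product)``; shallow: one pool of stride
  ``pool_product``); their features concatenate (default 64 + 80 = 144) and a
  pointwise fusion projects them to ``fusion_dim`` (default 128).
* optional fixed sinusoidal positional encoding, then a transformer encoder
  (post-norm, GELU, ``n_heads`` self-attention heads), a bidirectional LSTM
  stack, arithmetic mean over time, and an MLP head.

``width_multiplier`` scales the fusion width, the transformer feed-forward
width and the BiLSTM hidden size; it exists to emulate enlarged activation-
swap variants and its preset values are calibrated estimates, not measured
facts about any external model.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, GeometryError
from .nn.autograd import Tensor, concat

__all__ = [
    "ModelConfig",
    "ModelSummary",
    "HybridDecoder",
    "build_model",
    "count_parameters",
    "make_preset",
    "PRESET_NAMES",
    "save_checkpoint",
    "load_checkpoint",
    "adapt_to_geometry",
]

#: width multipliers emulating the enlarged ReLU/Tanh variants (estimates,
#: calibrated so the scaled networks land near the reported sizes)
WIDTH_MULT_RELU = 2.08
WIDTH_MULT_TANH = 1.80

PRESET_NAMES = (
    "baseline",
    "tl",
    "tl_relu",
    "tl_tanh",
    "tl_lstm",
    "scratch_simplified",
)


@dataclass(frozen=True)
class ModelConfig:
    """Declarative record of one decoder variant."""

    variant_name: str = "tl"
    n_channels: int = 3
    n_samples: int = 1125
    n_classes: int = 2
    activation: str = "elu"
    deep_block_filters: tuple[int, int] = (32, 64)
    deep_kernels_t: tuple[int, int] = (7, 5)
    shallow_spatial_filters: int = 80
    shallow_temporal_kernel_t: int = 25
    conv_dropout: float = 0.4
    pool_product: int = 4
    fusion_dim: int = 128
    positional_encoding: bool = True
    n_transformer_layers: int = 8
    n_heads: int = 4
    transformer_activation: str = "gelu"
    transformer_ff_dim: int = 256
    bilstm_layers: int = 3
    bilstm_hidden: int = 128
    bilstm_dropout: float = 0.3
    mlp_hidden: int = 128
    mlp_dropout: float = 0.5
    extra_lstm_branch: bool = False
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_samples", "n_classes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"invalid value for field '{name}'")
        if self.activation.lower() not in {"elu", "relu", "tanh"}:
            raise ConfigurationError("invalid value for field 'activation'")
        for name in ("conv_dropout", "bilstm_dropout", "mlp_dropout"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigurationError(f"invalid value for field '{name}'")
        if self.width_multiplier <= 0:
            raise ConfigurationError("invalid value for field 'width_multiplier'")
        root = int(round(np.sqrt(self.pool_product)))
        if root * root != self.pool_product:
            raise ConfigurationError(
                "invalid value for field 'pool_product': must be a perfect "
                "square (deep branch pools twice with equal stride)"
            )
        if self.n_samples < self.pool_product * 8:
            raise ConfigurationError(
                "invalid value for field 'n_samples': need >= 8 * pool_product"
            )
        if self.scaled_fusion_dim % self.n_heads:
            raise ConfigurationError(
                "invalid value for field 'fusion_dim': scaled width "
                f"{self.scaled_fusion_dim} not divisible by n_heads={self.n_heads}"
            )
        for k in (*self.deep_kernels_t, self.shallow_temporal_kernel_t):
            if k % 2 == 0 or k < 1:
                raise ConfigurationError(
                    "temporal kernels must be odd and positive"
                )

    # -- width scaling -----------------------------------------------------
    def _scale(self, width: int) -> int:
        scaled = int(round(width * self.width_multiplier / self.n_heads))
        return max(self.n_heads, scaled * self.n_heads)

    @property
    def scaled_fusion_dim(self) -> int:
        return self._scale(self.fusion_dim)

    @property
    def scaled_ff_dim(self) -> int:
        return self._scale(self.transformer_ff_dim)

    @property
    def scaled_bilstm_hidden(self) -> int:
        return self._scale(self.bilstm_hidden)

    @property
    def t_prime(self) -> int:
        return self.n_samples // self.pool_product


@dataclass
class ModelSummary:
    """Trainable-parameter accounting for one built model."""

    n_parameters: int
    n_parameters_millions: float
    layer_table: list[tuple[str, tuple[int, ...], int]] = field(default_factory=list)


def _sinusoidal_encoding(t_len: int, dim: int) -> np.ndarray:
    position = np.arange(t_len)[:, None]
    div = np.exp(np.arange(0, dim, 2) * (-np.log(10000.0) / dim))
    pe = np.zeros((t_len, dim))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div[: pe[:, 1::2].shape[1]])
    return pe


class _BiLSTMStack(nn.Module):
    """Stack of bidirectional LSTM layers with inter-layer dropout."""

    def __init__(self, input_size: int, hidden: int, n_layers: int,
                 dropout: float, rng, rng_box: nn.RngBox):
        super().__init__()
        fwd, bwd = [], []
        for i in range(n_layers):
            in_dim = input_size if i == 0 else 2 * hidden
            fwd.append(nn.LSTM(in_dim, hidden, rng))
            bwd.append(nn.LSTM(in_dim, hidden, rng, reverse=True))
        self.fwd = nn.ModuleList(fwd)
        self.bwd = nn.ModuleList(bwd)
        self.drop = nn.Dropout(dropout, rng_box)
        self.n_layers = n_layers

    def forward(self, x: Tensor) -> Tensor:
        for i in range(self.n_layers):
            out = concat([self.fwd[i](x), self.bwd[i](x)], axis=2)
            if i < self.n_layers - 1:
                out = self.drop(out)
            x = out
        return x


class HybridDecoder(nn.Module):
    """The assembled decoder; see module docstring for the dataflow."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.rng_box = nn.RngBox(seed + 1)
        act = cfg.activation.lower()
        C = cfg.n_channels
        f1, f2 = cfg.deep_block_filters
        k1, k2 = cfg.deep_kernels_t
        stride = int(round(np.sqrt(cfg.pool_product)))
        self._deep_stride = stride

        # deep branch: joint temporal-spatial first kernel collapses channels
        self.deep_conv1 = nn.Conv2d(1, f1, (k1, C), rng, pad=(k1 // 2, 0))
        self.deep_bn1 = nn.BatchNorm2d(f1)
        self.deep_conv2 = nn.Conv2d(f1, f2, (k2, 1), rng, pad=(k2 // 2, 0))
        self.deep_bn2 = nn.BatchNorm2d(f2)
        # shallow branch: spatial then temporal convolution
        fs = cfg.shallow_spatial_filters
        kt = cfg.shallow_temporal_kernel_t
        self.shallow_spatial = nn.Conv2d(1, fs, (1, C), rng)
        self.shallow_temporal = nn.Conv2d(fs, fs, (kt, 1), rng, pad=(kt // 2, 0))
        self.shallow_bn = nn.BatchNorm2d(fs)

        self.act = nn.Activation(act)
        self.conv_drop = nn.Dropout(cfg.conv_dropout, self.rng_box)

        d = cfg.scaled_fusion_dim
        self.fusion = nn.Linear(f2 + fs, d, rng)

        t_deep = (cfg.n_samples // stride) // stride
        t_shallow = cfg.n_samples // cfg.pool_product
        if t_deep != t_shallow:
            raise GeometryError(
                f"branch temporal lengths differ: deep pools 2x stride {stride} "
                f"-> {t_deep}, shallow pools stride {cfg.pool_product} -> "
                f"{t_shallow}"
            )
        self._pe = (
            _sinusoidal_encoding(t_shallow, d) if cfg.positional_encoding else None
        )

        self.transformer = nn.ModuleList(
            [
                nn.TransformerEncoderLayer(
                    d, cfg.n_heads, cfg.scaled_ff_dim, rng,
                    activation=cfg.transformer_activation,
                )
                for _ in range(cfg.n_transformer_layers)
            ]
        )
        h = cfg.scaled_bilstm_hidden
        self.bilstm = _BiLSTMStack(
            d, h, cfg.bilstm_layers, cfg.bilstm_dropout, rng, self.rng_box
        )
        feat = 2 * h
        if cfg.extra_lstm_branch:
            self.extra_lstm = nn.LSTM(d, h, rng)
            feat += h
        self.head_hidden = nn.Linear(feat, cfg.mlp_hidden, rng)
        self.head_drop = nn.Dropout(cfg.mlp_dropout, self.rng_box)
        self.head_out = nn.Linear(cfg.mlp_hidden, cfg.n_classes, rng)

    def reseed_dropout(self, seed: int) -> None:
        self.rng_box.reseed(seed)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.shape[1:] != (1, cfg.n_samples, cfg.n_channels):
            raise GeometryError(
                f"expected input (B, 1, {cfg.n_samples}, {cfg.n_channels}), "
                f"got {x.shape}"
            )
        s = self._deep_stride
        # deep branch
        d = self.deep_conv1(x)
        d = self.conv_drop(self.act(self.deep_bn1(d)).max_pool_time(s))
        d = self.deep_conv2(d)
        d = self.conv_drop(self.act(self.deep_bn2(d)).max_pool_time(s))
        # shallow branch
        sh = self.shallow_temporal(self.shallow_spatial(x))
        sh = self.conv_drop(
            self.act(self.shallow_bn(sh)).avg_pool_time(cfg.pool_product)
        )
        # fuse: (B, F, T', 1) each -> (B, T', F_deep + F_shallow) -> (B, T', d)
        fused = concat([d, sh], axis=1)
        B, F, Tp, _ = fused.shape
        fused = fused.reshape(B, F, Tp).transpose(0, 2, 1)
        z = self.fusion(fused)
        if self._pe is not None:
            z = z + Tensor(self._pe[None, :, :])
        for layer in self.transformer:
            z = layer(z)
        seq = self.bilstm(z)
        if cfg.extra_lstm_branch:
            seq = concat([seq, self.extra_lstm(z)], axis=2)
        pooled = seq.mean(axis=1)
        hid = self.head_drop(self.act(self.head_hidden(pooled)))
        return self.head_out(hid)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities in eval mode for a (B, 1, T, C) array."""
        self.eval()
        chunks = []
        for a in range(0, len(x), batch_size):
            logits = self.forward(Tensor(x[a : a + batch_size]))
            chunks.append(logits.softmax(axis=-1).data)
        return np.concatenate(chunks) if chunks else np.empty((0, self.cfg.n_classes))


def build_model(cfg: ModelConfig, seed: int = 0) -> HybridDecoder:
    """Construct a decoder with reproducible, seed-determined initialization."""
    return HybridDecoder(cfg, seed=seed)


def count_parameters(model: nn.Module) -> ModelSummary:
    """Count trainable parameters, with a per-tensor breakdown."""
    table = [
        (name, tuple(p.data.shape), int(p.size))
        for name, p in model.named_parameters()
        if p.requires_grad
    ]
    total = sum(n for _, _, n in table)
    return ModelSummary(
        n_parameters=total,
        n_parameters_millions=round(total / 1e6, 2),
        layer_table=table,
    )


def make_preset(
    name: str,
    n_channels: int = 3,
    n_samples: int = 1125,
    n_classes: int = 2,
) -> ModelConfig:
    """Named decoder variants.

    ``baseline`` and ``tl`` share the full architecture (8 transformer
    layers, 3 BiLSTM layers, positional encoding) and differ only in the
    training plan applied to them. ``scratch_simplified`` is the reduced
    from-scratch variant (6 transformer layers, 2 BiLSTM layers, positional
    encoding off). ``tl_relu`` / ``tl_tanh`` swap the activation and enlarge
    the network via ``width_multiplier``; ``tl_lstm`` adds a parallel
    unidirectional LSTM branch.
    """
    geometry = dict(
        n_channels=n_channels, n_samples=n_samples, n_classes=n_classes
    )
    presets = {
        "baseline": dict(activation="elu"),
        "tl": dict(activation="elu"),
        "tl_relu": dict(activation="relu", width_multiplier=WIDTH_MULT_RELU),
        "tl_tanh": dict(activation="tanh", width_multiplier=WIDTH_MULT_TANH),
        "tl_lstm": dict(activation="elu", extra_lstm_branch=True),
        "scratch_simplified": dict(
            activation="elu",
            n_transformer_layers=6,
            bilstm_layers=2,
            positional_encoding=False,
        ),
    }
    if name not in presets:
        raise ConfigurationError(
            f"unknown preset '{name}'; choose from {sorted(presets)}"
        )
    return ModelConfig(variant_name=name, **geometry, **presets[name])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------
def save_checkpoint(
    model: HybridDecoder, path: str | Path, meta: dict | None = None
) -> Path:
    """Single-file archive: named parameter arrays + embedded config JSON."""
    path = Path(path)
    state = model.state_dict()
    buf = io.BytesIO()
    np.savez_compressed(buf, **state)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("params.npz", buf.getvalue())
        zf.writestr("config.json", json.dumps(asdict(model.cfg)))
        zf.writestr("meta.json", json.dumps(meta or {}))
    return path


def load_checkpoint(
    path: str | Path, expected_cfg: ModelConfig | None = None, seed: int = 0
) -> tuple[HybridDecoder, dict]:
    """Rebuild a model from a checkpoint; fails loudly on config mismatch."""
    with zipfile.ZipFile(path) as zf:
        cfg_dict = json.loads(zf.read("config.json"))
        meta = json.loads(zf.read("meta.json"))
        with np.load(io.BytesIO(zf.read("params.npz"))) as bundle:
            state = {k: bundle[k] for k in bundle.files}
    for key in ("deep_block_filters", "deep_kernels_t"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = ModelConfig(**cfg_dict)
    if expected_cfg is not None and cfg != expected_cfg:
        raise ConfigurationError(
            "checkpoint config does not match the expected ModelConfig"
        )
    model = build_model(cfg, seed=seed)
    model.load_state_dict(state)
    return model, meta


# ---------------------------------------------------------------------------
# cross-geometry weight transfer
# ---------------------------------------------------------------------------
def adapt_to_geometry(
    source: HybridDecoder, target_cfg: ModelConfig, seed: int = 0
) -> tuple[HybridDecoder, list[str]]:
    """Transfer weights to a model with different channel/class geometry.

    Builds the target model, copies every parameter whose name and shape
    match (temporal convolutions, transformer, recurrent stack, hidden head
    layer), and leaves freshly initialized whatever depends on the changed
    geometry (the channel-spanning convolutions and, when the class count
    changes, the output layer). Returns the new model and the names that
    could NOT be transferred.
    """
    target = build_model(target_cfg, seed=seed)
    src_state = source.state_dict()
    reinitialized: list[str] = []
    for name, p in target.named_parameters():
        if name in src_state and src_state[name].shape == p.data.shape:
            p.data = src_state[name].copy()
        else:
            reinitialized.append(name)
    return target, reinitialized
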