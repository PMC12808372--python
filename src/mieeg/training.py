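"""Training regimes: from-scratch, full fine-tuning, reduced fine-tuning.

Three regimes with fixed hyperparameters (Adam, cross-entropy, batch 64):

========================  ======  =============
regime                    epochs  learning rate
========================  ======  =============
``scratch``               150     1e-3
``finetune_full``         150     5e-4
``finetune_reduced``      75      5e-5
========================  ======  =============

Fine-tuning applies a :class:`FreezePolicy` before the first optimizer step:
convolutional and recurrent parts stay trainable while a configurable set of
transformer encoder layers (default: the lower half) is frozen to protect the
general temporal representations acquired during pretraining. Frozen tensors
are excluded from the optimizer and remain bit-identical.

Model selection returns the parameters of the epoch with the best validation
accuracy (ties resolved to the earliest epoch). Fixed seeds give identical
training histories across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import EEGTrialSet
from .errors import ConfigurationError, GeometryError
from .model import HybridDecoder, ModelConfig, adapt_to_geometry, build_model
from .nn import Adam, cross_entropy
from .nn.autograd import Tensor

__all__ = [
    "FreezePolicy",
    "TrainPlan",
    "TrainHistory",
    "plan_for_regime",
    "apply_freeze_policy",
    "train",
    "pretrain_then_finetune",
    "trials_to_input",
    "NeuralPredictor",
]

log = logging.getLogger(__name__)

REGIMES = {
    "scratch": (150, 1e-3),
    "finetune_full": (150, 5e-4),
    "finetune_reduced": (75, 5e-5),
}


@dataclass(frozen=True)
class FreezePolicy:
    """Which parts stay fixed during fine-tuning.

    Default: convolutional, recurrent and head layers fully unfrozen; the
    lower half of the transformer encoder frozen (layers 0-3 of the 8-layer
    variant). ``transformer_frozen_layers=None`` is the adaptive "lower
    half" sentinel, resolved against the model depth at apply time.
    """

    conv_frozen: bool = False
    bilstm_frozen: bool = False
    transformer_frozen_layers: frozenset[int] | None = None
    mlp_frozen: bool = False

    def resolve(self, n_transformer_layers: int) -> frozenset[int]:
        if self.transformer_frozen_layers is None:
            return frozenset(range(n_transformer_layers // 2))
        return self.transformer_frozen_layers

    @classmethod
    def none(cls) -> "FreezePolicy":
        return cls(transformer_frozen_layers=frozenset())

    @classmethod
    def all_frozen(cls, n_transformer_layers: int) -> "FreezePolicy":
        return cls(
            conv_frozen=True,
            bilstm_frozen=True,
            transformer_frozen_layers=frozenset(range(n_transformer_layers)),
            mlp_frozen=True,
        )


@dataclass(frozen=True)
class TrainPlan:
    """Optimizer/schedule/freezing record for one training stage."""

    regime: str = "scratch"
    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 64
    freeze_policy: FreezePolicy = field(default_factory=FreezePolicy.none)
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigurationError(
                f"invalid value for field 'regime': choose from {sorted(REGIMES)}"
            )
        if self.learning_rate <= 0:
            raise ConfigurationError("invalid value for field 'learning_rate'")
        if self.epochs < 0:
            raise ConfigurationError("invalid value for field 'epochs'")
        if self.batch_size < 1:
            raise ConfigurationError("invalid value for field 'batch_size'")


def plan_for_regime(regime: str, seed: int = 0, **overrides) -> TrainPlan:
    """The documented (epochs, learning-rate) pair for a named regime."""
    if regime not in REGIMES:
        raise ConfigurationError(
            f"invalid value for field 'regime': choose from {sorted(REGIMES)}"
        )
    epochs, lr = REGIMES[regime]
    base = dict(regime=regime, epochs=epochs, learning_rate=lr, seed=seed)
    if regime != "scratch" and "freeze_policy" not in overrides:
        base["freeze_policy"] = FreezePolicy()
    base.update(overrides)
    return TrainPlan(**base)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    epochs_run: int = 0
    learning_rate: float = 0.0


def trials_to_input(ds: EEGTrialSet) -> np.ndarray:
    """(n, channels, samples) microvolt trials -> (n, 1, samples, channels)."""
    return np.ascontiguousarray(ds.data.transpose(0, 2, 1)[:, None, :, :])


def apply_freeze_policy(model: HybridDecoder, policy: FreezePolicy) -> list[str]:
    """Set ``requires_grad`` per the policy; returns the frozen names."""
    frozen: list[str] = []
    n_layers = model.cfg.n_transformer_layers
    frozen_layers = policy.resolve(n_layers)
    bad = [i for i in frozen_layers if i >= n_layers]
    if bad:
        raise ConfigurationError(
            f"invalid value for field 'transformer_frozen_layers': {bad} out "
            f"of range for {n_layers} layers"
        )
    for name, p in model.named_parameters():
        freeze = False
        if name.startswith(("deep_", "shallow_", "fusion.")):
            freeze = policy.conv_frozen
        elif name.startswith(("bilstm.", "extra_lstm.")):
            freeze = policy.bilstm_frozen
        elif name.startswith(("head_",)):
            freeze = policy.mlp_frozen
        elif name.startswith("transformer."):
            layer = int(name.split(".")[1][1:])  # "transformer.m<i>..."
            freeze = layer in frozen_layers
        p.requires_grad = not freeze
        if freeze:
            frozen.append(name)
    return frozen


def _evaluate(model: HybridDecoder, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    model.eval()
    losses, correct = [], 0
    for a in range(0, len(x), batch_size):
        xb, yb = x[a : a + batch_size], y[a : a + batch_size]
        logits = model(Tensor(xb))
        losses.append(float(cross_entropy(logits, yb).data) * len(yb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    model.train()
    return sum(losses) / len(y), correct / len(y)


def train(
    model: HybridDecoder,
    train_set: EEGTrialSet,
    val_set: EEGTrialSet | None,
    plan: TrainPlan,
) -> tuple[HybridDecoder, TrainHistory]:
    """Run one training stage in place; returns the best-validation model.

    The freeze policy is applied before the first step and frozen tensors are
    never touched by the optimizer. With ``epochs=0`` the model is returned
    unchanged. When no validation set is given, selection falls back to the
    final epoch.
    """
    if train_set.n_trials == 0:
        raise ConfigurationError("empty train set")
    if int(train_set.labels.max()) >= model.cfg.n_classes:
        raise ConfigurationError(
            f"label {int(train_set.labels.max())} out of range for "
            f"{model.cfg.n_classes} classes"
        )
    history = TrainHistory(learning_rate=plan.learning_rate)
    if plan.epochs == 0:
        return model, history

    apply_freeze_policy(model, plan.freeze_policy)
    model.reseed_dropout(plan.seed + 1)
    opt = Adam(model.parameters(), lr=plan.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    x = trials_to_input(train_set)
    y = train_set.labels
    xv = trials_to_input(val_set) if val_set is not None else None

    best_state = None
    best_acc = -1.0
    stale = 0
    model.train()
    for ep in range(plan.epochs):
        order = rng.permutation(len(x))
        ep_loss, ep_correct = 0.0, 0
        for a in range(0, len(order), plan.batch_size):
            idx = order[a : a + plan.batch_size]
            xb, yb = x[idx], y[idx]
            model.zero_grad()
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb)
            if loss.requires_grad:  # fully frozen models take no steps
                loss.backward()
                opt.step()
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((logits.data.argmax(axis=1) == yb).sum())
        history.train_loss.append(ep_loss / len(x))
        history.train_accuracy.append(ep_correct / len(x))
        if xv is not None:
            vl, va = _evaluate(model, xv, val_set.labels, plan.batch_size)
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
            if va > best_acc:  # strict: ties keep the earliest epoch
                best_acc = va
                history.best_epoch = ep
                best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
                if (
                    plan.early_stop_patience is not None
                    and stale >= plan.early_stop_patience
                ):
                    break
        history.epochs_run = ep + 1
    if best_state is not None:
        model.load_state_dict(best_state)
    else:
        history.best_epoch = history.epochs_run - 1
    model.eval()
    return model, history


def pretrain_then_finetune(
    cfg: ModelConfig,
    source_sets: tuple[EEGTrialSet, EEGTrialSet | None],
    target_sets: tuple[EEGTrialSet, EEGTrialSet | None],
    pre_plan: TrainPlan,
    ft_plan: TrainPlan,
    target_cfg: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[HybridDecoder, dict]:
    """Two-stage transfer: scratch pretraining, then fine-tuning with freezing.

    Stage 1 trains ``cfg`` from scratch on the pooled source subjects. Stage 2
    applies ``ft_plan`` (full or reduced regime with its freeze policy) on the
    target training data. If the target geometry differs, ``target_cfg`` must
    be supplied; the channel-spanning convolutions (and the output layer when
    the class count changes) are rebuilt and re-initialized while all temporal,
    transformer and recurrent weights transfer.
    """
    src_train, _ = source_sets
    tgt_train, tgt_val = target_sets
    model = build_model(cfg, seed=seed)
    model, pre_hist = train(model, *source_sets, plan=pre_plan)

    provenance: dict = {
        "pre_plan": _plan_record(pre_plan),
        "ft_plan": _plan_record(ft_plan),
        "seed": seed,
        "pre_history": pre_hist,
    }
    geometry_matches = (
        cfg.n_channels == tgt_train.n_channels
        and cfg.n_samples == tgt_train.n_samples
        and cfg.n_classes >= int(tgt_train.labels.max()) + 1
    )
    if not geometry_matches:
        if target_cfg is None:
            raise GeometryError(
                "source and target geometries differ; supply target_cfg to "
                "adapt the channel-spanning layers"
            )
        model, reinit = adapt_to_geometry(model, target_cfg, seed=seed + 1)
        provenance["reinitialized"] = reinit
    model, ft_hist = train(model, tgt_train, tgt_val, plan=ft_plan)
    provenance["ft_history"] = ft_hist
    return model, provenance


def _plan_record(plan: TrainPlan) -> dict:
    return {
        "regime": plan.regime,
        "epochs": plan.epochs,
        "learning_rate": plan.learning_rate,
        "batch_size": plan.batch_size,
        "seed": plan.seed,
        "transformer_frozen_layers": (
            "lower_half"
            if plan.freeze_policy.transformer_frozen_layers is None
            else sorted(plan.freeze_policy.transformer_frozen_layers)
        ),
    }


class NeuralPredictor:
    """Adapter giving the decoder the fit/predict contract of the LOSO engine.

    ``pretrained`` optionally carries a source model whose weights initialize
    fine-tuning; otherwise training starts from scratch with ``cfg``.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 pretrained: HybridDecoder | None = None):
        self.cfg = cfg
        self.seed = seed
        self.pretrained = pretrained
        self.model: HybridDecoder | None = None
        self.history: TrainHistory | None = None

    def fit(self, train_set: EEGTrialSet, val_set: EEGTrialSet | None,
            plan: TrainPlan) -> "NeuralPredictor":
        if self.pretrained is not None:
            model = build_model(self.cfg, seed=self.seed)
            model.load_state_dict(self.pretrained.state_dict())
        else:
            model = build_model(self.cfg, seed=self.seed)
        self.model, self.history = train(model, train_set, val_set, plan)
        return self

    def predict(self, ds: EEGTrialSet) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit() must run before predict()")
        proba = self.model.predict_proba(trials_to_input(ds))
        return proba.argmax(axis=1)
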