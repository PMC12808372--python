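"""Training regime contracts: freezing, determinism, regime hyperparameters,
two-stage transfer."""

import dataclasses

import numpy as np
import pytest

from mieeg.data import EEGTrialSet
from mieeg.errors import ConfigurationError
from mieeg.model import build_model
from mieeg.training import (
    FreezePolicy,
    TrainPlan,
    apply_freeze_policy,
    plan_for_regime,
    pretrain_then_finetune,
    train,
)

from conftest import tiny_model_config

T = 128  # short epochs keep these tests fast


def _toy_set(n=12, n_classes=2, seed=0, separation=3.0):
    """Linearly separable toy trials: class means differ per channel."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    data = rng.normal(size=(n, 3, T))
    for i, y in enumerate(labels):
        data[i, y % 3] += separation
    return EEGTrialSet(
        data=data,
        labels=labels,
        subjects=np.zeros(n, dtype=int),
        channel_names=["C3", "Cz", "C4"],
        fs=256.0,
        window=(0.0, T / 256.0),
    )


def _tiny_cfg(**kw):
    return tiny_model_config(n_samples=T, **kw)


def _flat_params(model) -> np.ndarray:
    return np.concatenate([p.data.ravel() for p in model.parameters()])


class TestRegimes:
    def test_regime_hyperparameters(self):
        assert (plan_for_regime("scratch").epochs,
                plan_for_regime("scratch").learning_rate) == (150, 1e-3)
        assert (plan_for_regime("finetune_full").epochs,
                plan_for_regime("finetune_full").learning_rate) == (150, 5e-4)
        assert (plan_for_regime("finetune_reduced").epochs,
                plan_for_regime("finetune_reduced").learning_rate) == (75, 5e-5)

    def test_default_finetune_freeze_is_lower_half(self):
        plan = plan_for_regime("finetune_full")
        assert plan.freeze_policy.resolve(8) == frozenset({0, 1, 2, 3})
        assert plan.freeze_policy.resolve(6) == frozenset({0, 1, 2})

    def test_invalid_plan_fields(self):
        with pytest.raises(ConfigurationError):
            TrainPlan(regime="warmup")
        with pytest.raises(ConfigurationError):
            TrainPlan(learning_rate=-1.0)


class TestTrainContracts:
    def test_zero_epochs_returns_identical_parameters(self):
        model = build_model(_tiny_cfg(), seed=0)
        before = _flat_params(model)
        plan = TrainPlan(regime="scratch", epochs=0, learning_rate=1e-3, seed=0)
        model, hist = train(model, _toy_set(), None, plan)
        np.testing.assert_array_equal(_flat_params(model), before)
        assert hist.epochs_run == 0

    def test_all_frozen_policy_is_identity(self):
        cfg = _tiny_cfg()
        model = build_model(cfg, seed=0)
        before = _flat_params(model)
        plan = TrainPlan(
            regime="scratch", epochs=2, learning_rate=1e-3, seed=0,
            freeze_policy=FreezePolicy.all_frozen(cfg.n_transformer_layers),
        )
        model, _ = train(model, _toy_set(), None, plan)
        np.testing.assert_array_equal(_flat_params(model), before)

    def test_empty_train_set_and_bad_labels_error(self):
        model = build_model(_tiny_cfg(), seed=0)
        empty = _toy_set().select([])
        with pytest.raises(ConfigurationError):
            train(model, empty, None, TrainPlan(regime="scratch", epochs=1))
        bad = _toy_set(n_classes=2)
        bad.labels[0] = 5
        with pytest.raises(ConfigurationError):
            train(model, bad, None, TrainPlan(regime="scratch", epochs=1))

    def test_loss_decreases_on_learnable_set(self):
        model = build_model(_tiny_cfg(), seed=1)
        plan = TrainPlan(regime="scratch", epochs=8, learning_rate=1e-3,
                         batch_size=12, seed=1)
        _, hist = train(model, _toy_set(separation=4.0), None, plan)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_training_history_deterministic_across_runs(self):
        histories = []
        for _ in range(2):
            model = build_model(_tiny_cfg(), seed=5)
            plan = TrainPlan(regime="scratch", epochs=3, learning_rate=1e-3,
                             batch_size=8, seed=5)
            _, hist = train(model, _toy_set(), _toy_set(seed=1), plan)
            histories.append(hist)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_accuracy == histories[1].val_accuracy
        assert histories[0].best_epoch == histories[1].best_epoch

    def test_validation_history_and_best_model_selection(self):
        model = build_model(_tiny_cfg(), seed=2)
        plan = TrainPlan(regime="scratch", epochs=4, learning_rate=1e-3,
                         batch_size=12, seed=2)
        _, hist = train(model, _toy_set(), _toy_set(seed=3), plan)
        assert len(hist.val_accuracy) == 4
        assert hist.best_epoch == int(np.argmax(hist.val_accuracy))


class TestFreezePolicy:
    def test_frozen_layer_indices_validated(self):
        cfg = _tiny_cfg()  # 2 transformer layers
        model = build_model(cfg, seed=0)
        with pytest.raises(ConfigurationError):
            apply_freeze_policy(
                model, FreezePolicy(transformer_frozen_layers=frozenset({5}))
            )

    def test_frozen_transformer_layers_bit_identical_conv_changed(self):
        """Default policy: frozen lower transformer layers untouched while
        every convolutional tensor moves."""
        cfg = _tiny_cfg()
        model = build_model(cfg, seed=3)
        policy = FreezePolicy(transformer_frozen_layers=frozenset({0}))
        before = {n: p.data.copy() for n, p in model.named_parameters()}
        plan = TrainPlan(regime="finetune_full", epochs=3, learning_rate=1e-3,
                         batch_size=12, seed=3, freeze_policy=policy)
        model, _ = train(model, _toy_set(), None, plan)
        for name, p in model.named_parameters():
            if name.startswith("transformer.m0."):
                np.testing.assert_array_equal(p.data, before[name])
            elif name.startswith(("deep_conv", "shallow_")):
                assert np.linalg.norm(p.data - before[name]) > 0, name


class TestPretrainThenFinetune:
    def _run(self, regime):
        cfg = _tiny_cfg()
        plan_pre = TrainPlan(regime="scratch", epochs=2, learning_rate=1e-3,
                             batch_size=12, seed=0)
        ft = plan_for_regime(regime, seed=0)
        ft = dataclasses.replace(
            ft, epochs=2, batch_size=12,
            freeze_policy=FreezePolicy(transformer_frozen_layers=frozenset({0})),
        )
        model, prov = pretrain_then_finetune(
            cfg, (_toy_set(seed=0), None), (_toy_set(seed=4), None),
            plan_pre, ft, seed=0,
        )
        return model, prov

    @pytest.mark.parametrize("regime,lr", [
        ("finetune_reduced", 5e-5),
        ("finetune_full", 5e-4),
    ])
    def test_finetune_stage_records_regime_lr(self, regime, lr):
        _, prov = self._run(regime)
        assert prov["ft_plan"]["learning_rate"] == lr
        assert prov["ft_history"].learning_rate == lr
        assert prov["ft_history"].epochs_run == 2

    def test_documented_epoch_budgets(self):
        assert plan_for_regime("finetune_reduced").epochs == 75
        assert plan_for_regime("finetune_full").epochs == 150

    def test_reduced_moves_parameters_less_than_full(self):
        """Lower learning rate and fewer updates => smaller L2 displacement."""
        cfg = _tiny_cfg()
        pre = TrainPlan(regime="scratch", epochs=2, learning_rate=1e-3,
                        batch_size=12, seed=0)
        model0 = build_model(cfg, seed=0)
        model0, _ = train(model0, _toy_set(seed=0), None, pre)
        start = _flat_params(model0)
        dists = {}
        for regime, epochs in (("finetune_full", 4), ("finetune_reduced", 2)):
            m = build_model(cfg, seed=0)
            m.load_state_dict(model0.state_dict())
            ft = dataclasses.replace(
                plan_for_regime(regime, seed=0), epochs=epochs, batch_size=12,
                freeze_policy=FreezePolicy(
                    transformer_frozen_layers=frozenset({0})
                ),
            )
            m, _ = train(m, _toy_set(seed=4), None, ft)
            dists[regime] = np.linalg.norm(_flat_params(m) - start)
        assert dists["finetune_reduced"] < dists["finetune_full"]

    def test_geometry_mismatch_without_adapter_errors(self):
        cfg = _tiny_cfg(n_channels=3)
        target = _toy_set(seed=1)
        target = EEGTrialSet(
            data=np.repeat(target.data, 2, axis=1),
            labels=target.labels,
            subjects=target.subjects,
            channel_names=[f"c{i}" for i in range(6)],
            fs=target.fs,
            window=target.window,
        )
        pre = TrainPlan(regime="scratch", epochs=0)
        ft = TrainPlan(regime="finetune_full", epochs=0, learning_rate=5e-4)
        from mieeg.errors import GeometryError

        with pytest.raises(GeometryError):
            pretrain_then_finetune(
                cfg, (_toy_set(seed=0), None), (target, None), pre, ft
            )
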