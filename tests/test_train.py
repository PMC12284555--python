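"""Context protocols, early stopping, and the shared training harness."""

import numpy as np
import pytest

from paomni.dataset import ImagePair
from paomni.omninet import ModelConfig, OmniNet
from paomni.train import (ContextSet, EarlyStopper, OmniNetAdapter, TrainConfig,
                          Trainer, UNetAdapter, context_size_sweep, context_swap,
                          group_context, infer, sliding_context, static_context)
from paomni.unet import BaselineUNet, UnetConfig


def make_pairs(n, shape=(16, 16), group=0):
    rng = np.random.default_rng(42)
    return [ImagePair(sparse_input=rng.random(shape, dtype=np.float32),
                      ground_truth=rng.random(shape, dtype=np.float32),
                      group_id=group, seed=i) for i in range(n)]


class TestSlidingContext:
    def test_next_four_pairs(self):
        pairs = make_pairs(6)
        ctx = sliding_context(pairs, index=0, window=4)
        assert [p.seed for p in ctx.pairs] == [1, 2, 3, 4]

    def test_wraps_modulo_dataset_size(self):
        pairs = make_pairs(6)
        ctx = sliding_context(pairs, index=4, window=4)
        assert [p.seed for p in ctx.pairs] == [5, 0, 1, 2]

    def test_never_contains_target(self):
        pairs = make_pairs(9)
        for i in range(9):
            ctx = sliding_context(pairs, i, 4)
            assert i not in [p.seed for p in ctx.pairs]

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            sliding_context(make_pairs(4), 0, window=4)


class TestStaticContext:
    def test_first_k_in_stored_order(self):
        pairs = make_pairs(100)
        ctx = static_context(pairs, 16)
        assert [p.seed for p in ctx.pairs] == list(range(16))

    def test_single_pair(self):
        assert static_context(make_pairs(3), 1).k == 1

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            static_context(make_pairs(100), 200)

    def test_group_context_filters_by_group(self, small_bundle):
        g = small_bundle.groups_in_split("train")[0]
        ctx = group_context(small_bundle, g, 3)
        assert all(p.group_id == g for p in ctx.pairs)
        with pytest.raises(ValueError):
            group_context(small_bundle, g, 99)


class TestEarlyStopping:
    def test_patience_rule_on_synthetic_sequence(self):
        # losses [1.0, 0.9, 0.95, 0.96, 0.97] with patience 3:
        # stop after epoch 5, best model is epoch 2
        stopper = EarlyStopper(patience=3)
        stops = [stopper.update(e, v) for e, v in
                 enumerate([1.0, 0.9, 0.95, 0.96, 0.97], start=1)]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 2

    def test_no_stop_while_improving(self):
        stopper = EarlyStopper(patience=2)
        assert not any(stopper.update(e, 1.0 / e) for e in range(1, 10))
        assert stopper.best_epoch == 9

    def test_plateau_does_not_count_as_improvement(self):
        stopper = EarlyStopper(patience=2)
        assert [stopper.update(e, v) for e, v in enumerate([1.0, 1.0, 1.0], 1)] \
            == [False, False, True]
        assert stopper.best_epoch == 1


TOY_MODEL = dict(base_channels=4, channel_multipliers=(1, 2, 2, 2))


def toy_trainer(bundle, seed=0, **kw):
    cfg = TrainConfig(loss="mse", learning_rate=1e-3, max_epochs=kw.pop("max_epochs", 2),
                      early_stop_patience=5, batch_size=4, context_size_train=4,
                      seed=seed, **kw)
    model = OmniNet(ModelConfig(seed=seed, **TOY_MODEL))
    return Trainer(OmniNetAdapter(model), bundle, cfg)


class TestTrainer:
    def test_same_seed_reproduces_loss_curve(self, small_bundle):
        h1 = toy_trainer(small_bundle, seed=3).fit().history
        h2 = toy_trainer(small_bundle, seed=3).fit().history
        assert np.array_equal(h1["train_loss"].to_numpy(), h2["train_loss"].to_numpy())
        assert np.array_equal(h1["val_loss"].to_numpy(), h2["val_loss"].to_numpy())

    def test_optimization_reduces_training_loss(self, small_bundle):
        hist = toy_trainer(small_bundle, seed=1, max_epochs=6).fit().history
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_best_epoch_weights_are_restored(self, small_bundle):
        result = toy_trainer(small_bundle, seed=2, max_epochs=3).fit()
        assert result.best_epoch == int(result.history["val_loss"].idxmin()) + 1
        assert result.best_val_loss == result.history["val_loss"].min()

    def test_unet_trains_through_same_harness(self, small_bundle):
        cfg = TrainConfig(loss="mse", learning_rate=1e-3, max_epochs=2,
                          early_stop_patience=5, batch_size=4, seed=0)
        adapter = UNetAdapter(BaselineUNet(UnetConfig(depth=2, base_channels=4, seed=0)))
        result = Trainer(adapter, small_bundle, cfg).fit()
        assert len(result.history) == 2
        assert "U" in result.summary()  # summary names the architecture

    def test_summary_mentions_key_facts(self, small_bundle):
        res = toy_trainer(small_bundle, seed=0).fit()
        text = res.summary()
        assert "OmniNet" in text and "Adam" in text and "best epoch" in text


@pytest.fixture(scope="module")
def fitted(small_bundle):
    return toy_trainer(small_bundle, seed=5).fit()


class TestInference:

    def test_repeat_calls_bitwise_identical(self, fitted, small_bundle):
        ctx = static_context(small_bundle.train, 8)
        xs = [p.sparse_input for p in small_bundle.test[:3]]
        a = infer(fitted.adapter, xs, ctx)
        b = infer(fitted.adapter, xs, ctx)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_outputs_clipped_to_unit_interval(self, fitted, small_bundle):
        ctx = static_context(small_bundle.train, 4)
        for y in infer(fitted.adapter, [p.sparse_input for p in small_bundle.test], ctx):
            assert y.min() >= 0.0 and y.max() <= 1.0

    def test_permuted_context_same_outputs(self, fitted, small_bundle):
        ctx = static_context(small_bundle.train, 8)
        perm = ContextSet(pairs=tuple(ctx.pairs[i] for i in [5, 2, 7, 0, 3, 6, 1, 4]))
        xs = [small_bundle.test[0].sparse_input]
        a = infer(fitted.adapter, xs, ctx)[0]
        b = infer(fitted.adapter, xs, perm)[0]
        assert np.abs(a - b).max() <= 1e-6

    def test_sweep_reports_one_row_per_size_and_duplication_invariance(
            self, fitted, small_bundle):
        pool = static_context(small_bundle.train, 8)
        sweep = context_size_sweep(fitted.adapter, small_bundle.test[:4], pool,
                                   sizes=[1, 2, 4, 8])
        assert list(sweep["context_size"]) == [1, 2, 4, 8]
        base = static_context(small_bundle.train, 4)
        doubled = ContextSet(pairs=base.pairs + base.pairs)
        r4 = context_size_sweep(fitted.adapter, small_bundle.test[:4], base, [4])
        r8 = context_size_sweep(fitted.adapter, small_bundle.test[:4], doubled, [8])
        assert np.isclose(r4["ssim"][0], r8["ssim"][0], atol=1e-6)

    def test_context_swap_identical_contexts_identical_reports(
            self, fitted, small_bundle):
        ctx = static_context(small_bundle.train, 4)
        reports = context_swap(fitted.adapter, small_bundle.test[:4],
                               {"a": ctx, "b": ctx})
        assert np.array_equal(reports["a"].ssim, reports["b"].ssim)
        with pytest.raises(ValueError):
            context_swap(fitted.adapter, small_bundle.test[:4], {})


class TestValidation:
    def test_context_set_constraints(self):
        with pytest.raises(ValueError):
            ContextSet(pairs=())
        pairs = make_pairs(3)
        ctx = ContextSet(pairs=tuple(pairs))
        assert ctx.take(2).k == 2
        with pytest.raises(ValueError):
            ctx.take(5)

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=0)
        with pytest.raises(ValueError):
            TrainConfig(context_size_train=0)
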