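"""PA OmniNet architecture: block/forward oracles and invariances."""

import numpy as np
import pytest

from paomni.autodiff import Tensor
from paomni.losses import mse_loss
from paomni.nnet import residual_unit, residual_unit_params
from paomni.omninet import FeatureState, ModelConfig, OmniNet, pairwise_conv_avg_block


# ---- plain-numpy reference ops (independent of the autodiff engine) ----

def np_conv(x, w, b):
    """Zero-same-padded correlation, explicit loops; x (C,h,w), w (O,C,k,k)."""
    o, c, k, _ = w.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    h, wd = x.shape[1:]
    out = np.zeros((o, h, wd))
    for oc in range(o):
        for i in range(h):
            for j in range(wd):
                out[oc, i, j] = (xp[:, i:i + k, j:j + k] * w[oc]).sum() + b[oc]
    return out


def np_lrelu(x, s=0.01):
    return np.where(x > 0, x, s * x)


def np_residual_unit(x, params, prefix):
    h = np_conv(x, params[f"{prefix}.conv1.w"].data, params[f"{prefix}.conv1.b"].data)
    h = np_conv(np_lrelu(h), params[f"{prefix}.conv2.w"].data, params[f"{prefix}.conv2.b"].data)
    if f"{prefix}.proj.w" in params:
        sc = np_conv(x, params[f"{prefix}.proj.w"].data, params[f"{prefix}.proj.b"].data)
    else:
        sc = x
    return sc + h


def np_block(target, ctx_in, ctx_out, params, prefix):
    """Naive per-pair loop implementation of the Pairwise-Conv-Avg block."""
    t1 = np_residual_unit(target, params, f"{prefix}.target")
    cands = []
    new_in, new_out = [], []
    for cin_k, cout_k in zip(ctx_in, ctx_out):
        i1 = np_residual_unit(cin_k, params, f"{prefix}.context")
        o1 = np_residual_unit(cout_k, params, f"{prefix}.context")
        cat = np.concatenate([t1, i1, o1], axis=0)
        cands.append(np_conv(cat, params[f"{prefix}.pair.w"].data,
                             params[f"{prefix}.pair.b"].data))
        new_in.append(i1)
        new_out.append(o1)
    return np.mean(cands, axis=0), new_in, new_out


TINY = ModelConfig(base_channels=4, channel_multipliers=(1, 2, 2, 2), seed=5,
                   dtype="float64")


class TestResidualUnit:
    def test_zero_weights_give_identity(self):
        rng = np.random.default_rng(0)
        params = residual_unit_params(rng, "ru", 3, 3, dtype=np.float64)
        for p in params.values():
            p.data = np.zeros_like(p.data)
        x = Tensor(rng.standard_normal((1, 3, 8, 8)))
        out = residual_unit(x, params, "ru")
        assert np.array_equal(out.data, x.data)

    def test_matches_direct_composition(self):
        rng = np.random.default_rng(1)
        params = residual_unit_params(rng, "ru", 3, 5, dtype=np.float64)
        x = rng.standard_normal((3, 8, 8))
        ref = np_residual_unit(x, params, "ru")
        out = residual_unit(Tensor(x[None]), params, "ru").data[0]
        assert np.abs(out - ref).max() < 1e-10

    def test_linearity_without_activation(self):
        rng = np.random.default_rng(2)
        params = residual_unit_params(rng, "ru", 4, 4, dtype=np.float64)
        for name in ("ru.conv1.b", "ru.conv2.b"):
            params[name].data = np.zeros_like(params[name].data)
        x = Tensor(rng.standard_normal((1, 4, 8, 8)))
        f_x = residual_unit(x, params, "ru", activation="none").data
        f_3x = residual_unit(Tensor(3.0 * x.data), params, "ru", activation="none").data
        assert np.abs(f_3x - 3.0 * f_x).max() < 1e-9

    def test_shape_preserved(self):
        rng = np.random.default_rng(3)
        params = residual_unit_params(rng, "ru", 2, 2)
        out = residual_unit(Tensor(np.zeros((1, 2, 16, 16), dtype=np.float32)), params, "ru")
        assert out.data.shape == (1, 2, 16, 16)


class TestPairwiseConvAvgBlock:
    def _state(self, rng, c, k, h=8):
        return FeatureState(
            target=Tensor(rng.standard_normal((1, c, h, h))),
            ctx_in=Tensor(rng.standard_normal((k, c, h, h))),
            ctx_out=Tensor(rng.standard_normal((k, c, h, h))),
        )

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(7)
        model = OmniNet(ModelConfig(base_channels=4, channel_multipliers=(1, 1, 1, 1),
                                    seed=7, dtype="float64"))
        state = self._state(rng, 4, k=2)
        out = pairwise_conv_avg_block(state, model.params, "enc0", resize="none")
        ref_t, ref_in, ref_out = np_block(state.target.data[0], state.ctx_in.data,
                                          state.ctx_out.data, model.params, "enc0")
        assert np.abs(out.target.data[0] - ref_t).max() < 1e-6
        for k in range(2):
            assert np.abs(out.ctx_in.data[k] - ref_in[k]).max() < 1e-6
            assert np.abs(out.ctx_out.data[k] - ref_out[k]).max() < 1e-6

    def test_context_permutation_invariance(self):
        rng = np.random.default_rng(8)
        model = OmniNet(TINY)
        state = self._state(rng, 4, k=5)
        out1 = pairwise_conv_avg_block(state, model.params, "enc0", "none")
        perm = rng.permutation(5)
        state_p = FeatureState(target=Tensor(state.target.data),
                               ctx_in=Tensor(state.ctx_in.data[perm]),
                               ctx_out=Tensor(state.ctx_out.data[perm]))
        out2 = pairwise_conv_avg_block(state_p, model.params, "enc0", "none")
        assert np.abs(out1.target.data - out2.target.data).max() <= 1e-6

    def test_duplicated_single_pair_equals_singleton(self):
        rng = np.random.default_rng(9)
        model = OmniNet(TINY)
        s1 = self._state(rng, 4, k=1)
        s4 = FeatureState(target=Tensor(s1.target.data),
                          ctx_in=Tensor(np.repeat(s1.ctx_in.data, 4, axis=0)),
                          ctx_out=Tensor(np.repeat(s1.ctx_out.data, 4, axis=0)))
        o1 = pairwise_conv_avg_block(s1, model.params, "enc0", "none")
        o4 = pairwise_conv_avg_block(s4, model.params, "enc0", "none")
        assert np.abs(o1.target.data - o4.target.data).max() <= 1e-6

    def test_resize_modes(self):
        rng = np.random.default_rng(10)
        model = OmniNet(TINY)
        state = self._state(rng, 4, k=2)
        down = pairwise_conv_avg_block(state, model.params, "enc0", "down")
        up = pairwise_conv_avg_block(state, model.params, "enc0", "up")
        assert down.target.data.shape[-2:] == (4, 4)
        assert up.target.data.shape[-2:] == (16, 16)


class TestForward:
    def test_output_shape_contract(self):
        model = OmniNet(ModelConfig(base_channels=4, channel_multipliers=(1, 2, 2, 2), seed=0))
        rng = np.random.default_rng(0)
        out = model.forward(rng.random((64, 64)), rng.random((4, 64, 64)),
                            rng.random((4, 64, 64)))
        assert out.data.shape == (64, 64)

    def test_context_permutation_invariance_full(self):
        model = OmniNet(TINY)
        rng = np.random.default_rng(1)
        x = rng.random((32, 32))
        ci, co = rng.random((16, 32, 32)), rng.random((16, 32, 32))
        perm = rng.permutation(16)
        y1 = model.predict(x, ci, co, clip=False)
        y2 = model.predict(x, ci[perm], co[perm], clip=False)
        assert np.abs(y1 - y2).max() <= 1e-6

    def test_context_duplication_invariance_full(self):
        model = OmniNet(TINY)
        rng = np.random.default_rng(2)
        x = rng.random((32, 32))
        ci, co = rng.random((4, 32, 32)), rng.random((4, 32, 32))
        y1 = model.predict(x, ci, co, clip=False)
        y3 = model.predict(x, np.tile(ci, (3, 1, 1)), np.tile(co, (3, 1, 1)), clip=False)
        assert np.abs(y1 - y3).max() <= 1e-6

    def test_matches_step_by_step_composition(self):
        config = ModelConfig(base_channels=2, channel_multipliers=(1, 2, 2, 2),
                             seed=11, dtype="float64")
        model = OmniNet(config)
        rng = np.random.default_rng(11)
        x = rng.random((16, 16))
        ci, co = rng.random((1, 16, 16)), rng.random((1, 16, 16))

        state = FeatureState(target=model.embed(x, "target"),
                             ctx_in=model.embed(ci, "context_in"),
                             ctx_out=model.embed(co, "context_out"))
        skips = []
        for i in range(3):
            state, pre = model.run_block(state, i, return_target_preresize=True)
            skips.append(pre)
        state = model.run_block(state, 3)
        for i, lvl in zip((4, 5, 6), (2, 1, 0)):
            state = model.run_block(state, i)
            state = FeatureState(target=model.fuse_skip(state.target, skips[lvl], lvl),
                                 ctx_in=state.ctx_in, ctx_out=state.ctx_out)
        manual = model.output_conv(state.target).data.reshape(16, 16)
        assert np.abs(model.forward(x, ci, co).data - manual).max() < 1e-12

    def test_rejects_invalid_inputs(self):
        model = OmniNet(TINY)
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):  # empty context
            model.forward(rng.random((16, 16)), np.empty((0, 16, 16)), np.empty((0, 16, 16)))
        with pytest.raises(ValueError):  # dims not divisible by 8
            model.forward(rng.random((20, 20)), rng.random((1, 20, 20)), rng.random((1, 20, 20)))
        with pytest.raises(ValueError):  # context shape mismatch
            model.forward(rng.random((16, 16)), rng.random((2, 24, 24)), rng.random((2, 24, 24)))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x, ci, co = rng.random((16, 16)), rng.random((2, 16, 16)), rng.random((2, 16, 16))
        y1 = OmniNet(TINY).predict(x, ci, co)
        y2 = OmniNet(TINY).predict(x, ci, co)
        assert np.array_equal(y1, y2)


def expected_param_count(cfg: ModelConfig) -> int:
    """Closed-form parameter count, derived independently from the layout."""
    c = cfg.channels()
    k2 = cfg.kernel_size**2
    plan = [(c[0], c[0]), (c[0], c[1]), (c[1], c[2]), (c[2], c[3]),
            (c[3], c[2]), (c[2], c[1]), (c[1], c[0])]

    def ru(ci, co):
        n = co * ci * k2 + co + co * co * k2 + co
        if ci != co:
            n += co * ci + co
        return n

    total = c[0] * k2 + c[0]                      # shared embedding
    for ci, co in plan:
        total += 2 * ru(ci, co)                   # target + shared context unit
        total += co * 3 * co + co                 # pairwise 1x1
    for lvl in (2, 1, 0):                         # skip fusions
        total += c[lvl] * 2 * c[lvl] + c[lvl]
    total += c[0] + 1                             # output 1x1
    return total


class TestParameters:
    @pytest.mark.parametrize("cfg", [
        ModelConfig(base_channels=4, channel_multipliers=(1, 2, 2, 2)),
        ModelConfig(base_channels=8, channel_multipliers=(1, 2, 4, 8)),
        ModelConfig(base_channels=32),
    ])
    def test_count_matches_closed_form(self, cfg):
        assert OmniNet(cfg).n_parameters == expected_param_count(cfg)

    def test_channel_cap_at_8x_base(self):
        cfg = ModelConfig(base_channels=4, channel_multipliers=(1, 4, 8, 16))
        assert cfg.channels() == (4, 16, 32, 32)

    def test_gradient_reaches_every_weight_group(self):
        model = OmniNet(ModelConfig(base_channels=4, channel_multipliers=(1, 2, 2, 2),
                                    seed=13))
        rng = np.random.default_rng(13)
        out = model.forward(rng.random((16, 16)), rng.random((2, 16, 16)),
                            rng.random((2, 16, 16)))
        mse_loss(out, rng.random((16, 16))).backward()
        for name, p in model.params.items():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name

    def test_checkpoint_round_trip(self, tmp_path):
        model = OmniNet(TINY)
        rng = np.random.default_rng(14)
        x, ci, co = rng.random((16, 16)), rng.random((2, 16, 16)), rng.random((2, 16, 16))
        before = model.predict(x, ci, co)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        after = OmniNet.load(path).predict(x, ci, co)
        assert np.array_equal(before, after)

    def test_shared_embedding_is_role_independent(self):
        model = OmniNet(TINY)
        rng = np.random.default_rng(15)
        img = rng.random((16, 16))
        a = model.embed(img, "target").data
        b = model.embed(img, "context_out").data
        assert np.array_equal(a, b)

    def test_separate_embedding_option(self):
        cfg = ModelConfig(base_channels=4, channel_multipliers=(1, 2, 2, 2),
                          shared_embedding=False, seed=16)
        model = OmniNet(cfg)
        img = np.random.default_rng(0).random((16, 16))
        a = model.embed(img, "target").data
        b = model.embed(img, "context_in").data
        assert not np.array_equal(a, b)
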