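"""PA OmniNet: a context-conditioned U-net built from Pairwise-Conv-Avg blocks.

The network removes sparse-sampling artifacts from a target image while
being conditioned, in the same forward pass, on a *context set* of K
labeled input/output example pairs describing the degradation task.  A
shared embedding lifts the target and every context image to feature
space; seven Pairwise-Conv-Avg blocks arranged as a symmetric U (three
encoder blocks with factor-2 down-sampling, a bottleneck, three decoder
blocks with factor-2 up-sampling and skip connections on the target
stream) mix context information into the target; an output convolution
maps back to one channel.

Inside each Pairwise-Conv-Avg block:

1. the target features pass their own residual unit;
2. every context-in and context-out feature map passes a residual unit
   whose weights are shared between the in and out streams, applied
   independently per pair;
3. for each pair k the triple [target', in'_k, out'_k] is concatenated
   on channels and reduced by a 1x1 convolution to a candidate update;
4. the new target features are the *mean over pairs* of the candidates
   (hence permutation and duplication invariance over the context set);
5. the context streams continue as their residual-unit outputs;
6. all three outputs are resized (down / up / none) for the next block.

Channel widths follow standard U-net practice: ``base_channels`` at the
top level, doubling per down-resize, capped at 8x base.  Skip wiring,
resize operator, activation and embedding sharing are configurable
because the block structure itself does not constrain them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .nnet import init_conv, residual_unit, residual_unit_params

__all__ = ["ModelConfig", "FeatureState", "OmniNet", "pairwise_conv_avg_block"]

N_BLOCKS = 7  # 3 encoder + bottleneck + 3 decoder


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; fully determines all parameter shapes."""

    base_channels: int = 32
    channel_multipliers: tuple[int, int, int, int] = (1, 2, 4, 8)
    kernel_size: int = 3
    activation: str = "leaky_relu"
    shared_embedding: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")
        if len(self.channel_multipliers) != 4:
            raise ValueError("channel_multipliers must give one factor per level (4 levels)")

    def channels(self) -> tuple[int, ...]:
        """Per-level channel widths, capped at 8x base."""
        return tuple(min(self.base_channels * m, 8 * self.base_channels)
                     for m in self.channel_multipliers)

    def block_plan(self) -> list[tuple[str, int, int, str]]:
        """(name, c_in, c_out, resize) for the seven blocks in order."""
        c0, c1, c2, c3 = self.channels()
        return [
            ("enc0", c0, c0, "down"),
            ("enc1", c0, c1, "down"),
            ("enc2", c1, c2, "down"),
            ("bottleneck", c2, c3, "none"),
            ("dec0", c3, c2, "up"),
            ("dec1", c2, c1, "up"),
            ("dec2", c1, c0, "up"),
        ]


@dataclass
class FeatureState:
    """The three co-shaped streams flowing through a block."""

    target: Tensor          # (1, C, h, w)
    ctx_in: Tensor          # (K, C, h, w)
    ctx_out: Tensor         # (K, C, h, w)

    def __post_init__(self) -> None:
        st, si, so = self.target.data.shape, self.ctx_in.data.shape, self.ctx_out.data.shape
        if si != so or st[1:] != si[1:]:
            raise ValueError(f"feature streams not co-shaped: {st}, {si}, {so}")
        if si[0] < 1:
            raise ValueError("context must contain at least one pair")

    @property
    def k(self) -> int:
        return self.ctx_in.data.shape[0]


def _resize(t: Tensor, mode: str) -> Tensor:
    if mode == "down":
        return t.down2()
    if mode == "up":
        return t.up2()
    if mode == "none":
        return t
    raise ValueError(f"unknown resize mode {mode!r}")


def pairwise_conv_avg_block(
    state: FeatureState,
    params: dict[str, Tensor],
    prefix: str,
    resize: str = "none",
    activation: str = "leaky_relu",
    return_target_preresize: bool = False,
):
    """One Pairwise-Conv-Avg block (see module docstring for the steps).

    With ``return_target_preresize=True`` additionally returns the
    updated target features *before* resizing, which the full network
    uses as encoder skip features.
    """
    k = state.k
    t1 = residual_unit(state.target, params, f"{prefix}.target", activation)
    # context-in and context-out share residual-unit weights: run both
    # stacks through the same unit in one batched call
    both = concat([state.ctx_in, state.ctx_out], axis=0)
    both1 = residual_unit(both, params, f"{prefix}.context", activation)
    in1, out1 = both1[:k], both1[k:]
    cand = concat([t1.expand0(k), in1, out1], axis=1).conv2d(
        params[f"{prefix}.pair.w"], params[f"{prefix}.pair.b"])
    c = cand.data.shape[1]
    t_new = cand.mean(axis=0).reshape(1, c, *cand.data.shape[2:])
    out_state = FeatureState(
        target=_resize(t_new, resize),
        ctx_in=_resize(in1, resize),
        ctx_out=_resize(out1, resize),
    )
    if return_target_preresize:
        return out_state, t_new
    return out_state


class OmniNet:
    """The full architecture with its parameters.

    Parameters are created deterministically from ``config.seed``; the
    same config therefore always yields the same initial weights.
    """

    def __init__(self, config: ModelConfig = ModelConfig(),
                 params: dict[str, Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()

    # -- parameters ----------------------------------------------------
    def _init_params(self) -> dict[str, Tensor]:
        cfg = self.config
        dtype = np.float64 if cfg.dtype == "float64" else np.float32
        rng = np.random.default_rng(cfg.seed)
        k = cfg.kernel_size
        c0 = cfg.channels()[0]
        params: dict[str, Tensor] = {}

        roles = ["embed"] if cfg.shared_embedding else [
            "embed_target", "embed_ctx_in", "embed_ctx_out"]
        for role in roles:
            w, b = init_conv(rng, c0, 1, k, dtype)
            params[f"{role}.w"] = Tensor(w, requires_grad=True)
            params[f"{role}.b"] = Tensor(b, requires_grad=True)

        for name, c_in, c_out, _ in cfg.block_plan():
            params.update(residual_unit_params(rng, f"{name}.target", c_in, c_out, k, dtype))
            params.update(residual_unit_params(rng, f"{name}.context", c_in, c_out, k, dtype))
            w, b = init_conv(rng, c_out, 3 * c_out, 1, dtype)
            params[f"{name}.pair.w"] = Tensor(w, requires_grad=True)
            params[f"{name}.pair.b"] = Tensor(b, requires_grad=True)

        # skip fusions on the target stream after each decoder up-resize
        for lvl, c in zip((2, 1, 0), cfg.channels()[2::-1]):
            w, b = init_conv(rng, c, 2 * c, 1, dtype)
            params[f"fuse{lvl}.w"] = Tensor(w, requires_grad=True)
            params[f"fuse{lvl}.b"] = Tensor(b, requires_grad=True)

        # near-zero output head: the first forward passes then start close
        # to a zero image instead of an amplified random one, which keeps
        # early losses and Adam moments sane while preserving gradient flow
        w, b = init_conv(rng, 1, c0, 1, dtype)
        params["out.w"] = Tensor(0.01 * w, requires_grad=True)
        params["out.b"] = Tensor(b, requires_grad=True)
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward pieces ------------------------------------------------
    def embed(self, image: Tensor | np.ndarray, role: str = "target") -> Tensor:
        """Shared (or per-role) convolutional embedding of a 1-channel image.

        Accepts (H, W), (N, H, W) or (N, 1, H, W) input.
        """
        t = image if isinstance(image, Tensor) else Tensor(np.asarray(image))
        if t.data.ndim == 2:
            t = t.reshape(1, 1, *t.data.shape)
        elif t.data.ndim == 3:
            t = t.reshape(t.data.shape[0], 1, *t.data.shape[1:])
        if t.data.ndim != 4 or t.data.shape[1] != 1:
            raise ValueError(f"embedding expects single-channel input, got {t.data.shape}")
        if role not in ("target", "context_in", "context_out"):
            raise ValueError(f"unknown embedding role {role!r}")
        if self.config.shared_embedding:
            key = "embed"
        else:
            key = {"target": "embed_target", "context_in": "embed_ctx_in",
                   "context_out": "embed_ctx_out"}[role]
        return t.conv2d(self.params[f"{key}.w"], self.params[f"{key}.b"])

    def run_block(self, state: FeatureState, index: int,
                  return_target_preresize: bool = False):
        name, _, _, resize = self.config.block_plan()[index]
        return pairwise_conv_avg_block(state, self.params, name, resize,
                                       self.config.activation,
                                       return_target_preresize)

    def fuse_skip(self, target: Tensor, skip: Tensor, level: int) -> Tensor:
        return concat([target, skip], axis=1).conv2d(
            self.params[f"fuse{level}.w"], self.params[f"fuse{level}.b"])

    def output_conv(self, target: Tensor) -> Tensor:
        return target.conv2d(self.params["out.w"], self.params["out.b"])

    # -- full forward --------------------------------------------------
    def forward(self, x: np.ndarray | Tensor,
                ctx_in: np.ndarray, ctx_out: np.ndarray) -> Tensor:
        """One conditioned forward pass.

        Parameters
        ----------
        x : (H, W) target image.
        ctx_in, ctx_out : (K, H, W) stacked context input / output images.

        Returns the (H, W) reconstruction as a graph Tensor (call
        ``.data`` for the array, or build a loss on it and backprop).
        """
        xd = x.data if isinstance(x, Tensor) else np.asarray(x)
        ci, co = np.asarray(ctx_in), np.asarray(ctx_out)
        if ci.ndim != 3 or ci.shape != co.shape:
            raise ValueError("context stacks must be (K, H, W) and co-shaped")
        if ci.shape[0] < 1:
            raise ValueError("context set must be nonempty")
        h, w = xd.shape[-2:]
        if ci.shape[1:] != (h, w):
            raise ValueError("context images must be co-shaped with the target")
        if h % 8 or w % 8:
            raise ValueError(f"spatial dims must be divisible by 8, got {h}x{w}")

        state = FeatureState(
            target=self.embed(x, "target"),
            ctx_in=self.embed(ci, "context_in"),
            ctx_out=self.embed(co, "context_out"),
        )
        skips: list[Tensor] = []
        for i in range(3):
            state, pre = self.run_block(state, i, return_target_preresize=True)
            skips.append(pre)
        state = self.run_block(state, 3)  # bottleneck
        for i, lvl in zip((4, 5, 6), (2, 1, 0)):
            state = self.run_block(state, i)
            state = FeatureState(
                target=self.fuse_skip(state.target, skips[lvl], lvl),
                ctx_in=state.ctx_in, ctx_out=state.ctx_out,
            )
        out = self.output_conv(state.target)
        return out.reshape(h, w)

    def predict(self, x: np.ndarray, ctx_in: np.ndarray, ctx_out: np.ndarray,
                clip: bool = True) -> np.ndarray:
        """Forward pass returning a plain array, optionally clipped to [0, 1]."""
        y = self.forward(x, ctx_in, ctx_out).data
        return np.clip(y, 0.0, 1.0) if clip else y

    # -- checkpoints ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(path, __config__=np.bytes_(json.dumps(asdict(self.config))), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "OmniNet":
        with np.load(path) as f:
            cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in json.loads(bytes(f["__config__"]).decode()).items()})
            model = cls(cfg)
            for name, p in model.params.items():
                arr = f[name]
                if arr.shape != p.data.shape:
                    raise ValueError(f"checkpoint shape mismatch for {name}: "
                                     f"{arr.shape} vs {p.data.shape}")
                p.data = arr
        return model
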