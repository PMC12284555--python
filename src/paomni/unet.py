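"""Baseline encoder-decoder U-net for sparse-sampling artifact removal.

A conventional U-net benchmark: per level two 3x3 convolutions with ELU
activations, factor-2 box down-sampling in the encoder, bilinear
up-sampling plus skip concatenation in the decoder, and a final 1x1
convolution to one channel.  It is trained under the exact same harness
and losses as PA OmniNet but takes no context set, so any performance
gap isolates the effect of context conditioning.

The scaled-RMSE (SRMSE) loss offered for this model multiplies both
images by a constant intensity scale before the RMSE, equivalently
``scale * RMSE(pred, target)``; with images in [0, 1] a scale of 255
keeps gradients of faint structures away from underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .nnet import apply_activation, init_conv

__all__ = ["UnetConfig", "BaselineUNet", "srmse_loss_value"]


@dataclass(frozen=True)
class UnetConfig:
    depth: int = 4
    base_channels: int = 32
    activation: str = "elu"
    srmse_scale: float | None = None
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")
        if self.srmse_scale is not None and self.srmse_scale <= 0:
            raise ValueError("srmse_scale must be positive")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2**i, 8 * self.base_channels)
                for i in range(self.depth)]


class BaselineUNet:
    """Standard U-net; same parameter-dict/checkpoint conventions as OmniNet."""

    def __init__(self, config: UnetConfig = UnetConfig(),
                 params: dict[str, Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()

    def _init_params(self) -> dict[str, Tensor]:
        cfg = self.config
        dtype = np.float64 if cfg.dtype == "float64" else np.float32
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels()
        params: dict[str, Tensor] = {}

        def add(name, co, ci, k):
            w, b = init_conv(rng, co, ci, k, dtype)
            params[f"{name}.w"] = Tensor(w, requires_grad=True)
            params[f"{name}.b"] = Tensor(b, requires_grad=True)

        c_prev = 1
        for i, c in enumerate(ch):  # encoder (deepest level is the bridge)
            add(f"enc{i}.conv1", c, c_prev, 3)
            add(f"enc{i}.conv2", c, c, 3)
            c_prev = c
        for i in range(cfg.depth - 2, -1, -1):  # decoder
            c, c_below = ch[i], ch[i + 1]
            add(f"dec{i}.conv1", c, c_below + c, 3)
            add(f"dec{i}.conv2", c, c, 3)
        add("out", 1, ch[0], 1)
        params["out.w"].data *= 0.01  # near-zero output head (see OmniNet)
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def _double_conv(self, x: Tensor, name: str) -> Tensor:
        act = self.config.activation
        x = apply_activation(x.conv2d(self.params[f"{name}.conv1.w"],
                                      self.params[f"{name}.conv1.b"]), act)
        return apply_activation(x.conv2d(self.params[f"{name}.conv2.w"],
                                         self.params[f"{name}.conv2.b"]), act)

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """(H, W) -> (H, W); H, W must be divisible by 2**(depth-1)."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        if t.data.ndim != 2:
            raise ValueError("expected a single 2-D image")
        h, w = t.data.shape
        div = 2 ** (self.config.depth - 1)
        if h % div or w % div:
            raise ValueError(f"spatial dims must be divisible by {div}, got {h}x{w}")
        t = t.reshape(1, 1, h, w)

        skips = []
        for i in range(self.config.depth - 1):
            t = self._double_conv(t, f"enc{i}")
            skips.append(t)
            t = t.down2()
        t = self._double_conv(t, f"enc{self.config.depth - 1}")
        for i in range(self.config.depth - 2, -1, -1):
            t = concat([t.up2(), skips[i]], axis=1)
            t = self._double_conv(t, f"dec{i}")
        out = t.conv2d(self.params["out.w"], self.params["out.b"])
        return out.reshape(h, w)

    def predict(self, x: np.ndarray, clip: bool = True) -> np.ndarray:
        y = self.forward(x).data
        return np.clip(y, 0.0, 1.0) if clip else y

    def save(self, path: str | Path) -> None:
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(path, __config__=np.bytes_(json.dumps(asdict(self.config))), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BaselineUNet":
        with np.load(path) as f:
            cfg = UnetConfig(**json.loads(bytes(f["__config__"]).decode()))
            model = cls(cfg)
            for name, p in model.params.items():
                arr = f[name]
                if arr.shape != p.data.shape:
                    raise ValueError(f"checkpoint shape mismatch for {name}")
                p.data = arr
        return model


def srmse_loss_value(pred: np.ndarray, target: np.ndarray, scale: float = 255.0) -> float:
    """Scaled RMSE on plain arrays: RMSE(scale*pred, scale*target)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    p, t = np.asarray(pred, dtype=np.float64), np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    return float(scale * np.sqrt(np.mean((p - t) ** 2)))
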