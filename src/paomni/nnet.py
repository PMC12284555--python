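"""Shared neural-network building blocks: parameters, residual units, Adam.

Parameters live in a flat ``dict[str, Tensor]`` per model, so checkpoints
are a name -> array mapping and weight sharing is explicit (two streams
that share weights simply read the same dict entries).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["init_conv", "apply_activation", "residual_unit", "residual_unit_params", "Adam"]


def init_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int,
              dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
    """He-normal weight and zero bias for a conv layer."""
    fan_in = c_in * k * k
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(dtype)
    b = np.zeros(c_out, dtype=dtype)
    return w, b


def apply_activation(x: Tensor, name: str) -> Tensor:
    if name == "leaky_relu":
        return x.leaky_relu(0.01)
    if name == "elu":
        return x.elu()
    if name == "none":
        return x
    raise ValueError(f"unknown activation {name!r}")


def residual_unit_params(rng: np.random.Generator, prefix: str, c_in: int, c_out: int,
                         k: int = 3, dtype=np.float32) -> dict[str, Tensor]:
    """Parameters for one residual unit (two convs + optional projection)."""
    params: dict[str, Tensor] = {}
    for name, (co, ci, kk) in {
        "conv1": (c_out, c_in, k), "conv2": (c_out, c_out, k),
    }.items():
        w, b = init_conv(rng, co, ci, kk, dtype)
        params[f"{prefix}.{name}.w"] = Tensor(w, requires_grad=True)
        params[f"{prefix}.{name}.b"] = Tensor(b, requires_grad=True)
    if c_in != c_out:
        w, b = init_conv(rng, c_out, c_in, 1, dtype)
        params[f"{prefix}.proj.w"] = Tensor(w, requires_grad=True)
        params[f"{prefix}.proj.b"] = Tensor(b, requires_grad=True)
    return params


def residual_unit(x: Tensor, params: dict[str, Tensor], prefix: str,
                  activation: str = "leaky_relu") -> Tensor:
    """x + conv2(act(conv1(x))), with a 1x1 projection shortcut when the
    channel count changes."""
    h = x.conv2d(params[f"{prefix}.conv1.w"], params[f"{prefix}.conv1.b"])
    h = apply_activation(h, activation)
    h = h.conv2d(params[f"{prefix}.conv2.w"], params[f"{prefix}.conv2.b"])
    if f"{prefix}.proj.w" in params:
        shortcut = x.conv2d(params[f"{prefix}.proj.w"], params[f"{prefix}.proj.b"])
    else:
        shortcut = x
    return shortcut + h


class Adam:
    """Adam optimizer over a flat parameter dict (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data = p.data - lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
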