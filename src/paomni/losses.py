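"""Differentiable training losses built on the autodiff graph.

The numeric conventions deliberately match :mod:`paomni.metrics`: the
SSIM term uses the same 11-tap Gaussian window (sigma 1.5), stabilizers
and valid-region averaging, so a loss value printed during training is
directly comparable with the evaluation metric.

The Alpha loss is the convex mixture

    L = (1 - a) * MSE + a * (1 - SSIM),        a = 0.84 by default,

i.e. the mean-squared error blended with structural *dissimilarity*;
minimizing the literal +SSIM mixture would reward dissimilar outputs,
so the dissimilarity convention is the trainable form (the literal one
remains available in :func:`paomni.metrics.alpha_loss` for audit).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .metrics import AlphaParams, SSIMParams

__all__ = ["mse_loss", "ssim_loss", "alpha_loss", "srmse_loss", "make_loss"]


def _pair(pred: Tensor, target: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target))
    if pred.data.shape != t.data.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {t.data.shape}")
    return pred, t


def mse_loss(pred: Tensor, target) -> Tensor:
    pred, t = _pair(pred, target)
    return ((pred - t) ** 2).mean()


def srmse_loss(pred: Tensor, target, scale: float = 255.0) -> Tensor:
    """scale * RMSE(pred, target); the constant scale keeps gradients of
    low-magnitude structures well above float underflow."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    pred, t = _pair(pred, target)
    return (mse_loss(pred, t) + 1e-12) ** 0.5 * scale


def ssim_loss(pred: Tensor, target, params: SSIMParams = SSIMParams()) -> Tensor:
    """Differentiable 1 - SSIM (valid-window mean), for 2-D images."""
    pred, t = _pair(pred, target)
    if pred.data.ndim != 2:
        raise ValueError("ssim_loss expects 2-D images")
    h, w = pred.data.shape
    win = params.window_size
    if min(h, w) < win:
        raise ValueError(f"image {pred.data.shape} smaller than SSIM window {win}")
    kern = Tensor(params.kernel().astype(pred.data.dtype).reshape(1, 1, win, win))
    pad = (win - 1) // 2
    sl = (slice(None), slice(None), slice(pad, h - pad), slice(pad, w - pad))

    def f(a: Tensor) -> Tensor:
        return a.conv2d(kern)[sl]

    x = pred.reshape(1, 1, h, w)
    y = t.reshape(1, 1, h, w)
    mu_x, mu_y = f(x), f(y)
    var_x = f(x * x) - mu_x * mu_x
    var_y = f(y * y) - mu_y * mu_y
    cov = f(x * y) - mu_x * mu_y
    c1 = (params.k1 * params.data_range) ** 2
    c2 = (params.k2 * params.data_range) ** 2
    s = ((mu_x * mu_y * 2.0 + c1) * (cov * 2.0 + c2)) / (
        (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2))
    return 1.0 - s.mean()


def alpha_loss(pred: Tensor, target, params: AlphaParams = AlphaParams(),
               ssim_params: SSIMParams = SSIMParams()) -> Tensor:
    a = params.alpha
    return mse_loss(pred, target) * (1.0 - a) + ssim_loss(pred, target, ssim_params) * a


def make_loss(name: str, alpha: float = 0.84, srmse_scale: float = 255.0,
              ssim_params: SSIMParams = SSIMParams()):
    """Loss factory: ``mse``, ``ssim``, ``alpha`` or ``srmse`` -> callable."""
    if name == "mse":
        return mse_loss
    if name == "ssim":
        return lambda p, t: ssim_loss(p, t, ssim_params)
    if name == "alpha":
        ap = AlphaParams(alpha=alpha)
        return lambda p, t: alpha_loss(p, t, ap, ssim_params)
    if name == "srmse":
        return lambda p, t: srmse_loss(p, t, srmse_scale)
    raise ValueError(f"unknown loss {name!r}; expected mse, ssim, alpha or srmse")
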