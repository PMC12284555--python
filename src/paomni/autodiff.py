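"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the networks in this package need are provided:
elementwise arithmetic, 2-D convolution (stride 1, zero same-padding),
factor-2 box down-sampling and bilinear up-sampling, channel
concatenation, reductions, slicing and the LeakyReLU / ELU activations.
Graphs are built eagerly; :meth:`Tensor.backward` runs a topological
sweep accumulating gradients into every ``requires_grad`` leaf.

Feature maps follow the (N, C, H, W) layout throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: list[tuple["Tensor", object]] = []

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents):
        out = Tensor(data)
        live = [(p, fn) for p, fn in parents if p.requires_grad]
        if live:
            out.requires_grad = True
            out._parents = live
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p, _ in node._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in node._parents:
                pg = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                elif parent._parents:
                    grads[id(parent)] = pg
                else:
                    parent.grad = pg if parent.grad is None else parent.grad + pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        o = self._wrap(other)
        return Tensor._make(self.data + o.data, [
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (o, lambda g: _unbroadcast(g, o.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        return Tensor._make(self.data * o.data, [
            (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
            (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        return Tensor._make(self.data / o.data, [
            (self, lambda g: _unbroadcast(g / o.data, self.data.shape)),
            (o, lambda g: _unbroadcast(-g * self.data / (o.data**2), o.data.shape)),
        ])

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        return Tensor._make(self.data**p, [
            (self, lambda g: g * p * self.data ** (p - 1)),
        ])

    def __getitem__(self, idx):
        def back(g):
            out = np.zeros_like(self.data)
            out[idx] = g
            return out
        return Tensor._make(self.data[idx], [(self, back)])

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(self.data.reshape(*shape), [
            (self, lambda g: g.reshape(old)),
        ])

    def expand0(self, k: int):
        """Broadcast a leading axis of size 1 to size ``k``."""
        if self.data.shape[0] != 1:
            raise ValueError("expand0 requires leading axis of size 1")
        out = np.broadcast_to(self.data, (k,) + self.data.shape[1:]).copy()
        return Tensor._make(out, [
            (self, lambda g: g.sum(axis=0, keepdims=True)),
        ])

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None):
        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            return np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy()
        return Tensor._make(self.data.sum(axis=axis), [(self, back)])

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- activations ---------------------------------------------------
    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, slope * self.data), [
            (self, lambda g: g * np.where(mask, 1.0, slope).astype(g.dtype)),
        ])

    def elu(self, alpha: float = 1.0):
        mask = self.data > 0
        ex = np.exp(np.minimum(self.data, 0.0))
        out = np.where(mask, self.data, alpha * (ex - 1.0))
        return Tensor._make(out, [
            (self, lambda g: g * np.where(mask, 1.0, alpha * ex).astype(g.dtype)),
        ])

    # -- convolution ---------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Stride-1, zero same-padded 2-D convolution (cross-correlation).

        self: (N, C, H, W); weight: (O, C, k, k) with odd k; bias: (O,).
        """
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, c2, k, k2 = w.shape
        if c != c2 or k != k2 or k % 2 == 0:
            raise ValueError(f"conv shapes incompatible: x{x.shape} w{w.shape}")
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # cols: (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * k * k)
        wm = w.reshape(o, c * k * k)
        out = cols2 @ wm.T
        if bias is not None:
            out = out + bias.data[None, :]
        out = out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)

        def back_x(g):
            # adjoint of same-padded correlation: same-padded correlation of
            # the upstream grad with the spatially flipped, channel-swapped kernel
            wt = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, o * k * k)
            gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else g
            gcols = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
            gcols2 = gcols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, o * k * k)
            return (gcols2 @ wt.T).reshape(n, h, wd, c).transpose(0, 3, 1, 2)

        def back_w(g):
            gm = g.transpose(0, 2, 3, 1).reshape(n * h * wd, o)
            return (gm.T @ cols2).reshape(w.shape)

        parents = [(self, back_x), (weight, back_w)]
        if bias is not None:
            parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
        return Tensor._make(out, parents)

    # -- resizing ------------------------------------------------------
    def down2(self):
        """Factor-2 box down-sampling (2x2 average pool) on H, W."""
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError(f"down2 requires even spatial dims, got {h}x{w}")
        out = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def back(g):
            return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        return Tensor._make(out, [(self, back)])

    def up2(self):
        """Factor-2 bilinear up-sampling (half-pixel centers) on H, W."""
        n, c, h, w = self.data.shape
        (i0h, i1h, wh), (i0w, i1w, ww) = _up2_index(h), _up2_index(w)
        a = self.data[:, :, i0h, :] * (1 - wh)[None, None, :, None] \
            + self.data[:, :, i1h, :] * wh[None, None, :, None]
        out = a[:, :, :, i0w] * (1 - ww)[None, None, None, :] \
            + a[:, :, :, i1w] * ww[None, None, None, :]

        def back(g):
            da = np.zeros((n, c, 2 * h, w), dtype=g.dtype)
            np.add.at(da, (slice(None), slice(None), slice(None), i0w),
                      g * (1 - ww)[None, None, None, :])
            np.add.at(da, (slice(None), slice(None), slice(None), i1w),
                      g * ww[None, None, None, :])
            dx = np.zeros((n, c, h, w), dtype=g.dtype)
            np.add.at(dx, (slice(None), slice(None), i0h),
                      da * (1 - wh)[None, None, :, None])
            np.add.at(dx, (slice(None), slice(None), i1h),
                      da * wh[None, None, :, None])
            return dx
        return Tensor._make(out, [(self, back)])


def _up2_index(n: int):
    """Gather indices and fractional weights for 2x bilinear upsampling."""
    s = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(s), 0, n - 1).astype(np.int64)
    i1 = np.clip(i0 + 1, 0, n - 1)
    w = np.clip(s - np.floor(s), 0.0, 1.0)
    w[s < 0] = 0.0
    w[s > n - 1] = 0.0
    return i0, i1, w


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_back(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor._make(out, [(t, make_back(i)) for i, t in enumerate(tensors)])


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)

    def make_back(i):
        return lambda g: np.take(g, i, axis=axis)

    return Tensor._make(out, [(t, make_back(i)) for i, t in enumerate(tensors)])
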