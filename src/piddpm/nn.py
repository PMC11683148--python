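"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the epsilon-prediction network needs:
broadcast arithmetic, reductions, SiLU, 2-D convolution (im2col), 2x average
pooling, 2x bilinear upsampling, channel concatenation, dense layers, and an
Adam optimiser.  Gradients are accumulated through a topologically sorted
backward pass; a module-level ``no_grad`` context disables graph construction
for inference.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "no_grad", "concat", "conv2d", "avg_pool2x",
           "upsample_bilinear2x", "Adam"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node: Tensor):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        grad = grad.astype(self.data.dtype, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- ops ---------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def pow(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def reciprocal(self):
        return self.pow(-1.0)

    def __truediv__(self, other):
        return self * self._wrap(other).reciprocal()

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """Same-size 2-D convolution (cross-correlation), zero padding.

    x: (B, C, H, W); w: (O, C, kh, kw); b: (O,).
    """
    B, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    assert C == C2, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
    out_data = np.tensordot(cols, w.data, axes=([1, 4, 5], [1, 2, 3]))  # B,H,W,O
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        # g: (B, O, H, W)
        if w.requires_grad:
            gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 2, 3]))  # O,C,kh,kw
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation of g with the flipped, channel-swapped kernel
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1 - pad, kh - 1 - pad),
                            (kw - 1 - pad, kw - 1 - pad)))
            gcols = sliding_window_view(gp, (kh, kw), axis=(2, 3))  # B,O,H,W,kh,kw
            w_rot = w.data[:, :, ::-1, ::-1]  # O,C,kh,kw flipped
            gx = np.tensordot(gcols, w_rot, axes=([1, 4, 5], [0, 2, 3]))  # B,H,W,C
            x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def avg_pool2x(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    out_data = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def _bilinear_weights(n_out: int, n_in: int):
    c = np.clip((np.arange(n_out) + 0.5) / (n_out / n_in) - 0.5, 0, n_in - 1)
    i0 = np.floor(c).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = c - i0
    return i0, i1, f


def upsample_bilinear2x(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    iy0, iy1, fy = _bilinear_weights(2 * H, H)
    ix0, ix1, fx = _bilinear_weights(2 * W, W)
    fy = fy[:, None]
    fx = fx[None, :]
    d = x.data
    out_data = ((1 - fy) * (1 - fx) * d[:, :, iy0[:, None], ix0[None, :]]
                + (1 - fy) * fx * d[:, :, iy0[:, None], ix1[None, :]]
                + fy * (1 - fx) * d[:, :, iy1[:, None], ix0[None, :]]
                + fy * fx * d[:, :, iy1[:, None], ix1[None, :]])

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for iy, wy in ((iy0, 1 - fy), (iy1, fy)):
            for ix, wx in ((ix0, 1 - fx), (ix1, fx)):
                np.add.at(gx, (slice(None), slice(None), iy[:, None], ix[None, :]),
                          g * (wy * wx))
        x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


class Adam:
    """Adam optimiser over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
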