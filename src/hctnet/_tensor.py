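"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine provides exactly the operations the network needs: broadcasting
arithmetic, batched matmul, stride-1 same-padded convolution (im2col),
2x2 max pooling, leaky ReLU, exact GELU, layer normalization, softmax and
reductions.  All arrays are float32; gradients are accumulated into
``Tensor.grad`` by :func:`backward`, which walks a topological order of the
recorded graph.  Gradient correctness is established against central finite
differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=DTYPE)


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None, free: bool = True) -> None:
        """Accumulate gradients of this (scalar or tensor) node into the graph.

        With ``free`` (the default) the recorded graph is dismantled after the
        pass: intermediate nodes drop their parent links, closures and grads,
        so their (large) buffers are reclaimed immediately by reference
        counting instead of waiting for the cycle collector.  Pass
        ``free=False`` to keep the graph (e.g. to call backward twice).
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        if free:
            for node in topo:
                if node._backward is not None:  # intermediate, not a leaf
                    node._backward = None
                    node._parents = ()
                    node.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if not (self.requires_grad or self._backward is not None):
            return
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._backward is not None for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# -- elementwise --------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _node(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    data = a.data ** exponent

    def backward(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _node(data, (a,), backward)


def log(a: Tensor, floor: float = 0.0) -> Tensor:
    clamped = np.maximum(a.data, floor) if floor > 0 else a.data
    data = np.log(clamped)

    def backward(g):
        a._accumulate(g / np.maximum(a.data, floor if floor > 0 else 1e-30))

    return _node(data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _node(data, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    pos = a.data > 0
    data = np.where(pos, a.data, slope * a.data)

    def backward(g):
        a._accumulate(g * np.where(pos, 1.0, slope).astype(DTYPE))

    return _node(data, (a,), backward)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = a.data
    cdf = (0.5 * (1.0 + erf(x * DTYPE(1.0 / _SQRT2)))).astype(DTYPE)
    data = x * cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        a._accumulate(g * (cdf + x * pdf))

    return _node(data, (a,), backward)


# -- shape manipulation --------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _node(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    inv = np.argsort(axes)
    data = a.data.transpose(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _node(data, (a,), backward)


def getitem(a: Tensor, idx) -> Tensor:
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _node(data, (a,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(data, tuple(tensors), backward)


# -- reductions ----------------------------------------------------------------

def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(DTYPE))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).astype(DTYPE))

    return _node(data, (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis, keepdims), _wrap(1.0 / n))


# -- linear algebra -------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _node(data, (a, b), backward)


# -- fused network primitives ----------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation); weight (Cout, Cin, kh, kw).

    Evaluated as a sum of kh*kw channel-mixing matmuls over shifted views,
    which avoids materializing the full im2col matrix (the memory traffic,
    not the arithmetic, dominates on large feature maps).
    """
    cout, cin, kh, kw = weight.shape
    b, c, h, w = x.shape
    if c != cin:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {cin}")
    if padding:
        xp = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=DTYPE)
        xp[:, :, padding : padding + h, padding : padding + w] = x.data
    else:
        xp = x.data
    oh, ow = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1

    def shifted(src, i, j):
        return np.ascontiguousarray(src[:, :, i : i + oh, j : j + ow]).reshape(
            b, -1, oh * ow
        )

    out = np.zeros((b, cout, oh * ow), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            out += np.matmul(weight.data[None, :, :, i, j], shifted(xp, i, j))
    if bias is not None:
        out += bias.data[None, :, None]
    data = out.reshape(b, cout, oh, ow)

    def backward(g):
        gm = g.reshape(b, cout, oh * ow)
        if bias is not None:
            bias._accumulate(gm.sum(axis=(0, 2)))
        gw = np.empty_like(weight.data)
        gxp = np.zeros_like(xp)
        gmt = np.ascontiguousarray(gm.transpose(0, 2, 1))  # (B, P, Cout)
        for i in range(kh):
            for j in range(kw):
                xs = shifted(xp, i, j)
                gw[:, :, i, j] = np.matmul(xs, gmt).sum(axis=0).T
                gxp[:, :, i : i + oh, j : j + ow] += np.matmul(
                    weight.data[None, :, :, i, j].transpose(0, 2, 1), gm
                ).reshape(b, cin, oh, ow)
        weight._accumulate(gw)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(data, parents, backward)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; ties resolve to the first element."""
    b, c, h, w = x.shape
    if h % size or w % size:
        raise ValueError(f"maxpool2d: spatial dims ({h},{w}) not divisible by {size}")
    oh, ow = h // size, w // size
    win = x.data.reshape(b, c, oh, size, ow, size).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(b, c, oh, ow, size * size)
    arg = win.argmax(axis=-1)
    data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros((b, c, oh, ow, size * size), dtype=DTYPE)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
        gx = (
            gwin.reshape(b, c, oh, ow, size, size)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )
        x._accumulate(gx)

    return _node(data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis; zero vectors map to zero (eps floor)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    data = xhat * gamma.data + beta.data
    n = x.shape[-1]

    def backward(g):
        gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        beta._accumulate(_unbroadcast(g, beta.shape))
        gx_hat = g * gamma.data
        gx = (
            gx_hat
            - gx_hat.mean(axis=-1, keepdims=True)
            - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        x._accumulate(gx.astype(DTYPE))

    return _node(data, (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized softmax (row max subtracted before exponentiation)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        x._accumulate(data * (g - dot))

    return _node(data, (x,), backward)


def grad_check(fn, tensors: list[Tensor], eps: float = 1e-3) -> float:
    """Max relative error between analytic and central-difference gradients.

    Used by the test suite; runs ``fn`` (mapping tensors to a scalar Tensor)
    repeatedly with perturbed float64 copies of each input.
    """
    for t in tensors:
        t.grad = None
    out = fn()
    out.backward()
    worst = 0.0
    for t in tensors:
        analytic = t.grad if t.grad is not None else np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn().data)
            flat[i] = orig - eps
            lo = float(fn().data)
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            ana = float(analytic.reshape(-1)[i])
            scale = max(1.0, abs(num), abs(ana))
            worst = max(worst, abs(num - ana) / scale)
    return worst
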