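"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core the segmentation backbones and losses are built
on: a :class:`Tensor` wrapping an ``ndarray``, a small set of differentiable
operations (elementwise arithmetic, reductions, 3D convolution, pooling,
upsampling, softmax), and a momentum-SGD optimizer.  The operation set is
deliberately tiny — exactly what an encoder–decoder segmentation network and
its losses need — and every gradient is validated against central finite
differences in the test suite.

Conventions
-----------
* Volumetric feature maps are ``(N, C, D, H, W)``.
* Gradients accumulate into ``Tensor.grad`` as plain ndarrays.
* ``detach()`` cuts the graph; pseudo-labels in co-training rely on it.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numba
import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv3d",
    "avg_pool3d",
    "instance_norm",
    "upsample_nearest3d",
    "leaky_relu",
    "softmax",
    "clip_min",
    "SGD",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
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
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operator
    # instead of numpy trying to iterate the Tensor into an object array
    __array_ufunc__ = None

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, out_req, (self, other), bwd if out_req else None)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, self.requires_grad, (self,), bwd if self.requires_grad else None)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, out_req, (self, other), bwd if out_req else None)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor(self.data / other.data, out_req, (self, other), bwd if out_req else None)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(
            self.data**exponent, self.requires_grad, (self,), bwd if self.requires_grad else None
        )

    # -- transcendental --------------------------------------------------
    def log(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(
            np.log(self.data), self.requires_grad, (self,), bwd if self.requires_grad else None
        )

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, self.requires_grad, (self,), bwd if self.requires_grad else None)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            self.requires_grad,
            (self,),
            bwd if self.requires_grad else None,
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor(
            self.data.reshape(*shape), self.requires_grad, (self,), bwd if self.requires_grad else None
        )

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] += g  # basic indexing only (no duplicate positions)
            self._accumulate(full)

        return Tensor(
            self.data[idx], self.requires_grad, (self,), bwd if self.requires_grad else None
        )


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (channel axis by default)."""
    tensors = [as_tensor(t) for t in tensors]
    out_req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        out_req,
        tuple(tensors),
        bwd if out_req else None,
    )


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); gradient passes only where x > lo."""
    x = as_tensor(x)
    mask = x.data > lo

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(
        np.maximum(x.data, lo), x.requires_grad, (x,), bwd if x.requires_grad else None
    )


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    x = as_tensor(x)
    pos = x.data > 0
    scale = np.where(pos, 1.0, negative_slope).astype(x.data.dtype)

    def bwd(g):
        x._accumulate(g * scale)

    return Tensor(x.data * scale, x.requires_grad, (x,), bwd if x.requires_grad else None)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax with the closed-form Jacobian product."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor(s, x.requires_grad, (x,), bwd if x.requires_grad else None)


# -- spatial ops ---------------------------------------------------------


@numba.njit(cache=True, fastmath=True)
def _corr3d_nb(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cross-correlate padded (N,C,Dp,Hp,Wp) with (O,C,k,k,k), stride 1.

    Row-major accumulation with a stride-1 innermost loop (vectorizable);
    no im2col buffer is materialized.
    """
    n_b, c_in, dp, hp, wp = xp.shape
    c_out, _, k, _, _ = w.shape
    d, h, wd = dp - k + 1, hp - k + 1, wp - k + 1
    out = np.zeros((n_b, c_out, d, h, wd), dtype=xp.dtype)
    for n in range(n_b):
        for o in range(c_out):
            for z in range(d):
                for y in range(h):
                    orow = out[n, o, z, y]
                    for c in range(c_in):
                        for a in range(k):
                            for b in range(k):
                                xrow = xp[n, c, z + a, y + b]
                                if k == 3:  # one fused pass over the row
                                    w0 = w[o, c, a, b, 0]
                                    w1 = w[o, c, a, b, 1]
                                    w2 = w[o, c, a, b, 2]
                                    for xx in range(wd):
                                        orow[xx] += (
                                            w0 * xrow[xx]
                                            + w1 * xrow[xx + 1]
                                            + w2 * xrow[xx + 2]
                                        )
                                else:
                                    for e in range(k):
                                        we = w[o, c, a, b, e]
                                        for xx in range(wd):
                                            orow[xx] += we * xrow[xx + e]
    return out


@numba.njit(cache=True, fastmath=True)
def _corr3d_dw_nb(xp: np.ndarray, g: np.ndarray, k: int) -> np.ndarray:
    """Weight gradient: gW[o,c,off] = sum_n,v g[n,o,v] * xp[n,c,v+off]."""
    n_b, c_in = xp.shape[0], xp.shape[1]
    c_out, d, h, wd = g.shape[1], g.shape[2], g.shape[3], g.shape[4]
    gw = np.zeros((c_out, c_in, k, k, k), dtype=xp.dtype)
    for n in range(n_b):
        for o in range(c_out):
            for c in range(c_in):
                for z in range(d):
                    for y in range(h):
                        grow = g[n, o, z, y]
                        for a in range(k):
                            for b in range(k):
                                xrow = xp[n, c, z + a, y + b]
                                if k == 3:  # fused triple dot product
                                    a0 = 0.0
                                    a1 = 0.0
                                    a2 = 0.0
                                    for xx in range(wd):
                                        gv = grow[xx]
                                        a0 += gv * xrow[xx]
                                        a1 += gv * xrow[xx + 1]
                                        a2 += gv * xrow[xx + 2]
                                    gw[o, c, a, b, 0] += a0
                                    gw[o, c, a, b, 1] += a1
                                    gw[o, c, a, b, 2] += a2
                                else:
                                    for e in range(k):
                                        acc = 0.0
                                        for xx in range(wd):
                                            acc += grow[xx] * xrow[xx + e]
                                        gw[o, c, a, b, e] += acc
    return gw


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return np.ascontiguousarray(x)
    return np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """3D convolution (cross-correlation), stride 1, odd kernel, 'same' padding."""
    x, weight = as_tensor(x), as_tensor(weight)
    k = weight.data.shape[2]
    pad = k // 2
    xp = _pad_spatial(x.data, pad)
    out_data = _corr3d_nb(xp, weight.data)
    if bias is not None:
        out_data += bias.data[None, :, None, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out_req = any(p.requires_grad for p in parents)

    def bwd(g):
        g = np.ascontiguousarray(g, dtype=x.data.dtype)
        if weight.requires_grad:
            weight._accumulate(_corr3d_dw_nb(xp, g, k))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            # dL/dx = full correlation of g with the spatially flipped,
            # channel-transposed kernel
            w_rot = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            x._accumulate(_corr3d_nb(_pad_spatial(g, pad), w_rot))

    return Tensor(out_data, out_req, parents, bwd if out_req else None)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes.

    Fused forward/backward (one op instead of a long chain of elementwise
    nodes); gamma/beta are (1, C, 1, 1, 1) scale and shift parameters.
    """
    x = as_tensor(x)
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_sigma = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv_sigma
    out_data = gamma.data * y + beta.data
    parents = (x, gamma, beta)
    out_req = any(p.requires_grad for p in parents)

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3, 4), keepdims=True)[0:1])
        if gamma.requires_grad:
            gamma._accumulate((g * y).sum(axis=(0, 2, 3, 4), keepdims=True)[0:1])
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=axes, keepdims=True)
            m2 = (gy * y).mean(axis=axes, keepdims=True)
            x._accumulate(inv_sigma * (gy - m1 - y * m2))

    return Tensor(out_data, out_req, parents, bwd if out_req else None)


def avg_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling; spatial dims must be divisible."""
    x = as_tensor(x)
    n, c, d, h, w = x.data.shape
    f = factor
    if d % f or h % f or w % f:
        raise ValueError(f"spatial dims {(d, h, w)} not divisible by pool factor {f}")
    r = x.data.reshape(n, c, d // f, f, h // f, f, w // f, f)
    out_data = r.mean(axis=(3, 5, 7))

    def bwd(g):
        gg = g[:, :, :, None, :, None, :, None] / (f**3)
        gg = np.broadcast_to(gg, (n, c, d // f, f, h // f, f, w // f, f))
        x._accumulate(gg.reshape(n, c, d, h, w).copy())

    return Tensor(out_data, x.requires_grad, (x,), bwd if x.requires_grad else None)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor."""
    x = as_tensor(x)
    n, c, d, h, w = x.data.shape
    f = factor
    out_data = (
        np.broadcast_to(
            x.data[:, :, :, None, :, None, :, None], (n, c, d, f, h, f, w, f)
        )
        .reshape(n, c, d * f, h * f, w * f)
        .copy()
    )

    def bwd(g):
        gg = g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
        x._accumulate(gg)

    return Tensor(out_data, x.requires_grad, (x,), bwd if x.requires_grad else None)


# -- optimizer -----------------------------------------------------------


class SGD:
    """Plain momentum SGD with decoupled-from-nothing L2 weight decay.

    update: v <- momentum*v + grad + weight_decay*param ; param <- param - lr*v
    """

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
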