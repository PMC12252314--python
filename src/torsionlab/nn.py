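"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the torsion estimator and the
nystagmus detector need: 2-D/1-D convolutions (stride 1, "same" padding,
implemented as im2col + BLAS matmul), max/global-average pooling, dense
layers, ReLU, softmax, and the Adam optimizer.  Everything is seeded
explicitly and runs single-threaded deterministic; there is no global
random state.

Tensors carry float32 data by default; tests build float64 graphs for
finite-difference gradient checks (ops preserve the input dtype).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "relu",
    "matmul",
    "transpose",
    "gather_channels_last",
    "conv2d",
    "conv1d",
    "maxpool2d",
    "maxpool1d",
    "global_avg_pool1d",
    "softmax",
    "concat",
    "gather_rows",
    "gather_per_sample",
    "huber",
    "binary_cross_entropy",
    "Module",
    "Conv2d",
    "Conv1d",
    "Linear",
    "Adam",
    "uniform_fan_in",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _as_float(data) -> np.ndarray:
    a = np.asarray(data)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ---- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                # the node is passed explicitly so closures never capture
                # their own output (avoids uncollectable reference cycles)
                node._backward(node, node.grad)
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return _binop(self, _wrap(other), np.add, _bcast_back_add)

    __radd__ = __add__

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __neg__(self):
        return _unop(self, lambda x: -x, lambda g, x: -g)

    def __mul__(self, other):
        other = _wrap(other)

        def back(out, g):
            if self.requires_grad or self._backward:
                self.accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._backward:
                other.accumulate(_unbroadcast(g * self.data, other.shape))

        return _node(np.multiply(self.data, other.data), (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only supported by scalars")
        return self * (1.0 / other)

    def __pow__(self, p: float):
        return _unop(self, lambda x: x ** p, lambda g, x: g * p * x ** (p - 1))

    def sum(self, axis=None, keepdims=False):
        def back(out, g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self.accumulate(np.broadcast_to(gg, self.shape).copy())

        return _node(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def back(out, g):
            self.accumulate(g.reshape(old))

        return _node(self.data.reshape(shape), (self,), back)

    def __getitem__(self, idx):
        plain = isinstance(idx, (slice, int)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (slice, int)) for i in idx))

        def back(out, g):
            dg = np.zeros_like(self.data)
            if plain:
                dg[idx] += g
            else:
                np.add.at(dg, idx, g)
            self.accumulate(dg)

        return _node(self.data[idx], (self,), back)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*parents: Tensor) -> bool:
    return _GRAD_ENABLED[-1] and any(
        p.requires_grad or p._backward is not None for p in parents
    )


def _node(data, parents, back) -> Tensor:
    if not _track(*parents):
        return Tensor(data)
    out = Tensor(data, parents=parents)
    out._backward = back
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _bcast_back_add(a: Tensor, b: Tensor, out: Tensor, g: np.ndarray) -> None:
    if a.requires_grad or a._backward:
        a.accumulate(_unbroadcast(g, a.shape))
    if b.requires_grad or b._backward:
        b.accumulate(_unbroadcast(g, b.shape))


def _binop(a: Tensor, b: Tensor, fwd, back) -> Tensor:
    return _node(fwd(a.data, b.data), (a, b),
                 lambda out, g: back(a, b, out, g))


def _unop(x: Tensor, fwd, back) -> Tensor:
    return _node(fwd(x.data), (x,),
                 lambda out, g: x.accumulate(back(g, x.data)))


# ---- nonlinearities ------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)
    return _node(y, (x,),
                 lambda out, g: x.accumulate(g * (y > 0)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(out, g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x.accumulate(s * (g - dot))

    return _node(s, (x,), back)


# ---- linear algebra ------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting semantics."""

    def back(out, g):
        if a.requires_grad or a._backward:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a.accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad or b._backward:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b.accumulate(_unbroadcast(gb, b.shape))

    return _node(np.matmul(a.data, b.data), (a, b), back)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(out, g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad or t._backward:
                t.accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), back)


def gather_rows(w: Tensor, idx: np.ndarray) -> Tensor:
    """w[idx] along axis 0; gradient scatters back with repetition handling."""

    def back(out, g):
        dg = np.zeros_like(w.data)
        np.add.at(dg, idx, g)
        w.accumulate(dg)

    return _node(w.data[idx], (w,), back)


def gather_per_sample(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select per-sample channels: x (N, C, ...) and idx (N, K) -> (N, K, ...)."""
    rows = np.arange(x.shape[0])[:, None]

    def back(out, g):
        dg = np.zeros_like(x.data)
        np.add.at(dg, (rows, idx), g)
        x.accumulate(dg)

    return _node(x.data[rows, idx], (x,), back)


def gather_channels_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select per-sample channel maps from channels-last features.

    x (N, H, W, C) and idx (N, K) -> (N, K, H, W).
    """
    rows = np.arange(x.shape[0])[:, None]
    sel = (rows, slice(None), slice(None), idx)

    def back(out, g):
        dg = np.zeros_like(x.data)
        np.add.at(dg, sel, g)
        x.accumulate(dg)

    return _node(x.data[sel], (x,), back)


# ---- convolutions --------------------------------------------------------
#
# 2-D feature maps use channels-last (N, H, W, C) layout throughout: the
# im2col gather then copies contiguous runs of kw*C elements, which is an
# order of magnitude faster than the channels-first pattern on one CPU.

def transpose(x: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))

    def back(out, g):
        x.accumulate(g.transpose(inv))

    return _node(np.ascontiguousarray(x.data.transpose(axes)), (x,), back)


try:                                   # direct JIT convolution kernels:
    import numba as _numba             # an im2col patch matrix is memory-
                                       # bandwidth-bound on a single CPU

    @_numba.njit(cache=False, fastmath=True)
    def _conv_fwd_red(xp, wt, out):
        """Reduction variant, wt (kh,kw,F,C); preferred when C >= F."""
        n, hp, wp, c = xp.shape
        kh, kw, f, _ = wt.shape
        h = hp - kh + 1
        w = wp - kw + 1
        for ni in range(n):
            for y in range(h):
                for x in range(w):
                    for fi in range(f):
                        acc = np.float32(0.0)
                        for i in range(kh):
                            for j in range(kw):
                                for ci in range(c):
                                    acc += xp[ni, y + i, x + j, ci] \
                                        * wt[i, j, fi, ci]
                        out[ni, y, x, fi] = acc

    @_numba.njit(cache=False, fastmath=True)
    def _conv_fwd_bc(xp, w, out):
        """Broadcast variant, w (kh,kw,C,F); preferred when F > C."""
        n, hp, wp, c = xp.shape
        kh, kw, _, f = w.shape
        h = hp - kh + 1
        w_ = wp - kw + 1
        for ni in range(n):
            for y in range(h):
                for x in range(w_):
                    for i in range(kh):
                        for j in range(kw):
                            for ci in range(c):
                                xv = xp[ni, y + i, x + j, ci]
                                for fi in range(f):
                                    out[ni, y, x, fi] += xv * w[i, j, ci, fi]

    @_numba.njit(cache=False, fastmath=True)
    def _conv_dw_kernel(xp, g, dw):
        """dw (kh,kw,C,F): correlation of input patches with output grads."""
        n, hp, wp, c = xp.shape
        kh, kw, _, f = dw.shape
        h = hp - kh + 1
        w = wp - kw + 1
        for ni in range(n):
            for y in range(h):
                for x in range(w):
                    for i in range(kh):
                        for j in range(kw):
                            for ci in range(c):
                                xv = xp[ni, y + i, x + j, ci]
                                for fi in range(f):
                                    dw[i, j, ci, fi] += xv * g[ni, y, x, fi]

    _HAVE_NUMBA = True
except Exception:                      # pragma: no cover - numba is expected
    _HAVE_NUMBA = False


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))


def _conv_same(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same' convolution of a pre-padded (N,Hp,Wp,C) map with (kh,kw,C,F)."""
    kh, kw, c, f = w.shape
    n, hp, wp, _ = xp.shape
    if _HAVE_NUMBA:
        out = np.zeros((n, hp - kh + 1, wp - kw + 1, f), dtype=xp.dtype)
        if c >= f:
            wt = np.ascontiguousarray(w.transpose(0, 1, 3, 2))
            _conv_fwd_red(xp, wt, out)
        else:
            _conv_fwd_bc(xp, np.ascontiguousarray(w), out)
        return out
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, kh * kw * c)
    return (cols @ w.reshape(-1, f)).reshape(n, hp - kh + 1, wp - kw + 1, f)


def _conv_dw_raw(xp: np.ndarray, g: np.ndarray, kh: int, kw: int,
                 c: int, f: int) -> np.ndarray:
    if _HAVE_NUMBA:
        dw = np.zeros((kh, kw, c, f), dtype=xp.dtype)
        _conv_dw_kernel(xp, np.ascontiguousarray(g), dw)
        return dw
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, kh * kw * c)
    return (cols.T @ g.reshape(-1, f)).reshape(kh, kw, c, f)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x (N,H,W,C), w (kh,kw,C,F), b (F,) -> (N,H,W,F); stride 1, same pad."""
    n, h, wd, c = x.shape
    kh, kw, _, f = w.shape
    xp = _pad_same(np.ascontiguousarray(x.data), kh, kw)
    y = _conv_same(xp, w.data) + b.data

    def back(out, g):
        g = np.ascontiguousarray(g)
        if w.requires_grad or w._backward:
            w.accumulate(_conv_dw_raw(xp, g, kh, kw, c, f))
        if b.requires_grad or b._backward:
            b.accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad or x._backward:
            wflip = np.ascontiguousarray(
                w.data[::-1, ::-1].transpose(0, 1, 3, 2))   # (kh,kw,F,C)
            x.accumulate(_conv_same(_pad_same(g, kh, kw), wflip))

    return _node(y, (x, w, b), back)


def _conv1d_raw(x: np.ndarray, w: np.ndarray):
    n, c, ln = x.shape
    f, _, k = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (k // 2, k // 2)))
    win = sliding_window_view(xp, k, axis=2)  # (N,C,L,k)
    cols = win.transpose(0, 2, 1, 3).reshape(n * ln, c * k)
    out = cols @ w.reshape(f, -1).T
    return out.reshape(n, ln, f).transpose(0, 2, 1), cols


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    n, c, ln = x.shape
    f, _, k = w.shape
    y, cols = _conv1d_raw(x.data, w.data)
    y = y + b.data[None, :, None]

    def back(out, g):
        gcols = g.transpose(0, 2, 1).reshape(n * ln, f)
        if w.requires_grad or w._backward:
            w.accumulate((gcols.T @ cols).reshape(w.shape))
        if b.requires_grad or b._backward:
            b.accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad or x._backward:
            wt = w.data[:, :, ::-1].transpose(1, 0, 2)
            dx, _ = _conv1d_raw(g, np.ascontiguousarray(wt))
            x.accumulate(dx)

    return _node(y, (x, w, b), back)


# ---- pooling -------------------------------------------------------------

def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2, channels-last; spatial dims must be even."""
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    v = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    v = np.ascontiguousarray(v.transpose(0, 1, 3, 5, 2, 4)).reshape(
        n, h // 2, w // 2, c, 4)
    arg = v.argmax(axis=-1)
    out = np.take_along_axis(v, arg[..., None], axis=-1)[..., 0]

    def back(o, g):
        dv = np.zeros_like(v)
        np.put_along_axis(dv, arg[..., None], g[..., None], axis=-1)
        dx = dv.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x.accumulate(dx.reshape(n, h, w, c))

    return _node(out, (x,), back)


def maxpool1d(x: Tensor) -> Tensor:
    """Window-2 stride-2 max pooling with ceil mode (odd lengths padded)."""
    n, c, ln = x.shape
    lp = ln + (ln % 2)
    xd = x.data
    if lp != ln:
        xd = np.concatenate(
            [xd, np.full((n, c, 1), -np.inf, dtype=xd.dtype)], axis=2)
    v = xd.reshape(n, c, lp // 2, 2)
    arg = v.argmax(axis=-1)
    out = np.take_along_axis(v, arg[..., None], axis=-1)[..., 0]

    def back(o, g):
        dv = np.zeros((n, c, lp // 2, 2), dtype=g.dtype)
        np.put_along_axis(dv, arg[..., None], g[..., None], axis=-1)
        x.accumulate(dv.reshape(n, c, lp)[:, :, :ln])

    return _node(out, (x,), back)


def global_avg_pool1d(x: Tensor) -> Tensor:
    return x.mean(axis=2)


# ---- losses --------------------------------------------------------------

def huber(pred: Tensor, target: np.ndarray, delta: float = 1.0) -> Tensor:
    """Mean Huber loss: quadratic for |e| <= delta, linear beyond.

    e = target - pred; per-sample loss 0.5 e^2 if |e| <= delta else
    delta*|e| - 0.5*delta^2, averaged over the batch.
    """
    e = np.asarray(target, dtype=pred.data.dtype) - pred.data
    small = np.abs(e) <= delta
    per = np.where(small, 0.5 * e * e, delta * np.abs(e) - 0.5 * delta * delta)
    m = per.size

    def back(out, g):
        de = np.where(small, e, delta * np.sign(e))
        pred.accumulate(-g * de / m)

    return _node(per.mean(), (pred,), back)


def binary_cross_entropy(p: Tensor, labels: np.ndarray,
                         eps: float = 1e-7) -> Tensor:
    """Mean BCE between predicted positive-class probabilities and 0/1 labels."""
    y = np.asarray(labels, dtype=p.data.dtype)
    pc = np.clip(p.data, eps, 1.0 - eps)
    val = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean()
    m = pc.size

    def back(out, g):
        inside = (p.data > eps) & (p.data < 1.0 - eps)
        dp = np.where(inside, (pc - y) / (pc * (1.0 - pc)), 0.0)
        p.accumulate(g * dp / m)

    return _node(val, (p,), back)


# ---- modules -------------------------------------------------------------

def uniform_fan_in(rng: np.random.Generator, shape: tuple, fan_in: int,
                   dtype=np.float32) -> np.ndarray:
    s = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-s, s, size=shape).astype(dtype)


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch in checkpoint")
        for i, p in enumerate(params):
            a = arrays[f"p{i}"]
            if a.shape != p.data.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = a.astype(p.data.dtype)


class Conv2d(Module):
    """3x3 'same' convolution on channels-last maps; weights (k,k,cin,cout)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan = cin * k * k
        self.w = Tensor(uniform_fan_in(rng, (k, k, cin, cout), fan),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan = cin * k
        self.w = Tensor(uniform_fan_in(rng, (cout, cin, k), fan),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.w = Tensor(uniform_fan_in(rng, (din, dout), din),
                        requires_grad=True)
        self.b = Tensor(np.zeros(dout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class Adam:
    """Adam with bias correction; deterministic given a fixed update order."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
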