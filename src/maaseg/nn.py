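"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains three small networks (a hierarchical transformer
encoder, a pixel-pair affinity perceptron, and a pyramid-pooling
segmentation CNN) on a single CPU.  All of them are expressed with the
:class:`Tensor` type defined here, which records a tape of operations and
back-propagates exact gradients.  Only the operations those networks need
are implemented; each op is vectorised NumPy, so forward/backward cost is
dominated by BLAS calls.

Conventions
-----------
* Image tensors are ``(B, C, H, W)``; token tensors are ``(B, N, C)``.
* Parameters are float32; gradient checks in the test-suite run the raw
  ops in float64.
* ``Tensor.backward()`` accumulates into ``.grad`` (a NumPy array).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "Embedding",
    "SGD",
    "cosine_lr",
    "concat",
    "bilinear_resize",
    "adaptive_avg_pool2d",
]


def _as_array(x, dtype=None):
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype, copy=False)
    elif a.dtype == np.float64:
        pass
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the tape bookkeeping for reverse-mode AD."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd driver ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: training graphs can be deep
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # keep python scalars at the tensor's dtype (avoid f64 promotion)
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2)
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            if other.requires_grad:
                other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))
        out._backward = bw
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(src))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        # divide (not multiply by reciprocal) so results match np.mean exactly
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def gelu(self):
        # tanh approximation; gradient derived from the same expression
        x = self.data
        c = math.sqrt(2.0 / math.pi)
        t = np.tanh(c * (x + 0.044715 * x ** 3))
        out = Tensor(0.5 * x * (1.0 + t), _parents=(self,))
        def bw(g):
            dt = (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * x ** 2)
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def softplus(self):
        """log(1 + exp(x)), overflow-safe; gradient is sigmoid(x)."""
        x = self.data
        out = Tensor(np.where(x > 0, x, 0) + np.log1p(np.exp(-np.abs(x))),
                     _parents=(self,))
        out._backward = lambda g: self._accum(
            g / (1.0 + np.exp(-np.clip(x, -60, 60))))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))
        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))
        out._backward = bw
        return out

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, _parents=(self,))
        def bw(g):
            self._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))
        out._backward = bw
        return out

    # -- indexing -----------------------------------------------------------
    def take(self, idx: np.ndarray):
        """Row lookup along axis 0 (embedding-style gather)."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], _parents=(self,))
        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)
        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# composite / structured ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square stride/padding.

    Implemented with a strided-view im2col so both passes reduce to
    einsum/BLAS; the input-gradient scatter loops only over the (small)
    kernel footprint.
    """
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    # im2col: one contiguous copy, then both passes are plain matmuls
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
        .reshape(B * Ho * Wo, C * kh * kw)
    w2d = w.data.reshape(O, C * kh * kw)
    out_data = (col @ w2d.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(out_data), _parents=parents)

    def bw(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
        if b is not None and b.requires_grad:
            b._accum(g2d.sum(axis=0))
        if w.requires_grad:
            w._accum((g2d.T @ col).reshape(w.data.shape))
        if x.requires_grad:
            dcol = (g2d @ w2d).reshape(B, Ho, Wo, C, kh, kw)
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding:padding + H, padding:padding + W]
            x._accum(gx)

    out._backward = bw
    return out


def _bilinear_coeffs(n_in: int, n_out: int):
    """Half-pixel-centre source coordinates, clamped at the border."""
    if n_out == 1:
        src = np.array([0.5 * n_in - 0.5])
    else:
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(np.int64)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    return lo, hi, frac


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor (half-pixel centres)."""
    B, C, H, W = x.data.shape
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return x * 1.0
    y0, y1, fy = _bilinear_coeffs(H, Ho)
    x0, x1, fx = _bilinear_coeffs(W, Wo)
    fy = fy[:, None]
    fx = fx[None, :]
    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx
    d = x.data
    out_data = (w00 * d[:, :, y0[:, None], x0[None, :]]
                + w01 * d[:, :, y0[:, None], x1[None, :]]
                + w10 * d[:, :, y1[:, None], x0[None, :]]
                + w11 * d[:, :, y1[:, None], x1[None, :]])
    out = Tensor(out_data, _parents=(x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        for wgt, yy, xx in ((w00, y0, x0), (w01, y0, x1),
                            (w10, y1, x0), (w11, y1, x1)):
            np.add.at(gx, (slice(None), slice(None), yy[:, None], xx[None, :]), g * wgt)
        x._accum(gx)

    out._backward = bw
    return out


def bilinear_resize_np(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Plain-NumPy bilinear resize of an (H, W) or (H, W, C) array
    (same half-pixel-centre convention as :func:`bilinear_resize`)."""
    H, W = arr.shape[:2]
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return arr.astype(np.float64, copy=True)
    y0, y1, fy = _bilinear_coeffs(H, Ho)
    x0, x1, fx = _bilinear_coeffs(W, Wo)
    fy = fy.reshape(-1, 1, *([1] * (arr.ndim - 2)))
    fx = fx.reshape(1, -1, *([1] * (arr.ndim - 2)))
    a = arr.astype(np.float64)
    return ((1 - fy) * (1 - fx) * a[y0[:, None], x0[None, :]]
            + (1 - fy) * fx * a[y0[:, None], x1[None, :]]
            + fy * (1 - fx) * a[y1[:, None], x0[None, :]]
            + fy * fx * a[y1[:, None], x1[None, :]])


def adaptive_avg_pool2d(x: Tensor, bins: tuple[int, int]) -> Tensor:
    """Average pooling to a fixed (bh, bw) grid with floor/ceil bin edges."""
    B, C, H, W = x.data.shape
    bh, bw = bins
    ys = [(int(math.floor(i * H / bh)), int(math.ceil((i + 1) * H / bh))) for i in range(bh)]
    xs = [(int(math.floor(j * W / bw)), int(math.ceil((j + 1) * W / bw))) for j in range(bw)]
    out_data = np.empty((B, C, bh, bw), dtype=x.data.dtype)
    for i, (y0, y1) in enumerate(ys):
        for j, (x0, x1) in enumerate(xs):
            out_data[:, :, i, j] = x.data[:, :, y0:y1, x0:x1].mean(axis=(2, 3))
    out = Tensor(out_data, _parents=(x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        for i, (y0, y1) in enumerate(ys):
            for j, (x0, x1) in enumerate(xs):
                area = (y1 - y0) * (x1 - x0)
                gx[:, :, y0:y1, x0:x1] += g[:, :, i, j][:, :, None, None] / area
        x._accum(gx)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Parameter container with recursive discovery, mirroring common NN APIs."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
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
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else math.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale or 1e-30, (n_in, n_out)))
        if zero_init:
            self.weight.data[:] = 0.0
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 bias: bool = True, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel))
        if zero_init:
            w[:] = 0.0
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 1.0, (n_rows, dim)))

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight.take(np.asarray(idx, dtype=np.int64))


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``max_grad_norm`` rescales the global gradient norm before the
    update; occasional loss spikes otherwise derail small-batch
    transformer training.
    """

    def __init__(self, params: Iterable[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0,
                 max_grad_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        scale = 1.0
        if self.max_grad_norm is not None:
            total = math.sqrt(sum(float((p.grad ** 2).sum())
                                  for p in self.params if p.grad is not None))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / (total + 1e-12)
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, step: int, total_steps: int, min_lr: float = 0.0) -> float:
    """Cosine annealing from ``base_lr`` down to ``min_lr`` over ``total_steps``."""
    if total_steps <= 1:
        return base_lr
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * frac))
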