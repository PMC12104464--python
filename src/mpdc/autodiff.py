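"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the operator set needed by the segmentation
network and its losses: broadcast arithmetic, reductions, 2-D convolution
(stride 1, "same" padding), 2x2/stride-2 transposed convolution, 2x2 max
pooling, bilinear resizing, batch normalisation, channel softmax /
log-softmax, ReLU, concatenation and basic indexing.  Every operator's
gradient is exercised against central finite differences in the test
suite.

Tensors are thin wrappers around float32/float64 ndarrays.  Calling
:meth:`Tensor.backward` on a scalar runs a topological sweep over the
recorded tape.  ``detach`` produces a view that blocks gradient flow —
the stop-gradient primitive required by the direction-consistency and
cross-pseudo-supervision losses.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "bilinear_resize",
    "batchnorm2d",
    "softmax_channels",
    "log_softmax_channels",
    "relu",
    "SGD",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype.kind == "f" else None)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return self.data.item()

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core ---------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def abs_pow(self, p: float) -> "Tensor":
        """|x|**p with subgradient 0 at x = 0 (used by channel compression)."""
        out = Tensor(np.abs(self.data) ** p, parents=(self,))

        def bw(g):
            self._accumulate(g * p * np.abs(self.data) ** (p - 1) * np.sign(self.data))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(self.data.dtype))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding kxk windows: (B, C, H, W) -> (B, H-k+1, W-k+1, C, k, k)."""
    w = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return w.transpose(0, 2, 3, 1, 4, 5)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 1) -> Tensor:
    """2-D correlation, stride 1.  weight: (Co, Ci, k, k)."""
    k = weight.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(xp, k)  # B, Ho, Wo, Ci, k, k
    y = np.tensordot(win, weight.data, axes=([3, 4, 5], [1, 2, 3]))  # B, Ho, Wo, Co
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bw(g):
        if weight.requires_grad:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 1, 2]))  # Co, Ci, k, k
            weight._accumulate(gw.astype(weight.data.dtype))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            pad_g = k - 1 - padding
            gp = np.pad(g, ((0, 0), (0, 0), (pad_g, pad_g), (pad_g, pad_g)))
            gwin = _windows(gp, k)  # B, H, W, Co, k, k
            wflip = weight.data[:, :, ::-1, ::-1]  # Co, Ci, k, k
            gx = np.tensordot(gwin, wflip, axes=([3, 4, 5], [0, 2, 3]))  # B, H, W, Ci
            x._accumulate(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)).astype(x.data.dtype))

    out._backward = bw
    return out


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution with 2x2 kernel, stride 2 (exact x2 upsampling).

    weight: (Ci, Co, 2, 2); output (B, Co, 2H, 2W).  Kernel and stride match
    so output blocks do not overlap.
    """
    b_, ci, h, w = x.shape
    co = weight.shape[1]
    t = np.tensordot(x.data, weight.data, axes=([1], [0]))  # B, H, W, Co, 2, 2
    y = t.transpose(0, 3, 1, 4, 2, 5).reshape(b_, co, 2 * h, 2 * w)
    y = np.ascontiguousarray(y)
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bw(g):
        gr = g.reshape(b_, co, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # B,H,W,Co,2,2
        if x.requires_grad:
            gx = np.tensordot(gr, weight.data, axes=([3, 4, 5], [1, 2, 3]))  # B,H,W,Ci
            x._accumulate(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)).astype(x.data.dtype))
        if weight.requires_grad:
            gw = np.tensordot(x.data, gr, axes=([0, 2, 3], [0, 1, 2]))  # Ci,Co,2,2
            weight._accumulate(gw.astype(weight.data.dtype))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    # one-hot of the (first) argmax so tied maxima do not double-count
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)
    out = Tensor(y, parents=(x,))

    def bw(g):
        sel = np.zeros_like(flat)
        np.put_along_axis(sel, arg[..., None], 1.0, axis=-1)
        gx = sel * g[..., None]
        gx = gx.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        x._accumulate(gx.astype(x.data.dtype))

    out._backward = bw
    return out


def _interp_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """1-D bilinear interpolation matrix (align_corners=False convention)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resize of (B, C, H, W) maps."""
    b, c, h, w = x.shape
    ah = _interp_matrix(out_h, h, x.data.dtype)
    aw = _interp_matrix(out_w, w, x.data.dtype)
    y = np.einsum("oh,bchw,pw->bcop", ah, x.data, aw, optimize=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        gx = np.einsum("oh,bcop,pw->bchw", ah, g, aw, optimize=True)
        x._accumulate(gx.astype(x.data.dtype))

    out._backward = bw
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (B, H, W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    out = Tensor(y, parents=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                inv4 = inv.reshape(1, -1, 1, 1)
                s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = inv4 * (gxh - s1 / n - xhat * s2 / n)
            else:
                gx = gxh * inv.reshape(1, -1, 1, 1)
            x._accumulate(gx.astype(x.data.dtype))

    out._backward = bw
    return out


def softmax_channels(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate((y * (g - dot)).astype(x.data.dtype))

    out._backward = bw
    return out


def log_softmax_channels(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    y = z - lse
    out = Tensor(y, parents=(x,))

    def bw(g):
        sm = np.exp(y)
        x._accumulate((g - sm * g.sum(axis=axis, keepdims=True)).astype(x.data.dtype))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class SGD:
    """SGD with classical momentum and decoupled L2 weight decay on gradients."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def state_arrays(self) -> list[np.ndarray]:
        return self.velocity

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        if len(arrays) != len(self.velocity):
            raise ValueError("optimizer state length mismatch")
        self.velocity = [np.array(a, copy=True) for a in arrays]
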