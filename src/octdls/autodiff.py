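"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the transformer segmenter and the
convolutional baseline: broadcast arithmetic, batched matmul, layer norm,
softmax, GELU/ReLU, masked cross-entropy on logits, 3x3 "same" convolution
via im2col, 2x2 max pooling, nearest-neighbour upsampling, channel
concatenation and spatial (channel) dropout.  All tensors are float64; the
graph is a plain DAG of `Tensor` nodes walked once, in reverse topological
order, by `Tensor.backward`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "layer_norm",
    "softmax",
    "gelu",
    "relu",
    "cross_entropy_logits",
    "conv2d",
    "max_pool2",
    "upsample2_nearest",
    "concat_channels",
    "spatial_dropout",
    "SGD",
    "Adam",
]


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node (a scalar unless `grad` is given)."""
        if grad is None:
            if self.data.ndim != 0:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep at many layers
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), constant(-1.0)))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(array) -> Tensor:
    return Tensor(array, requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape`, inverting numpy broadcasting."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting on leading axes."""
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


def transpose(a: Tensor, axes) -> Tensor:
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return Tensor(out_data, parents=(a,), backward=backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis with learnable gain/bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gain.data + bias.data

    def backward(g):
        if gain.requires_grad:
            gain._accumulate(
                _unbroadcast(g * xhat, gain.shape)
            )
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.shape))
        if x.requires_grad:
            dxhat = g * gain.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out_data, parents=(x, gain, bias), backward=backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            x._accumulate(p * (g - dot))

    return Tensor(p, parents=(x,), backward=backward)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out_data = x.data * cdf

    def backward(g):
        if x.requires_grad:
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data * x.data)
            x._accumulate(g * (cdf + x.data * pdf))

    return Tensor(out_data, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def cross_entropy_logits(
    logits: Tensor,
    labels: np.ndarray,
    ignore_index: int = 255,
    pixel_weights: np.ndarray | None = None,
) -> Tensor:
    """Mean per-pixel cross-entropy from logits, skipping `ignore_index` pixels.

    `logits` has class scores on the last axis; `labels` has the matching
    leading shape with integer class ids.  Optional `pixel_weights` (same
    shape as `labels`) reweight the per-pixel terms; the loss is then the
    weighted mean over valid pixels.
    """
    labels = np.asarray(labels)
    if labels.shape != logits.shape[:-1]:
        raise ValueError(
            f"labels shape {labels.shape} does not match logits {logits.shape[:-1]}"
        )
    n_classes = logits.shape[-1]
    valid = labels != ignore_index
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("all pixels are ignored; loss undefined")
    bad = np.unique(labels[valid & ((labels < 0) | (labels >= n_classes))])
    if bad.size:
        raise ValueError(f"labels outside class alphabet: {bad.tolist()}")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    safe_labels = np.where(valid, labels, 0)
    picked = np.take_along_axis(logp, safe_labels[..., None], axis=-1)[..., 0]
    if pixel_weights is None:
        w = valid / n_valid
    else:
        w = np.asarray(pixel_weights, dtype=np.float64) * valid
        total = w.sum()
        if total <= 0:
            raise ValueError("pixel weights sum to zero over valid pixels")
        w = w / total
    loss = -(picked * w).sum()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            grad = p.copy()
            np.put_along_axis(
                grad,
                safe_labels[..., None],
                np.take_along_axis(grad, safe_labels[..., None], axis=-1) - 1.0,
                axis=-1,
            )
            grad *= w[..., None]
            logits._accumulate(g * grad)

    return Tensor(loss, parents=(logits,), backward=backward)


# -- convolutional primitives (NCHW layout) ---------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, out_h: int, out_w: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + out_h, j : j + out_w]
    return cols.reshape(n, c * kh * kw, out_h * out_w)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int | None = None) -> Tensor:
    """Stride-1 2-D convolution; default padding keeps the spatial size."""
    n, c, h, w = x.shape
    f, c_in, kh, kw = weight.shape
    if c_in != c:
        raise ValueError(f"channel mismatch: input {c}, weight {c_in}")
    if padding is None:
        padding = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out_h = h + 2 * padding - kh + 1
    out_w = w + 2 * padding - kw + 1
    cols = _im2col(xp, kh, kw, out_h, out_w)
    wmat = weight.data.reshape(f, -1)
    out_data = (wmat @ cols).reshape(n, f, out_h, out_w) + bias.data[:, None, None]

    def backward(g):
        gmat = g.reshape(n, f, -1)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("nfk,nck->fc", gmat, cols)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = (wmat.T @ gmat).reshape(n, c, kh, kw, out_h, out_w)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + out_h, j : j + out_w] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2 requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gr = np.zeros((n, c, h // 2, w // 2, 4))
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gr.reshape(n, c, h, w))

    return Tensor(out_data, parents=(x,), backward=backward)


def upsample2_nearest(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = out_data.shape
            gr = g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
            x._accumulate(gr)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return Tensor(out_data, parents=(a, b), backward=backward)


def spatial_dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Drops whole feature maps (channels) with probability `rate`."""
    if not training or rate <= 0.0:
        return x
    n, c = x.shape[:2]
    keep = ((rng.random((n, c, 1, 1)) >= rate) / (1.0 - rate)).astype(x.data.dtype)
    return mul(x, constant(keep))


# -- optimizers -------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], momentum: float = 0.9):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adam with bias correction; learning rate supplied per step."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
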