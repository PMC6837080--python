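"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations needed by a fully-convolutional encoder-decoder are
implemented: stride-1 "same" convolution, 2x2 max pooling, 2x nearest
up-sampling, batch normalization, ReLU, channel concatenation, element-wise
addition, and a weighted softmax cross-entropy loss. All arithmetic is
float32; convolutions are im2col matmuls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "concat",
    "relu",
    "conv2d",
    "max_pool2",
    "upsample2",
    "batch_norm",
    "weighted_cross_entropy_loss",
]


class Tensor:
    """Array node in the autodiff graph.

    ``data`` is a float32 ndarray; ``grad`` accumulates the gradient of the
    final scalar loss with respect to ``data`` after :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def add(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise sum of two same-shape tensors."""
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    if not _needs_graph(a, b):
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=(a, b), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (channel axis by default)."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    if not _needs_graph(*tensors):
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=tuple(tensors), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        x._accumulate(g * mask)

    if not _needs_graph(x):
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=(x,), backward=backward)


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*kh*kw, OH*OW) for stride-1 windows."""
    n, c, hp, wp = xp.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N, C, OH, OW, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape, kh: int, kw: int) -> np.ndarray:
    n, c, hp, wp = shape
    oh, ow = hp - kh + 1, wp - kw + 1
    dx = np.zeros(shape, dtype=np.float32)
    d = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + oh, j : j + ow] += d[:, :, i, j]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 convolution with "same" zero padding.

    ``weight`` has shape (Cout, Cin, kh, kw) with odd kh, kw so the output
    spatial size equals the input's.
    """
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw)  # (N, Cin*kh*kw, H*W)
    wmat = weight.data.reshape(cout, -1)
    out_data = np.matmul(wmat, cols).reshape(n, cout, h, w)
    if bias is not None:
        out_data += bias.data.reshape(1, cout, 1, 1)

    def backward(g):
        gflat = g.reshape(n, cout, h * w)
        weight._accumulate(
            np.matmul(gflat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
        )
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(wmat.T, gflat)  # (N, Cin*kh*kw, H*W)
        dxp = _col2im(dcols, xp.shape, kh, kw)
        x._accumulate(dxp[:, :, ph : ph + h, pw : pw + w])

    parents = (x, weight) if bias is None else (x, weight, bias)
    if not _needs_graph(*parents):
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=parents, backward=backward)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2: spatial size ({h}, {w}) not divisible by 2")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(xr, axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(n, c, h, w))

    if not _needs_graph(x):
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=(x,), backward=backward)


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour up-sampling."""
    n, c, h, w = x.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    if not _needs_graph(x):
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=(x,), backward=backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running estimates are
    updated in place; in eval mode the running estimates are used.
    """
    n, c, h, w = x.shape
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gs = gamma.data.reshape(1, c, 1, 1) * inv_std.reshape(1, c, 1, 1)
        if training:
            m = n * h * w
            dxhat = g * gamma.data.reshape(1, c, 1, 1)
            t1 = dxhat.sum(axis=axes, keepdims=True)
            t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            dx = (inv_std.reshape(1, c, 1, 1) / m) * (m * dxhat - t1 - xhat * t2)
            x._accumulate(dx.astype(np.float32))
        else:
            x._accumulate(g * gs)

    if not _needs_graph(x, gamma, beta):
        return Tensor(out_data)
    return Tensor(out_data, requires_grad=True, parents=(x, gamma, beta), backward=backward)


def weighted_cross_entropy_loss(
    scores: Tensor, target: np.ndarray, weights: np.ndarray
) -> Tensor:
    """Mean per-pixel cross-entropy with per-class weights.

    loss = -(1/N) sum_i w[y_i] * log softmax(scores)_i[y_i], with N the number
    of pixels. With all-ones weights this is the plain pixel-wise
    cross-entropy.
    """
    n, c, h, w = scores.shape
    target = np.asarray(target)
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} != {(n, h, w)}")
    if target.min() < 0 or target.max() >= c:
        raise ValueError(f"target contains class index outside [0, {c})")
    weights = np.asarray(weights, dtype=np.float32)
    if weights.shape != (c,):
        raise ValueError(f"expected {c} class weights, got shape {weights.shape}")

    s = scores.data.astype(np.float64)
    s -= s.max(axis=1, keepdims=True)
    e = np.exp(s)
    p = e / e.sum(axis=1, keepdims=True)  # (N, C, H, W)
    npix = n * h * w
    onehot_idx = target[:, None, :, :]
    logp_true = np.take_along_axis(s - np.log(e.sum(axis=1, keepdims=True)), onehot_idx, axis=1)[:, 0]
    w_pix = weights[target]
    loss_val = -(w_pix * logp_true).sum() / npix

    def backward(g):
        dscores = p.copy()
        np.put_along_axis(
            dscores, onehot_idx, np.take_along_axis(dscores, onehot_idx, axis=1) - 1.0, axis=1
        )
        dscores *= w_pix[:, None, :, :] / npix
        scores._accumulate(g * dscores)

    if not _needs_graph(scores):
        return Tensor(np.float32(loss_val))
    return Tensor(np.float32(loss_val), requires_grad=True, parents=(scores,), backward=backward)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    """Plain (non-differentiable) softmax over ``axis`` for inference."""
    s = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=axis, keepdims=True)
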