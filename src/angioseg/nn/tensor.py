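"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape: :class:`Tensor` wraps a float32 ``ndarray`` and
records, per op, a closure that scatters the upstream gradient to the op's
inputs.  Convolutions are lowered to GEMM via im2col so the heavy lifting is
done by BLAS; the transposed convolution and the data-gradient of the forward
convolution share one adjoint routine (``_corr_adjoint``), which keeps the two
code paths consistent by construction.

Only the operations the segmentation network needs are provided.  Everything
is float32; inputs that do not require gradients are never cached, so feeding
constant image batches costs no extra memory.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward = None

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _tracked(self) -> bool:
        """Whether gradients must flow to or through this tensor."""
        return self.requires_grad or self._backward is not None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Run the tape backwards from this tensor.

        ``grad`` is the cotangent seeded at this node (defaults to ones, which
        is only meaningful for scalar-like outputs).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(_topo_order(self)):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/closures promptly
                if not node.requires_grad:
                    node.grad = None
                node._backward = None
                node._parents = ()


def _topo_order(root: Tensor) -> list:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p._tracked():
                stack.append((p, False))
    return order


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if not _GRAD_ENABLED:
        return out
    tracked = tuple(p for p in parents if p._tracked())
    if tracked:
        out._parents = tracked
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# correlation (convolution) cores — pure ndarray helpers, no tape
# ---------------------------------------------------------------------------

def _out_size(n: int, k: int, stride: int, pad: int, dilation: int) -> int:
    ke = dilation * (k - 1) + 1
    return (n + 2 * pad - ke) // stride + 1


def _im2col(xp: np.ndarray, k: int, stride: int, dilation: int,
            ho: int, wo: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B, C*k*k, ho*wo) patch matrix."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        hi = i * dilation
        for j in range(k):
            wj = j * dilation
            cols[:, :, i, j] = xp[:, :, hi:hi + (ho - 1) * stride + 1:stride,
                                  wj:wj + (wo - 1) * stride + 1:stride]
    return cols.reshape(b, c * k * k, ho * wo)


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, dilation: int,
            ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    dxp = np.zeros(xp_shape, dtype=np.float32)
    b, c = xp_shape[:2]
    d6 = dcols.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        hi = i * dilation
        for j in range(k):
            wj = j * dilation
            dxp[:, :, hi:hi + (ho - 1) * stride + 1:stride,
                wj:wj + (wo - 1) * stride + 1:stride] += d6[:, :, i, j]
    return dxp


def _corr_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int,
                  dilation: int, return_cols: bool = False):
    """Cross-correlation of (B,C,H,W) with (O,C,k,k) weights."""
    b, c, h, wd = x.shape
    o, cw, k, _ = w.shape
    if c != cw:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {cw}")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    ho = _out_size(h, k, stride, pad, dilation)
    wo = _out_size(wd, k, stride, pad, dilation)
    cols = _im2col(xp, k, stride, dilation, ho, wo)
    y = np.matmul(w.reshape(o, -1), cols).reshape(b, o, ho, wo)
    return (y, cols) if return_cols else y


def _corr_adjoint(g: np.ndarray, w: np.ndarray, in_shape, stride: int,
                  pad: int, dilation: int) -> np.ndarray:
    """Adjoint of ``_corr_forward`` in its input: maps (B,O,ho,wo) -> in_shape."""
    b, c, h, wd = in_shape
    o, _, k, _ = w.shape
    ho, wo = g.shape[2], g.shape[3]
    dcols = np.matmul(w.reshape(o, -1).T, g.reshape(b, o, -1))
    dxp = _col2im(dcols, (b, c, h + 2 * pad, wd + 2 * pad), k, stride,
                  dilation, ho, wo)
    return dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp


def _corr_weight_grad(cols: np.ndarray, g: np.ndarray, w_shape) -> np.ndarray:
    o, c, k, _ = w_shape
    b = g.shape[0]
    g2 = g.reshape(b, o, -1)
    return np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w_shape)


# ---------------------------------------------------------------------------
# tape ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2D cross-correlation, torch weight layout (out, in, k, k)."""
    need_cols = w._tracked() and _GRAD_ENABLED
    res = _corr_forward(x.data, w.data, stride, padding, dilation,
                        return_cols=True)
    y, cols = res
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1)
    if not need_cols:
        cols = None
    in_shape = x.data.shape
    wdata = w.data

    def _bw(dy):
        if w._tracked() and cols is not None:
            w._accum(_corr_weight_grad(cols, dy, wdata.shape))
        if b is not None and b._tracked():
            b._accum(dy.sum(axis=(0, 2, 3)))
        if x._tracked():
            x._accum(_corr_adjoint(dy, wdata, in_shape, stride, padding,
                                   dilation))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, _bw)


def conv_transpose2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
                     stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transposed 2D convolution, torch weight layout (in, out, k, k).

    Implemented as the adjoint of the corresponding forward correlation, so
    the two stay numerically consistent.
    """
    bsz, cin, h, wd = x.data.shape
    cinw, cout, k, _ = w.data.shape
    if cin != cinw:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cinw}")
    hb = stride * (h - 1) + k - 2 * padding + output_padding
    wb = stride * (wd - 1) + k - 2 * padding + output_padding
    big_shape = (bsz, cout, hb, wb)
    y = _corr_adjoint(x.data, w.data, big_shape, stride, padding, 1)
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1)
    xdata = x.data
    wdata = w.data

    def _bw(dy):
        if w._tracked():
            _, cols = _corr_forward(dy, wdata, stride, padding, 1,
                                    return_cols=True)
            w._accum(_corr_weight_grad(cols, xdata, wdata.shape))
        if b is not None and b._tracked():
            b._accum(dy.sum(axis=(0, 2, 3)))
        if x._tracked():
            x._accum(_corr_forward(dy, wdata, stride, padding, 1))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, _bw)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)

    def _bw(dy):
        x._accum(dy * (x.data > 0))

    return _make(y, (x,), _bw)


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data).astype(np.float32)

    def _bw(dy):
        x._accum(dy * y * (1.0 - y))

    return _make(y, (x,), _bw)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in add: {a.data.shape} vs {b.data.shape}")
    y = a.data + b.data

    def _bw(dy):
        if a._tracked():
            a._accum(dy)
        if b._tracked():
            b._accum(dy)

    return _make(y, (a, b), _bw)


def concat(parts: Iterable[Tensor], axis: int = 1) -> Tensor:
    parts = list(parts)
    y = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def _bw(dy):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p._tracked():
                sl = [slice(None)] * dy.ndim
                sl[axis] = slice(lo, hi)
                p._accum(dy[tuple(sl)])

    return _make(y, parts, _bw)


def maxpool2d(x: Tensor, k: int) -> Tensor:
    """Max pooling with kernel == stride (floor mode)."""
    b, c, h, w = x.data.shape
    if k > min(h, w):
        raise ValueError(f"pool kernel {k} exceeds spatial size {(h, w)}")
    ho, wo = h // k, w // k
    xc = x.data[:, :, :ho * k, :wo * k]
    xr = (xc.reshape(b, c, ho, k, wo, k)
          .transpose(0, 1, 2, 4, 3, 5)
          .reshape(b, c, ho, wo, k * k))
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def _bw(dy):
        dxr = np.zeros((b, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((b, c, h, w), dtype=np.float32)
        dx[:, :, :ho * k, :wo * k] = (
            dxr.reshape(b, c, ho, wo, k, k)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(b, c, ho * k, wo * k))
        x._accum(dx)

    return _make(y, (x,), _bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    xd = x.data
    mu = xd.mean(axis=(2, 3), keepdims=True)
    var = xd.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    c = xd.shape[1]
    y = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def _bw(dy):
        if gamma._tracked():
            gamma._accum((dy * xhat).sum(axis=(0, 2, 3)))
        if beta._tracked():
            beta._accum(dy.sum(axis=(0, 2, 3)))
        if x._tracked():
            dxhat = dy * gamma.data.reshape(1, c, 1, 1)
            m1 = dxhat.mean(axis=(2, 3), keepdims=True)
            m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return _make(y, (x, gamma, beta), _bw)


def upsample_nearest(x: Tensor, size: Tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize to ``size`` (any integer target)."""
    b, c, h, w = x.data.shape
    ho, wo = size
    rows = (np.arange(ho) * h) // ho
    cols = (np.arange(wo) * w) // wo
    y = x.data[:, :, rows][:, :, :, cols]

    def _bw(dy):
        dx = np.zeros((b, c, h, w), dtype=np.float32)
        np.add.at(dx, (slice(None), slice(None), rows[:, None], cols[None, :]), dy)
        x._accum(dx)

    return _make(y, (x,), _bw)
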