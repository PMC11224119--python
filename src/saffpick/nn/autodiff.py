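"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the segmentation network needs —
2-D (grouped/dilated) convolution via im2col, max pooling, bilinear
upsampling, batch normalization, channel permutation/concatenation, the
pointwise nonlinearities and a softmax cross-entropy head — each with a
hand-derived backward pass.  Gradients are checked against finite
differences in the test suite.

All tensors are NCHW float64 unless noted.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


# -- convolution ---------------------------------------------------------

def _conv_out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, d: int, oh: int, ow: int):
    n, c, _, _ = xp.shape
    sn, sc, sh, sw = xp.strides
    view = as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh * d, sw * d, sh * s, sw * s),
        writeable=False,
    )
    return view.reshape(n, c, kh * kw, oh * ow)


def _col2im(gcols, xp_shape, kh, kw, s, d, oh, ow):
    n, c, hp, wp = xp_shape
    gxp = np.zeros(xp_shape, dtype=np.float64)
    gc = gcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i * d : i * d + s * oh : s, j * d : j * d + s * ow : s] += gc[
                :, :, i, j
            ]
    return gxp


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """Grouped dilated 2-D convolution.

    ``groups`` must be 1 (dense) or equal to the input channel count
    (depthwise); these are the only forms the architecture uses.
    """
    n, c, h, w = x.data.shape
    co, cig, kh, kw = weight.data.shape
    if groups not in (1, c):
        raise ValueError("conv2d supports groups=1 or depthwise groups=C only")
    depthwise = groups == c and c > 1
    if depthwise and (cig != 1 or co != c):
        raise ValueError("depthwise conv requires weight of shape (C, 1, kh, kw)")
    if not depthwise and cig != c:
        raise ValueError("weight in-channels mismatch")
    oh = _conv_out_size(h, kh, stride, padding, dilation)
    ow = _conv_out_size(w, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)  # (N, C, K, L)

    if depthwise:
        w2 = weight.data.reshape(c, kh * kw)
        out_l = np.einsum("ck,nckl->ncl", w2, cols, optimize=True)
        out_data = out_l.reshape(n, co, oh, ow)
    else:
        w2 = weight.data.reshape(co, c, kh * kw)
        out_l = np.einsum("ock,nckl->nol", w2, cols, optimize=True)
        out_data = out_l.reshape(n, co, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1)

    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, parents=parents)

    def backward(g):
        gl = g.reshape(n, co, oh * ow)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if depthwise:
            if weight.requires_grad:
                gw = np.einsum("ncl,nckl->ck", gl, cols, optimize=True)
                weight._accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = gl[:, :, None, :] * w2[None, :, :, None]
                gxp = _col2im(gcols, xp.shape, kh, kw, stride, dilation, oh, ow)
                x._accumulate(gxp[:, :, padding : padding + h, padding : padding + w])
        else:
            if weight.requires_grad:
                gw = np.einsum("nol,nckl->ock", gl, cols, optimize=True)
                weight._accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = np.einsum("nol,ock->nckl", gl, w2, optimize=True)
                gxp = _col2im(gcols, xp.shape, kh, kw, stride, dilation, oh, ow)
                x._accumulate(gxp[:, :, padding : padding + h, padding : padding + w])

    out._backward = backward
    return out


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    oh = _conv_out_size(h, kernel, stride, padding, 1)
    ow = _conv_out_size(w, kernel, stride, padding, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    cols = _im2col(xp, kernel, kernel, stride, 1, oh, ow)  # (N, C, K, L)
    arg = cols.argmax(axis=2)  # (N, C, L)
    out_data = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]
    out = Tensor(out_data.reshape(n, c, oh, ow), parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gl = g.reshape(n, c, oh * ow)
        gxp = np.zeros(xp.shape, dtype=np.float64)
        l_idx = np.arange(oh * ow)
        rows = (l_idx // ow) * stride + arg // kernel  # padded row of chosen tap
        cols_i = (l_idx % ow) * stride + arg % kernel
        flat = rows * xp.shape[3] + cols_i  # (N, C, L)
        np.add.at(
            gxp.reshape(n, c, -1),
            (np.arange(n)[:, None, None], np.arange(c)[None, :, None], flat),
            gl,
        )
        x._accumulate(gxp[:, :, padding : padding + h, padding : padding + w])

    out._backward = backward
    return out


_BILINEAR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D interpolation matrix, align_corners=False convention."""
    key = (n_in, n_out)
    if key not in _BILINEAR_CACHE:
        m = np.zeros((n_out, n_in))
        scale = n_in / n_out
        for o in range(n_out):
            src = (o + 0.5) * scale - 0.5
            src = min(max(src, 0.0), n_in - 1.0)
            i0 = int(np.floor(src))
            i1 = min(i0 + 1, n_in - 1)
            f = src - i0
            m[o, i0] += 1.0 - f
            m[o, i1] += f
        _BILINEAR_CACHE[key] = m
    return _BILINEAR_CACHE[key]


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    n, c, h, w = x.data.shape
    wr = _bilinear_matrix(h, out_h)
    wc = _bilinear_matrix(w, out_w)
    tmp = np.einsum("oh,nchw->ncow", wr, x.data, optimize=True)
    out = Tensor(np.einsum("pw,ncow->ncop", wc, tmp, optimize=True), parents=(x,))

    def backward(g):
        if x.requires_grad:
            t = np.einsum("pw,ncop->ncow", wc, g, optimize=True)
            x._accumulate(np.einsum("oh,ncow->nchw", wr, t, optimize=True))

    out._backward = backward
    return out


def broadcast_hw(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Tile a (N, C, 1, 1) map to (N, C, H, W)."""
    n, c, h, w = x.data.shape
    assert h == 1 and w == 1
    out = Tensor(np.broadcast_to(x.data, (n, c, out_h, out_w)).copy(), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.sum(axis=(2, 3), keepdims=True))

    out._backward = backward
    return out


def _reduce_max(x: Tensor, axis: int, keepdims: bool = True) -> Tensor:
    arg = np.expand_dims(x.data.argmax(axis=axis), axis)
    out_data = np.take_along_axis(x.data, arg, axis=axis)
    out = Tensor(out_data if keepdims else out_data.squeeze(axis), parents=(x,))

    def backward(g):
        if x.requires_grad:
            gk = g if keepdims else np.expand_dims(g, axis)
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, arg, gk, axis=axis)
            x._accumulate(gx)

    out._backward = backward
    return out


def spatial_mean(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3), keepdims=True), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    out._backward = backward
    return out


def spatial_max(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    flat = Tensor(x.data.reshape(n, c, 1, h * w), parents=(x,))

    def fb(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    flat._backward = fb
    return _reduce_max(flat, axis=3)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[1]
    out = Tensor(x.data.mean(axis=1, keepdims=True), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / c, x.data.shape).copy())

    out._backward = backward
    return out


def channel_max(x: Tensor) -> Tensor:
    return _reduce_max(x, axis=1)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def narrow_channels(x: Tensor, start: int, length: int) -> Tensor:
    out = Tensor(x.data[:, start : start + length].copy(), parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, start : start + length] = g
            x._accumulate(gx)

    out._backward = backward
    return out


def permute_channels(x: Tensor, perm: np.ndarray) -> Tensor:
    perm = np.asarray(perm)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    out = Tensor(x.data[:, perm], parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[:, inv])

    out._backward = backward
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Batch normalization over (N, H, W) per channel; returns (out, mu, var)."""
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    gshape = (1, -1, 1, 1)
    out = Tensor(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape),
                 parents=(x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(gshape)
            mean_d = dxhat.sum(axis=axes, keepdims=True) / m
            mean_dx = (dxhat * xhat).sum(axis=axes, keepdims=True) / m
            x._accumulate((dxhat - mean_d - xhat * mean_dx) / std)

    out._backward = backward
    return out, mu.squeeze(), var.squeeze()


def batchnorm_eval(x: Tensor, gamma: Tensor, beta: Tensor,
                   running_mean: np.ndarray, running_var: np.ndarray,
                   eps: float = 1e-5) -> Tensor:
    gshape = (1, -1, 1, 1)
    scale = gamma.data.reshape(gshape) / np.sqrt(running_var.reshape(gshape) + eps)
    out = Tensor(scale * (x.data - running_mean.reshape(gshape)) + beta.data.reshape(gshape),
                 parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * scale)

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross entropy of NKHW logits against NHW int labels."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sm = ez / ez.sum(axis=1, keepdims=True)
    n, k, h, w = z.shape
    lab = labels.reshape(n, h, w)
    idx = (np.arange(n)[:, None, None], lab, np.arange(h)[None, :, None],
           np.arange(w)[None, None, :])
    logp = (z - zmax) - np.log(ez.sum(axis=1, keepdims=True))
    loss = -logp[idx[0], lab, idx[2], idx[3]].mean()
    out = Tensor(loss, parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            grad = sm.copy()
            onehot_idx = (idx[0], lab, idx[2], idx[3])
            grad[onehot_idx] -= 1.0
            logits._accumulate(g * grad / (n * h * w))

    out._backward = backward
    return out


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar f at x (test oracle)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
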