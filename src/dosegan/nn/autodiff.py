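"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains 3D convolutional networks on CPU, so this module provides
exactly the operator set those networks need (3D convolution, batch
normalisation, factor-2 resampling, pointwise nonlinearities and the
reductions used by the losses) rather than a general tensor algebra.

Convolutions are evaluated as one GEMM per kernel offset (27 for a 3^3
kernel) against strided views of the padded input, which keeps peak memory
at a small multiple of the activation size instead of materialising a full
im2col matrix.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / detached forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Var:
    """A node in the computation graph: an ndarray plus backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=None):
        self.data = np.asarray(data)
        self.grad = None
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        if not _GRAD_ENABLED:
            parents, backward = (), None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Var":
        return Var(self.data, requires_grad=False)

    def accumulate(self, g):
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.array(g, dtype=self.data.dtype, copy=True)
            else:
                self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order (graphs can be deep for big nets)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x, requires_grad=False)


# ---------------------------------------------------------------------------
# convolution


def _conv_out_len(n, k, s, p):
    return (n + 2 * p - k) // s + 1


def conv3d(x: Var, w: Var, b: Var | None, stride: int = 1, pad: int = 0) -> Var:
    """3D cross-correlation, NCDHW layout, cubic kernel and isotropic stride.

    ``w`` has shape (C_out, C_in, k, k, k); ``b`` is (C_out,) or None.
    """
    xd = x.data
    n, cin, d, h, wd = xd.shape
    cout, cin_w, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if cin != cin_w:
        raise ValueError(f"conv3d: input has {cin} channels, kernel expects {cin_w}")
    do, ho, wo = (_conv_out_len(m, k, stride, pad) for m in (d, h, wd))
    if min(do, ho, wo) < 1:
        raise ValueError(
            f"conv3d: spatial size {(d, h, wd)} too small for kernel {k} stride {stride}"
        )
    xp = np.pad(xd, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else xd
    wf = w.data
    w2 = wf.reshape(cout, cin * k**3)

    # depth-slab chunking keeps the materialised im2col matrix bounded
    col_bytes = n * cin * do * ho * wo * k**3 * xd.dtype.itemsize
    n_chunks = max(1, int(np.ceil(col_bytes / (256 * 2**20))))
    chunk = max(1, int(np.ceil(do / n_chunks)))

    def slabs():
        for d0 in range(0, do, chunk):
            yield d0, min(d0 + chunk, do)

    def im2col(d0, d1):
        """Column matrix (cin*k^3, n*dd*ho*wo) for output depths [d0, d1)."""
        dd = d1 - d0
        cols = np.empty((cin, k, k, k, n, dd, ho, wo), dtype=xp.dtype)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    view = xp[
                        :, :,
                        d0 * stride + a : d0 * stride + a + stride * (dd - 1) + 1 : stride,
                        bb : bb + stride * (ho - 1) + 1 : stride,
                        c : c + stride * (wo - 1) + 1 : stride,
                    ]
                    cols[:, a, bb, c] = view.transpose(1, 0, 2, 3, 4)
        return cols.reshape(cin * k**3, n * dd * ho * wo)

    out = np.empty((cout, n, do, ho, wo), dtype=xd.dtype)
    for d0, d1 in slabs():
        out[:, :, d0:d1] = (w2 @ im2col(d0, d1)).reshape(cout, n, d1 - d0, ho, wo)
    out = np.ascontiguousarray(np.moveaxis(out, 0, 1))
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward_full(g):
        if b is not None:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
        need_w, need_x = w.requires_grad, x.requires_grad
        gw = np.zeros((cout, cin * k**3), dtype=wf.dtype) if need_w else None
        gxp = np.zeros(xp.shape, dtype=xd.dtype) if need_x else None
        for d0, d1 in slabs():
            dd = d1 - d0
            g2 = np.ascontiguousarray(
                np.moveaxis(g[:, :, d0:d1], 1, 0)
            ).reshape(cout, n * dd * ho * wo)
            cols = im2col(d0, d1) if need_w else None
            if need_w:
                gw += g2 @ cols.T
            if need_x:
                gcols = (w2.T @ g2).reshape(cin, k, k, k, n, dd, ho, wo)
                for a in range(k):
                    for bb in range(k):
                        for c in range(k):
                            sl = (
                                slice(None), slice(None),
                                slice(
                                    d0 * stride + a,
                                    d0 * stride + a + stride * (dd - 1) + 1,
                                    stride,
                                ),
                                slice(bb, bb + stride * (ho - 1) + 1, stride),
                                slice(c, c + stride * (wo - 1) + 1, stride),
                            )
                            gxp[sl] += gcols[:, a, bb, c].transpose(1, 0, 2, 3, 4)
        if need_w:
            w.accumulate(gw.reshape(wf.shape))
        if need_x:
            if pad:
                x.accumulate(gxp[:, :, pad:-pad, pad:-pad, pad:-pad])
            else:
                x.accumulate(gxp)

    return Var(out, parents, backward_full)


# ---------------------------------------------------------------------------
# batch normalisation


def batchnorm3d(
    x: Var,
    gamma: Var,
    beta: Var,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Var:
    """Channel-wise batch normalisation for NCDHW tensors.

    Running statistics are updated in place when ``training`` is true.
    """
    xd = x.data
    c = xd.shape[1]
    shape = (1, c, 1, 1, 1)
    if training:
        axes = (0, 2, 3, 4)
        mu = xd.mean(axis=axes)
        var = xd.var(axis=axes)
        m = xd.size // c
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased variance in the running estimate, as is conventional
        running_var += momentum * var * (m / max(m - 1, 1))
        ivar = 1.0 / np.sqrt(var + eps)
        xhat = (xd - mu.reshape(shape)) * ivar.reshape(shape)
        out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

        def backward(g):
            gamma.accumulate((g * xhat).sum(axis=axes))
            beta.accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gxh = g * gamma.data.reshape(shape)
                s1 = gxh.sum(axis=axes).reshape(shape)
                s2 = (gxh * xhat).sum(axis=axes).reshape(shape)
                gx = (ivar.reshape(shape) / m) * (m * gxh - s1 - xhat * s2)
                x.accumulate(gx)

        return Var(out, (x, gamma, beta), backward)

    ivar = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * ivar).reshape(shape)
    out = scale * (xd - running_mean.reshape(shape)) + beta.data.reshape(shape)

    def backward_eval(g):
        axes = (0, 2, 3, 4)
        xh = (xd - running_mean.reshape(shape)) * ivar.reshape(shape)
        gamma.accumulate((g * xh).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            x.accumulate(g * scale)

    return Var(out, (x, gamma, beta), backward_eval)


# ---------------------------------------------------------------------------
# resampling


def avgpool2(x: Var) -> Var:
    """Average pooling with a 2^3 window and stride 2 (even sizes only)."""
    xd = x.data
    n, c, d, h, w = xd.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avgpool2 requires even spatial sizes, got {(d, h, w)}")
    r = xd.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = r.mean(axis=(3, 5, 7))

    def backward(g):
        if x.requires_grad:
            gx = np.broadcast_to(
                g[:, :, :, None, :, None, :, None] / 8.0,
                (n, c, d // 2, 2, h // 2, 2, w // 2, 2),
            ).reshape(xd.shape)
            x.accumulate(gx)

    return Var(out, (x,), backward)


def _up1d(a: np.ndarray, axis: int) -> np.ndarray:
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    out = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    # half-pixel-centred linear interpolation, edges clamped
    out[..., 0::2] = 0.75 * a
    out[..., 0] += 0.25 * a[..., 0]
    out[..., 2::2] += 0.25 * a[..., :-1]
    out[..., 1::2] = 0.75 * a
    out[..., -1] += 0.25 * a[..., -1]
    out[..., 1:-1:2] += 0.25 * a[..., 1:]
    return np.moveaxis(out, -1, axis)


def _up1d_t(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of :func:`_up1d` for the backward pass."""
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    gx = 0.75 * (ge + go)
    gx[..., 0] += 0.25 * ge[..., 0]
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., -1] += 0.25 * go[..., -1]
    gx[..., 1:] += 0.25 * go[..., :-1]
    return np.moveaxis(gx, -1, axis)


def upsample2_linear(x: Var) -> Var:
    """Factor-2 trilinear upsampling (separable, half-pixel centres)."""
    out = x.data
    for ax in (2, 3, 4):
        out = _up1d(out, ax)

    def backward(g):
        if x.requires_grad:
            for ax in (4, 3, 2):
                g = _up1d_t(g, ax)
            x.accumulate(g)

    return Var(out, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise and structural ops


def relu(x: Var) -> Var:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        x.accumulate(g * mask)

    return Var(out, (x,), backward)


def leaky_relu(x: Var, slope: float = 0.2) -> Var:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)

    def backward(g):
        x.accumulate(g * np.where(mask, 1.0, slope))

    return Var(out, (x,), backward)


def tanh(x: Var) -> Var:
    out = np.tanh(x.data)

    def backward(g):
        x.accumulate(g * (1.0 - out * out))

    return Var(out, (x,), backward)


def softplus(x: Var) -> Var:
    """log(1 + e^x), evaluated stably; the BCE-with-logits building block."""
    out = np.logaddexp(0.0, x.data)

    def backward(g):
        x.accumulate(g / (1.0 + np.exp(-x.data)))

    return Var(out, (x,), backward)


def neg(x: Var) -> Var:
    return Var(-x.data, (x,), lambda g: x.accumulate(-g))


def sub(a: Var, b: Var) -> Var:
    a, b = as_var(a), as_var(b)

    def backward(g):
        a.accumulate(g)
        b.accumulate(-g)

    return Var(a.data - b.data, (a, b), backward)


def add(a: Var, b: Var) -> Var:
    a, b = as_var(a), as_var(b)

    def backward(g):
        a.accumulate(g)
        b.accumulate(g)

    return Var(a.data + b.data, (a, b), backward)


def scale(x: Var, s: float) -> Var:
    return Var(x.data * s, (x,), lambda g: x.accumulate(g * s))


def square(x: Var) -> Var:
    return Var(x.data**2, (x,), lambda g: x.accumulate(2.0 * g * x.data))


def absolute(x: Var) -> Var:
    sgn = np.sign(x.data)
    return Var(np.abs(x.data), (x,), lambda g: x.accumulate(g * sgn))


def mean(x: Var) -> Var:
    n = x.data.size

    def backward(g):
        x.accumulate(np.full(x.data.shape, g / n, dtype=x.data.dtype))

    return Var(np.asarray(x.data.mean()), (x,), backward)


def total(x: Var) -> Var:
    def backward(g):
        x.accumulate(np.full(x.data.shape, g, dtype=x.data.dtype))

    return Var(np.asarray(x.data.sum()), (x,), backward)


def axis_diff(x: Var, axis: int) -> Var:
    """Differences between consecutive elements along ``axis``."""
    out = np.diff(x.data, axis=axis)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            sl_hi = [slice(None)] * x.data.ndim
            sl_lo = [slice(None)] * x.data.ndim
            sl_hi[axis] = slice(1, None)
            sl_lo[axis] = slice(None, -1)
            gx[tuple(sl_hi)] += g
            gx[tuple(sl_lo)] -= g
            x.accumulate(gx)

    return Var(out, (x,), backward)


def concat(parts: list[Var], axis: int = 1) -> Var:
    datas = [p.data for p in parts]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p.accumulate(g[tuple(sl)])

    return Var(out, tuple(parts), backward)
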