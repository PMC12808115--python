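"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports higher-order differentiation: every op's vector-Jacobian product is
itself expressed with these same ops, so ``grad(..., create_graph=True)``
returns tensors that can be differentiated again. This is what the
Wasserstein-GAN gradient penalty needs (a gradient-of-gradient-norm term in
the critic objective).

Conventions: image tensors are (batch, channels, rows, cols) float32 by
default; gradients are accumulated in the dtype of the forward data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "grad", "no_grad"]


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    a = np.asarray(x)
    if dtype is not None and a.dtype != dtype:
        a = a.astype(dtype)
    return a


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "requires_grad", "parents", "vjp", "name")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad=False, parents=(), vjp=None, name=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.parents = tuple(parents)
        self.vjp = vjp
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def numpy(self):
        return self.data

    def item(self):
        return float(self.data)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / _as_array(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)


def tensor(data, requires_grad=False, dtype=np.float32):
    return Tensor(_as_array(data, dtype=dtype), requires_grad=requires_grad)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, vjp):
    if _GradMode.enabled and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, vjp=vjp)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum gradient g down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(a.data + b.data, (a, b), vjp)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return _make(a.data * b.data, (a, b), vjp)


def power(a, p: float):
    a = _wrap(a)
    p = float(p)

    def vjp(g):
        return (mul(g, mul(power(a, p - 1.0), p)),)

    return _make(a.data ** p, (a,), vjp)


def exp(a):
    a = _wrap(a)
    out_data = np.exp(a.data)

    def vjp(g):
        # recompute exp(a) as a graph node so higher-order grads flow
        return (mul(g, exp(a)),)

    return _make(out_data, (a,), vjp)


def log(a):
    a = _wrap(a)

    def vjp(g):
        return (mul(g, power(a, -1.0)),)

    return _make(np.log(a.data), (a,), vjp)


def sigmoid(a):
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def vjp(g):
        s = sigmoid(a)
        return (mul(g, mul(s, add(1.0, mul(s, -1.0)))),)

    return _make(out_data, (a,), vjp)


def silu(a):
    """x * sigmoid(x), the default activation in the networks here."""
    a = _wrap(a)
    return mul(a, sigmoid(a))


def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.shape

    def vjp(g):
        if axis is None:
            gg = reshape(g, (1,) * len(in_shape))
        elif not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % len(in_shape) for ax in axes)
            shp = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
            gg = reshape(g, shp)
        else:
            gg = g
        return (broadcast_to(gg, in_shape),)

    return _make(out_data, (a,), vjp)


def mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape):
    a = _wrap(a)
    shape = tuple(shape)
    in_shape = a.shape

    def vjp(g):
        return (_unbroadcast(g, in_shape),)

    return _make(np.broadcast_to(a.data, shape), (a,), vjp)


def reshape(a, shape):
    a = _wrap(a)
    shape = tuple(shape)
    in_shape = a.shape

    def vjp(g):
        return (reshape(g, in_shape),)

    return _make(a.data.reshape(shape), (a,), vjp)


def transpose(a, axes=None):
    a = _wrap(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return _make(a.data.transpose(axes), (a,), vjp)


def getitem(a, idx):
    a = _wrap(a)
    in_shape = a.shape

    def vjp(g):
        return (scatter(g, idx, in_shape),)

    return _make(a.data[idx], (a,), vjp)


def scatter(g, idx, shape):
    """Zeros of ``shape`` with ``g`` added at ``idx`` (adjoint of getitem)."""
    g = _wrap(g)

    def vjp(gg):
        return (getitem(gg, idx),)

    out = np.zeros(shape, dtype=g.dtype)
    np.add.at(out, idx, g.data)
    return _make(out, (g,), vjp)


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(getitem(g, tuple(sl)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul expects 2-D operands")

    def vjp(g):
        return matmul(g, transpose(b)), matmul(transpose(a), g)

    return _make(a.data @ b.data, (a, b), vjp)


def flip2(a):
    """Flip the two trailing (spatial) axes."""
    a = _wrap(a)

    def vjp(g):
        return (flip2(g),)

    return _make(a.data[..., ::-1, ::-1].copy(), (a,), vjp)


# --------------------------------------------------------------------------
# convolution primitives (stride 1, 'same' zero padding, odd kernel)
# --------------------------------------------------------------------------

def _im2col(x, kh, kw):
    """(B, C, H, W) -> ((kh*kw*C), B*H*W) patch matrix, 'same' zero padding.

    Built from whole-plane slice copies (leading-axis transposes move
    contiguous blocks), which is far cheaper than a windowed-view copy.
    """
    b, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xpt = np.zeros((c, b, h + 2 * ph, w + 2 * pw), x.dtype)
    xpt[:, :, ph : ph + h, pw : pw + w] = x.transpose(1, 0, 2, 3)
    cols = np.empty((kh * kw, c, b, h, w), x.dtype)
    k = 0
    for i in range(kh):
        for j in range(kw):
            cols[k] = xpt[:, :, i : i + h, j : j + w]
            k += 1
    return cols.reshape(kh * kw * c, b * h * w)


def _conv2d_raw(x, w):
    """Full-plane GEMM followed by contiguous shifted accumulation: one
    (kh*kw*O x C) GEMM on the padded planes, then kh*kw flat shifted adds.
    Avoids building a patch matrix entirely."""
    o, c, kh, kw = w.shape
    b, _, h, wd = x.shape
    if kh == 1 and kw == 1:
        xt = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, -1)
        out = (w[:, :, 0, 0] @ xt).reshape(o, b, h, wd)
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))
    ph, pw = kh // 2, kw // 2
    hp, wp = h + 2 * ph, wd + 2 * pw
    xpt = np.zeros((c, b, hp, wp), x.dtype)
    xpt[:, :, ph : ph + h, pw : pw + wd] = x.transpose(1, 0, 2, 3)
    wall = np.ascontiguousarray(w.transpose(2, 3, 0, 1)).reshape(kh * kw * o, c)
    out9 = (wall @ xpt.reshape(c, -1)).reshape(kh * kw, o, b, hp * wp)
    m = (h - 1) * wp + wd
    acc = np.zeros((o, b, h * wp), x.dtype)
    target = acc[:, :, :m]
    k = 0
    for i in range(kh):
        for j in range(kw):
            off = i * wp + j
            target += out9[k, :, :, off : off + m]
            k += 1
    res = acc.reshape(o, b, h, wp)[:, :, :, :wd]
    return np.ascontiguousarray(res.transpose(1, 0, 2, 3))


def _conv2d_wgrad_raw(x, g, kh, kw):
    b, c, h, w = x.shape
    o = g.shape[1]
    cols = _im2col(x, kh, kw)  # (kh*kw*C, B*H*W)
    gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, b * h * w)
    dw = (gt @ cols.T).reshape(o, kh, kw, c)
    return np.ascontiguousarray(dw.transpose(0, 3, 1, 2))


def conv2d(x, w):
    """2-D cross-correlation, stride 1, zero 'same' padding, odd kernel.

    x: (B, C, H, W); w: (O, C, kh, kw) -> (B, O, H, W).
    """
    x, w = _wrap(x), _wrap(w)
    kh, kw = w.shape[2], w.shape[3]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes")

    def vjp(g):
        # d/dx: convolve g with spatially flipped, in/out-swapped kernel
        gx = conv2d(g, transpose(flip2(w), (1, 0, 2, 3)))
        gw = conv2d_wgrad(x, g, kh, kw)
        return gx, gw

    return _make(_conv2d_raw(x.data, w.data), (x, w), vjp)


def conv2d_wgrad(x, g, kh, kw):
    """Adjoint of conv2d w.r.t. the kernel; bilinear in (x, g)."""
    x, g = _wrap(x), _wrap(g)

    def vjp(dw):
        # directional derivatives of the bilinear map
        vx = conv2d(g, transpose(flip2(dw), (1, 0, 2, 3)))
        vg = conv2d(x, dw)
        return vx, vg

    return _make(_conv2d_wgrad_raw(x.data, g.data, kh, kw), (x, g), vjp)


# --------------------------------------------------------------------------
# pooling / resampling (compositional, hence double-differentiable)
# --------------------------------------------------------------------------

def avg_pool2(x):
    """2x2 average pooling on (B, C, H, W)."""
    x = _wrap(x)
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dims")
    r = reshape(x, (b, c, h // 2, 2, w // 2, 2))
    return mean(r, axis=(3, 5))


def upsample2(x):
    """Nearest-neighbour 2x upsampling on (B, C, H, W)."""
    x = _wrap(x)
    b, c, h, w = x.shape
    r = reshape(x, (b, c, h, 1, w, 1))
    r = broadcast_to(r, (b, c, h, 2, w, 2))
    return reshape(r, (b, c, 2 * h, 2 * w))


def sqrt(a):
    return power(a, 0.5)


# --------------------------------------------------------------------------
# reverse pass
# --------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children after parents; iterate reversed for backprop


def grad(output: Tensor, wrt, grad_output=None, create_graph=False):
    """Gradients of a scalar (or seeded) output w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned tensors participate in the graph
    and can be differentiated again.
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if not output.requires_grad:
        zeros = [Tensor(np.zeros_like(w.data)) for w in wrt_list]
        return zeros[0] if single else zeros
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad of non-scalar output needs grad_output")
        seed = Tensor(np.ones_like(output.data))
    else:
        seed = _wrap(grad_output)

    ctx = no_grad() if not create_graph else None
    if ctx is not None:
        ctx.__enter__()
    try:
        grads = {id(output): seed}
        for node in reversed(_toposort(output)):
            g = grads.get(id(node))
            if g is None or node.vjp is None:
                continue
            parent_grads = node.vjp(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else add(acc, pg)
        out = []
        for w in wrt_list:
            g = grads.get(id(w))
            out.append(g if g is not None else Tensor(np.zeros_like(w.data)))
    finally:
        if ctx is not None:
            ctx.__exit__(None, None, None)
    return out[0] if single else out
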