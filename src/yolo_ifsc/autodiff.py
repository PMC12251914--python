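"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operator set the detection network needs:
strided/dilated/grouped 2-D convolution (via explicit patch extraction and
GEMM), batch normalisation, pooling, nearest-neighbour upsampling, the usual
elementwise activations, softmax, and a numerically stable binary
cross-entropy with logits.  Gradients flow through a dynamically recorded
tape; ``Tensor.backward`` performs a topological sweep exactly once per node.

Arrays are kept in float32 throughout.  Convolution layouts follow the
(N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg
            if t is self or not t._parents:
                pass
        # leaves reached through the dict but never popped (no children visited
        # after them) are handled in the loop above; nothing left to do.

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bw(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / (other.data ** 2),
                                         other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            return ((self, g * 0.5 / np.maximum(out_data, 1e-12)),)

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            return ((self, g / self.data),)

        return Tensor._make(out_data, (self,), bw)

    def atan(self):
        out_data = np.arctan(self.data)

        def bw(g):
            return ((self, g / (1.0 + self.data ** 2)),)

        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def bw(g):
            return ((self, g * sign),)

        return Tensor._make(out_data, (self,), bw)

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi

        def bw(g):
            return ((self, g * mask),)

        return Tensor._make(out_data, (self,), bw)

    def maximum(self, other: "Tensor"):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.maximum(self.data, other.data)
        mask = (self.data >= other.data).astype(np.float32)

        def bw(g):
            return ((self, _unbroadcast(g * mask, self.data.shape)),
                    (other, _unbroadcast(g * (1.0 - mask), other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    def minimum(self, other: "Tensor"):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.minimum(self.data, other.data)
        mask = (self.data <= other.data).astype(np.float32)

        def bw(g):
            return ((self, _unbroadcast(g * mask, self.data.shape)),
                    (other, _unbroadcast(g * (1.0 - mask), other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    # -- activations ----------------------------------------------------------
    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def bw(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor._make(out_data, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out_data = self.data * s

        def bw(g):
            return ((self, g * (s * (1.0 + self.data * (1.0 - s)))),)

        return Tensor._make(out_data, (self,), bw)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bw(g):
            return ((self, g * np.where(mask, 1.0, slope).astype(np.float32)),)

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return ((self, out_data * (g - dot)),)

        return Tensor._make(out_data, (self,), bw)

    def bce_with_logits(self, target: np.ndarray):
        """Elementwise binary cross-entropy on raw logits (stable form)."""
        x, t = self.data, np.asarray(target, dtype=np.float32)
        out_data = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

        def bw(g):
            return ((self, g * (1.0 / (1.0 + np.exp(-x)) - t)),)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions / shape ops ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).astype(np.float32)),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, shape).astype(np.float32)),)

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == expanded).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis if isinstance(axis, tuple) else (axis,))
            return ((self, mask * g),)

        return Tensor._make(out_data, (self,), bw)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            return ((self, g.reshape(src)),)

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def bw(g):
            full = np.zeros(shape, dtype=np.float32)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor._make(out_data, (self,), bw)

    def matmul(self, other: "Tensor"):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.data.shape)),
                    (other, _unbroadcast(gb, other.data.shape)))

        return Tensor._make(out_data, (self, other), bw)

    __matmul__ = matmul


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even under no_grad


# ---------------------------------------------------------------------------
# functional ops on tensors
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        return tuple((t, np.take(g, i, axis=axis)) for i, t in enumerate(tensors))

    return Tensor._make(out_data, tuple(tensors), bw)


def _out_size(size: int, k: int, s: int, p: int, d: int) -> int:
    return (size + 2 * p - d * (k - 1) - 1) // s + 1


def _im2col(xp: np.ndarray, k: int, s: int, d: int, ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C, k, k, ho, wo) patch tensor (copies)."""
    n, c = xp.shape[:2]
    col = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        hi = i * d
        for j in range(k):
            wj = j * d
            col[:, :, i, j] = xp[:, :, hi:hi + (ho - 1) * s + 1:s,
                                 wj:wj + (wo - 1) * s + 1:s]
    return col


def _col2im(gcol: np.ndarray, xp_shape, k: int, s: int, d: int,
            ho: int, wo: int) -> np.ndarray:
    gxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(k):
        hi = i * d
        for j in range(k):
            wj = j * d
            gxp[:, :, hi:hi + (ho - 1) * s + 1:s,
                wj:wj + (wo - 1) * s + 1:s] += gcol[:, :, i, j]
    return gxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Grouped, strided, dilated 2-D cross-correlation.

    weight shape: (C_out, C_in // groups, k, k).
    """
    n, cin, h, w = x.data.shape
    cout, cing, k, _ = weight.data.shape
    assert cin == cing * groups, "channel/group mismatch"
    ho, wo = _out_size(h, k, stride, padding, dilation), _out_size(w, k, stride, padding, dilation)
    parents = (x, weight) if bias is None else (x, weight, bias)

    if k == 1 and padding == 0:
        # pointwise fast path: pure (grouped) matmul, no patch extraction
        xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
        xr = xs.reshape(n, groups, cing, ho * wo)
        wmat = weight.data.reshape(groups, cout // groups, cing)
        out_data = np.matmul(wmat, xr).reshape(n, cout, ho, wo)
        if bias is not None:
            out_data += bias.data.reshape(1, cout, 1, 1)

        def bw1(g):
            gr = g.reshape(n, groups, cout // groups, ho * wo)
            gw = np.matmul(gr, xr.transpose(0, 1, 3, 2)).sum(axis=0)
            gxs = np.matmul(wmat.transpose(0, 2, 1), gr).reshape(n, cin, ho, wo)
            if stride > 1:
                gx = np.zeros_like(x.data)
                gx[:, :, ::stride, ::stride] = gxs
            else:
                gx = gxs
            grads = [(x, gx), (weight, gw.reshape(weight.data.shape))]
            if bias is not None:
                grads.append((bias, g.sum(axis=(0, 2, 3))))
            return tuple(grads)

        return Tensor._make(out_data, parents, bw1)

    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    col = _im2col(xp, k, stride, dilation, ho, wo)          # N,C,k,k,ho,wo

    if groups == cin and cing == 1 and cout == cin:
        # depthwise fast path: per-channel weighted window sum
        colr = col.reshape(n, cin, k * k, ho * wo)
        wd = weight.data.reshape(cout, k * k)
        out_data = np.einsum("nckp,ck->ncp", colr, wd, optimize=True)
        out_data = out_data.reshape(n, cout, ho, wo)
        if bias is not None:
            out_data += bias.data.reshape(1, cout, 1, 1)

        def bwd(g):
            gr = g.reshape(n, cout, ho * wo)
            gw = np.einsum("ncp,nckp->ck", gr, colr, optimize=True)
            gcol = gr[:, :, None, :] * wd[None, :, :, None]
            gxp = _col2im(gcol.reshape(n, cin, k, k, ho, wo), xp.shape,
                          k, stride, dilation, ho, wo)
            gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
            grads = [(x, gx), (weight, gw.reshape(weight.data.shape))]
            if bias is not None:
                grads.append((bias, g.sum(axis=(0, 2, 3))))
            return tuple(grads)

        return Tensor._make(out_data, parents, bwd)

    col = col.reshape(n, groups, cing * k * k, ho * wo)
    wmat = weight.data.reshape(groups, cout // groups, cing * k * k)
    out_data = np.matmul(wmat, col).reshape(n, cout, ho, wo)
    if bias is not None:
        out_data += bias.data.reshape(1, cout, 1, 1)

    def bw(g):
        gr = g.reshape(n, groups, cout // groups, ho * wo)
        gw = np.matmul(gr, col.transpose(0, 1, 3, 2)).sum(axis=0)
        gcol = np.matmul(wmat.transpose(0, 2, 1), gr)
        gcol = gcol.reshape(n, cin, k, k, ho, wo)
        gxp = _col2im(gcol, xp.shape, k, stride, dilation, ho, wo)
        gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
        grads = [(x, gx), (weight, gw.reshape(weight.data.shape))]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._make(out_data, parents, bw)


def max_pool2d(x: Tensor, k: int, stride: int = None, padding: int = 0) -> Tensor:
    stride = stride or k
    n, c, h, w = x.data.shape
    ho, wo = _out_size(h, k, stride, padding, 1), _out_size(w, k, stride, padding, 1)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    col = _im2col(xp, k, stride, 1, ho, wo)                  # N,C,k,k,ho,wo
    flat = col.reshape(n, c, k * k, ho, wo)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        gcol = np.zeros((n, c, k * k, ho, wo), dtype=np.float32)
        np.put_along_axis(gcol, arg[:, :, None], g[:, :, None], axis=2)
        gxp = _col2im(gcol.reshape(n, c, k, k, ho, wo), xp.shape, k, stride, 1, ho, wo)
        if padding:
            return ((x, gxp[:, :, padding:padding + h, padding:padding + w]),)
        return ((x, gxp),)

    return Tensor._make(out_data, (x,), bw)


def avg_pool2d(x: Tensor, k: int, stride: int = None, padding: int = 0) -> Tensor:
    stride = stride or k
    n, c, h, w = x.data.shape
    ho, wo = _out_size(h, k, stride, padding, 1), _out_size(w, k, stride, padding, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    col = _im2col(xp, k, stride, 1, ho, wo)
    out_data = col.mean(axis=(2, 3))

    def bw(g):
        gcol = np.broadcast_to(g[:, :, None, None] / (k * k),
                               (n, c, k, k, ho, wo)).astype(np.float32)
        gxp = _col2im(gcol, xp.shape, k, stride, 1, ho, wo)
        if padding:
            return ((x, gxp[:, :, padding:padding + h, padding:padding + w]),)
        return ((x, gxp),)

    return Tensor._make(out_data, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        n, c, h2, w2 = g.shape
        gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        return ((x, gx),)

    return Tensor._make(out_data, (x,), bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Per-channel batch normalisation on (N,C,H,W)."""
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            m = n * h * w
            t1 = gxhat.sum(axis=(0, 2, 3))
            t2 = (gxhat * xhat).sum(axis=(0, 2, 3))
            gx = (inv[None, :, None, None] / m) * (
                m * gxhat - t1[None, :, None, None] - xhat * t2[None, :, None, None])
        else:
            gx = gxhat * inv[None, :, None, None]
        return ((x, gx.astype(np.float32)), (gamma, ggamma), (beta, gbeta))

    return Tensor._make(out_data, (x, gamma, beta), bw)
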