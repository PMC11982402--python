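"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network needs only a small closed set of differentiable
primitives (n-D convolution, pooling, upsampling, elementwise math and
reductions), all operating on single samples laid out ``(channels, *spatial)``
with no batch axis (the training protocol uses batch size 1). Rather than
depending on a deep-learning framework, those primitives are implemented here
directly and verified against central-difference gradients in the test suite.

Tensors carry float data of any numpy float dtype; models use float32 for
speed, gradient-check tests use float64 for accuracy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "softplus",
    "sqrt",
    "exp",
    "instance_norm",
    "concat",
    "conv_nd",
    "maxpool_down",
    "maxpool_same",
    "avgpool_same",
    "upsample_nearest",
    "matmul",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the graph bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name",
                 "_nconsumers", "_grad_adopted")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name: str | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name
        self._nconsumers = 0
        self._grad_adopted = False
        for p in self._parents:
            p._nconsumers += 1

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}, name={self.name!r})"

    # -- graph --------------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            g = np.asarray(grad, dtype=self.data.dtype)
            if self._nconsumers <= 1 and not self.requires_grad_is_leaf():
                # sole consumer: adopt the buffer (it is never mutated again)
                self.grad = g
                self._grad_adopted = True
            else:
                self.grad = g.copy()
                self._grad_adopted = False
        else:
            if self._grad_adopted:
                self.grad = self.grad.copy()
                self._grad_adopted = False
            self.grad += grad

    def requires_grad_is_leaf(self) -> bool:
        # leaf parameters keep an owned grad buffer (optimizers mutate/read it)
        return self._backward is None and self.requires_grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        in_shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, in_shape).astype(self.data.dtype))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        in_shape = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(in_shape))

        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    d = x.data
    s = np.empty_like(d)
    pos = d >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    s[~pos] = e / (1.0 + e)
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    d = x.data
    s = np.logaddexp(0.0, d).astype(d.dtype)
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            sig = np.empty_like(d)
            pos = d >= 0
            sig[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
            e = np.exp(d[~pos])
            sig[~pos] = e / (1.0 + e)
            x._accumulate(g * sig)

    out._backward = bw
    return out


def sqrt(x: Tensor) -> Tensor:
    s = np.sqrt(x.data)
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * 0.5 / s)

    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * e)

    out._backward = bw
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: Tensor) -> Tensor:
    """Fused per-channel normalization ``gamma*(x-mu)/sqrt(var+eps) + beta``.

    ``x``: (C, *spatial); ``gamma``/``beta``: (C,); ``eps``: scalar tensor
    (already positive). Statistics are per channel over spatial positions.
    Fusing forward and backward avoids a long chain of full-size temporaries.
    """
    nd = x.data.ndim - 1
    sp_axes = _spatial_axes(nd)
    n = int(np.prod(x.data.shape[1:]))
    mu = x.data.mean(axis=sp_axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=sp_axes, keepdims=True)
    std = np.sqrt(var + eps.data)
    xhat = xc / std
    cshape = (x.data.shape[0],) + (1,) * nd
    out = Tensor(gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape),
                 parents=(x, gamma, beta, eps))

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=sp_axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=sp_axes))
        need_x = x.requires_grad
        need_eps = eps.requires_grad
        if not (need_x or need_eps):
            return
        dxhat = g * gamma.data.reshape(cshape)
        m1 = dxhat.mean(axis=sp_axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=sp_axes, keepdims=True)
        if need_x:
            x._accumulate((dxhat - m1 - xhat * m2) / std)
        if need_eps:
            # d/d(eps) of (x-mu)/sqrt(var+eps) = -0.5 * xhat / (var+eps)
            deps = float((-0.5 * n * m2 / (var + eps.data)).sum())
            eps._accumulate(np.asarray(deps, dtype=eps.data.dtype))

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix/vector product for 2-D weights against 1-D or 2-D operands."""
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                a._accumulate(np.outer(g, b.data) if a.data.ndim == 2 else g * b.data)
            else:
                a._accumulate(g @ b.data.T)
        if b.requires_grad:
            if b.data.ndim == 1:
                b._accumulate(a.data.T @ g)
            else:
                b._accumulate(a.data.T @ g)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# spatial primitives: layout (C, *spatial), stride-1 "same" convolution
# ---------------------------------------------------------------------------

def _spatial_axes(nd: int) -> tuple[int, ...]:
    return tuple(range(1, nd + 1))


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """n-D cross-correlation, stride 1, zero 'same' padding.

    ``x``: (Cin, *spatial); ``w``: (Cout, Cin, *k); ``b``: (Cout,) or None.
    Implemented as im2col + GEMM (plain GEMM for 1x1 kernels) so both the
    forward pass and both gradients are single BLAS calls.
    """
    nd = x.data.ndim - 1
    k = w.data.shape[2:]
    if len(k) != nd:
        raise ValueError(f"kernel rank {len(k)} does not match spatial rank {nd}")
    cin = x.data.shape[0]
    cout = w.data.shape[0]
    if w.data.shape[1] != cin:
        raise ValueError(f"conv channel mismatch: input has {cin}, weight expects {w.data.shape[1]}")
    sp = x.data.shape[1:]
    n = int(np.prod(sp))
    K = int(np.prod(k))
    w2 = w.data.reshape(cout, cin * K)

    if K == 1:
        col = x.data.reshape(cin, n)
        xp = None
        offsets = None
    else:
        pad = [(0, 0)] + [((kk - 1) // 2, kk // 2) for kk in k]
        xp = np.pad(x.data, pad)
        offsets = list(np.ndindex(*k))
        col = np.empty((cin, K, n), dtype=x.data.dtype)
        for i, kidx in enumerate(offsets):
            sl = tuple(slice(o, o + s) for o, s in zip(kidx, sp))
            col[:, i, :] = xp[(slice(None),) + sl].reshape(cin, n)
        col = col.reshape(cin * K, n)

    out_data = (w2 @ col).reshape((cout,) + sp)
    if b is not None:
        out_data += b.data.reshape((-1,) + (1,) * nd)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bw(g):
        g2 = g.reshape(cout, n)
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=1))
        if w.requires_grad:
            w._accumulate((g2 @ col.T).reshape(w.data.shape))
        if x.requires_grad:
            dcol = w2.T @ g2  # (cin*K, n)
            if K == 1:
                x._accumulate(dcol.reshape(x.data.shape))
            else:
                dcol = dcol.reshape(cin, K, n)
                dxp = np.zeros_like(xp)
                for i, kidx in enumerate(offsets):
                    sl = tuple(slice(o, o + s) for o, s in zip(kidx, sp))
                    dxp[(slice(None),) + sl] += dcol[:, i, :].reshape((cin,) + sp)
                crop = tuple(slice((kk - 1) // 2, (kk - 1) // 2 + s) for kk, s in zip(k, sp))
                x._accumulate(dxp[(slice(None),) + crop])

    out._backward = bw
    return out


def maxpool_down(x: Tensor) -> Tensor:
    """Max pooling, kernel 2, stride 2, halving every spatial axis.

    Odd extents are padded (by one trailing -inf plane) before pooling.
    """
    nd = x.data.ndim - 1
    sp = x.data.shape[1:]
    pad = [(0, 0)] + [(0, s % 2) for s in sp]
    padded = any(s % 2 for s in sp)
    xp = np.pad(x.data, pad, constant_values=-np.inf) if padded else x.data
    psp = xp.shape[1:]
    # reshape to expose 2-blocks, move block axes last, flatten them
    shape = (xp.shape[0],) + sum(((s // 2, 2) for s in psp), ())
    r = xp.reshape(shape)
    block_axes = tuple(2 + 2 * i for i in range(nd))
    r = np.moveaxis(r, block_axes, tuple(range(-nd, 0)))
    r = r.reshape(r.shape[:1 + nd] + (-1,))
    arg = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dflat = np.zeros(r.shape, dtype=g.dtype)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        d = dflat.reshape(r.shape[:1 + nd] + (2,) * nd)
        d = np.moveaxis(d, tuple(range(-nd, 0)), block_axes)
        d = d.reshape(xp.shape)
        if padded:
            crop = tuple(slice(0, s) for s in sp)
            d = d[(slice(None),) + crop]
        x._accumulate(d)

    out._backward = bw
    return out


def _pool_same(x: Tensor, mode: str) -> Tensor:
    """Kernel-2, stride-1 pooling that preserves spatial shape.

    The trailing edge is padded by one plane (replicated for 'avg',
    -inf for 'max') so windows exist at every position.
    """
    nd = x.data.ndim - 1
    sp = x.data.shape[1:]
    pad = [(0, 0)] + [(0, 1)] * nd
    if mode == "max":
        xp = np.pad(x.data, pad, constant_values=-np.inf)
    else:
        xp = np.pad(x.data, pad, mode="edge")
    offsets = list(np.ndindex(*((2,) * nd)))
    acc = None
    for off in offsets:
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, sp))
        v = xp[sl]
        if acc is None:
            acc = v.copy()
        elif mode == "max":
            np.maximum(acc, v, out=acc)
        else:
            acc += v
    if mode == "avg":
        acc = acc / float(len(offsets))
    out = Tensor(acc, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        if mode == "avg":
            gs = g / float(len(offsets))
        else:
            # route each position's gradient to the first offset attaining the
            # max (recomputed; ties broken by offset order)
            assigned = np.zeros(g.shape, dtype=bool)
        for off in offsets:
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, sp))
            if mode == "max":
                m = (xp[sl] == acc) & ~assigned
                dxp[sl] += np.where(m, g, 0)
                assigned |= m
            else:
                dxp[sl] += gs
        # fold the padded trailing plane back onto the edge (edge-replication
        # adjoint); for 'max' the -inf pad never wins so its grad is zero
        if mode == "avg":
            for axis in range(1, nd + 1):
                s = sp[axis - 1]
                edge_idx = [slice(None)] * dxp.ndim
                edge_idx[axis] = s
                last_idx = [slice(None)] * dxp.ndim
                last_idx[axis] = s - 1
                dxp[tuple(last_idx)] += dxp[tuple(edge_idx)]
        crop = (slice(None),) + tuple(slice(0, s) for s in sp)
        x._accumulate(np.ascontiguousarray(dxp[crop]))

    out._backward = bw
    return out


def maxpool_same(x: Tensor) -> Tensor:
    return _pool_same(x, "max")


def avgpool_same(x: Tensor) -> Tensor:
    return _pool_same(x, "avg")


def upsample_nearest(x: Tensor, target_shape: tuple[int, ...] | None = None) -> Tensor:
    """Nearest-neighbour 2x upsampling of every spatial axis.

    If ``target_shape`` is given the result is cropped to it (inverse of the
    padding maxpool_down applies to odd extents).
    """
    nd = x.data.ndim - 1
    up = x.data
    for axis in range(1, nd + 1):
        up = np.repeat(up, 2, axis=axis)
    full_shape = up.shape[1:]
    if target_shape is not None:
        crop = tuple(slice(0, t) for t in target_shape)
        up = up[(slice(None),) + crop]
    out = Tensor(up, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        if target_shape is not None and tuple(target_shape) != full_shape:
            pad = [(0, 0)] + [(0, f - t) for f, t in zip(full_shape, target_shape)]
            g = np.pad(g, pad)
        # sum over each 2-block
        shape = (g.shape[0],) + sum(((s // 2, 2) for s in full_shape), ())
        r = g.reshape(shape)
        d = r.sum(axis=tuple(2 + 2 * i for i in range(nd)))
        x._accumulate(d)

    out._backward = bw
    return out
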