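"""A minimal reverse-mode automatic differentiation engine on numpy.

Only the primitives the spectrum network needs are implemented: broadcasted
arithmetic, matrix products, dilated 1-D convolution (via im2col + GEMM),
max/average pooling, layer normalization, softmax and a few elementwise
functions. Convolutions are the only hot path; they reduce to single large
GEMMs so the engine runs at BLAS speed. Gradient correctness of every
primitive is established by finite-difference tests.

Tensors are float32 throughout. ``backward()`` may only be called on a
scalar tensor.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


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
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- factory for op results -------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)
        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        """2-D matrix product."""
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._result(out_data, (self, other), bwd)

    # -- elementwise -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        def bwd(g):
            self._accumulate(g * mask)
        return Tensor._result(self.data * mask, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        def bwd(g):
            self._accumulate(g * y * (1.0 - y))
        return Tensor._result(y, (self,), bwd)

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        def bwd(g):
            self._accumulate(g * y)
        return Tensor._result(y, (self,), bwd)

    def log(self, eps: float = 1e-12) -> "Tensor":
        clipped = np.maximum(self.data, eps)
        def bwd(g):
            self._accumulate(g / clipped)
        return Tensor._result(np.log(clipped), (self,), bwd)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        def bwd(g):
            self._accumulate(g * sign)
        return Tensor._result(np.abs(self.data), (self,), bwd)

    def square(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g * 2.0 * self.data)
        return Tensor._result(self.data ** 2, (self,), bwd)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._result(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        def bwd(g):
            self._accumulate(g.reshape(old))
        return Tensor._result(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        def bwd(g):
            self._accumulate(g.transpose(inv))
        return Tensor._result(self.data.transpose(axes), (self,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), bwd)


def broadcast_positions(x: Tensor, n_positions: int) -> Tensor:
    """(B, F) -> (B, n_positions, F) by repetition; backward sums."""
    out_data = np.broadcast_to(
        x.data[:, None, :], (x.data.shape[0], n_positions, x.data.shape[1])
    ).copy()

    def bwd(g):
        x._accumulate(g.sum(axis=1))

    return Tensor._result(out_data, (x,), bwd)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (..., F) @ w (F, O) [+ b (O,)], flattening leading dimensions."""
    lead = x.data.shape[:-1]
    x2 = x.reshape(int(np.prod(lead)) if lead else 1, x.data.shape[-1])
    y = x2.matmul(w)
    if b is not None:
        y = y + b
    return y.reshape(*lead, w.data.shape[-1])


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1) -> Tensor:
    """Dilated 1-D convolution with symmetric 'same' zero padding.

    x: (B, L, C_in); w: (K, C_in, C_out); b: (C_out,). Output (B, L, C_out).
    Implemented as im2col + one GEMM per call.
    """
    B, L, Cin = x.data.shape
    K, WCin, Cout = w.data.shape
    if WCin != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, weight {WCin}")
    span = dilation * (K - 1)
    left = span // 2
    xp = np.empty((B, L + span, Cin), dtype=np.float32)
    if span:
        xp[:, :left, :] = 0.0
        xp[:, left + L:, :] = 0.0
    xp[:, left:left + L, :] = x.data
    s0, s1, s2 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (B, L, K, Cin), (s0, s1, dilation * s1, s2))
    col = view.reshape(B * L, K * Cin)
    w2 = w.data.reshape(K * Cin, Cout)
    y = col @ w2
    if b is not None:
        y = y + b.data
    y = y.reshape(B, L, Cout)

    def bwd(g):
        g2 = g.reshape(B * L, Cout)
        if w.requires_grad:
            w._accumulate((col.T @ g2).reshape(K, Cin, Cout))
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcol = (g2 @ w2.T).reshape(B, L, K, Cin)
            dxp = np.zeros_like(xp)
            for j in range(K):
                dxp[:, j * dilation: j * dilation + L, :] += dcol[:, :, j, :]
            x._accumulate(dxp[:, left:left + L, :])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(y, parents, bwd)


def maxpool1d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling along the length axis of (B, L, C)."""
    B, L, C = x.data.shape
    if L % factor != 0:
        raise ValueError(f"length {L} not divisible by pool factor {factor}")
    xr = x.data.reshape(B, L // factor, factor, C)
    if factor == 2:
        right = xr[:, :, 1, :] > xr[:, :, 0, :]
        y = np.where(right, xr[:, :, 1, :], xr[:, :, 0, :])

        def bwd(g):
            dxr = np.zeros_like(xr)
            dxr[:, :, 1, :] = np.where(right, g, 0.0)
            dxr[:, :, 0, :] = np.where(right, 0.0, g)
            x._accumulate(dxr.reshape(B, L, C))

        return Tensor._result(y, (x,), bwd)
    idx = xr.argmax(axis=2)
    y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def bwd(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[:, :, None, :], g[:, :, None, :], axis=2)
        x._accumulate(dxr.reshape(B, L, C))

    return Tensor._result(y, (x,), bwd)


def avgpool_to(x: Tensor, n_out: int) -> Tensor:
    """Adaptive average pooling of (B, L, C) to (B, n_out, C); L % n_out == 0."""
    B, L, C = x.data.shape
    if L % n_out != 0:
        raise ValueError(f"length {L} not divisible by target {n_out}")
    window = L // n_out
    y = x.data.reshape(B, n_out, window, C).mean(axis=2)

    def bwd(g):
        dx = np.repeat(g[:, :, None, :] / window, window, axis=2)
        x._accumulate(dx.reshape(B, L, C))

    return Tensor._result(y, (x,), bwd)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the trailing (channel) axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = gamma.data * xhat + beta.data
    C = x.data.shape[-1]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(
                (g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            dxhat = g * gamma.data
            dx = (dxhat - dxhat.mean(axis=-1, keepdims=True)
                  - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) * inv
            x._accumulate(dx)

    return Tensor._result(y, (x, gamma, beta), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return Tensor._result(y, (x,), bwd)
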