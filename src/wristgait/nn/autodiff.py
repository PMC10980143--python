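"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's neural networks are small 1-D convolutional models trained on
CPU, so a compact vectorized tape suffices: a :class:`Tensor` wraps an
ndarray, records the operation that produced it, and ``backward`` walks the
tape in reverse topological order accumulating gradients.  Only the
operations the encoder, heads and losses need are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            return (g / self.data,)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            return (g * mask,)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            return (g / (1.0 + np.exp(-self.data)),)

        return self._make(out_data, (self,), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, in_shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(a % len(in_shape) for a in ax)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, in_shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            return (g.reshape(in_shape),)

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        in_shape = self.data.shape

        def backward(g):
            gx = np.zeros(in_shape, dtype=g.dtype)
            np.add.at(gx, idx, g)
            return (gx,)

        return self._make(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """1-D cross-correlation: x (B, Cin, L), w (Cout, Cin, K) -> (B, Cout, Lout).

    Implemented as K shifted tensordots rather than im2col, which keeps both
    the forward and the backward pass allocation-light for small kernels.
    """
    B, Cin, L = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    Lp = L + 2 * padding
    Lout = (Lp - K) // stride + 1
    if Lout < 1:
        raise ValueError("window too short for this convolution")
    xp = np.zeros((B, Cin, Lp), dtype=x.data.dtype)
    xp[:, :, padding:padding + L] = x.data

    out_data = np.zeros((B, Cout, Lout), dtype=x.data.dtype)
    for k in range(K):
        seg = xp[:, :, k:k + stride * Lout:stride]          # (B, Cin, Lout)
        out_data += np.matmul(w.data[:, :, k], seg)         # (Cout,Cin)@(B,Cin,Lout)
    if b is not None:
        out_data += b.data[None, :, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gxp = np.zeros((B, Cin, Lp), dtype=g.dtype)
        gw = np.zeros_like(w.data)
        for k in range(K):
            seg = xp[:, :, k:k + stride * Lout:stride]
            # sum over batch and length: (B,Cout,Lout) x (B,Cin,Lout) -> (Cout,Cin)
            gw[:, :, k] = np.tensordot(g, seg, axes=([0, 2], [0, 2]))
            gxp[:, :, k:k + stride * Lout:stride] += np.matmul(w.data[:, :, k].T, g)
        gx = gxp[:, :, padding:padding + L] if padding else gxp
        if b is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2)))

    return Tensor._make(out_data, parents, backward)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused per-channel batch normalization over axes (0, 2) of (B, C, L).

    Returns (out, batch_mean, batch_var) with the standard closed-form
    backward; fusing avoids the long primitive chain a composed version
    would put on the tape.
    """
    B, C, L = x.data.shape
    n = B * L
    mu = x.data.mean(axis=(0, 2))
    xc = x.data - mu[None, :, None]
    var = (xc * xc).mean(axis=(0, 2))
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = xc * invstd[None, :, None]
    out_data = xhat * gamma.data[None, :, None] + beta.data[None, :, None]

    def backward(g):
        dbeta = g.sum(axis=(0, 2))
        dgamma = (g * xhat).sum(axis=(0, 2))
        gx_hat = g * gamma.data[None, :, None]
        m1 = gx_hat.mean(axis=(0, 2))
        m2 = (gx_hat * xhat).mean(axis=(0, 2))
        dx = invstd[None, :, None] * (
            gx_hat - m1[None, :, None] - xhat * m2[None, :, None]
        )
        return (dx, dgamma, dbeta)

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out, mu, var


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp built from primitives.

    The max shift is treated as a constant, which leaves the gradient exact.
    """
    shift = np.max(t.data, axis=axis, keepdims=True)
    shifted = t - Tensor(shift)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
    if not keepdims:
        ax = axis % t.data.ndim
        new_shape = tuple(s for i, s in enumerate(out.data.shape) if i != ax)
        out = out.reshape(new_shape)
    return out
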