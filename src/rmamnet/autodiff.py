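"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a 1-D convolutional classifier: broadcast-aware
elementwise ops, matmul, reductions, reshape/transpose, a strided conv1d,
max-pooling and a fused softmax cross-entropy.  Everything is float32.

Gradients accumulate into ``Tensor.grad`` during :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order.  All gradient
formulas are exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "maxpool1d", "softmax_cross_entropy"]

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._op(out_data, (self,), bw)

    # -- nonlinearities ----------------------------------------------------

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._op(s, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._op(self.data * mask, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            self._accumulate(g * e)

        return Tensor._op(e, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._op(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(DTYPE))

        return Tensor._op(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor._op(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._op(self.data.transpose(axes), (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor._op(self.data @ other.data, (self, other), bw)


# -- convolution primitives ------------------------------------------------


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: str | int = "same") -> Tensor:
    """1-D convolution (cross-correlation) over (B, C_in, L) input.

    ``weight`` has shape (C_out, C_in, K).  ``padding="same"`` keeps
    L_out = ceil(L / stride); an integer pads both sides by that amount.
    """
    B, C, L = x.shape
    Cout, Cin, K = weight.shape
    if Cin != C:
        raise ValueError(f"input has {C} channels, weight expects {Cin}")
    if padding == "same":
        total = max((-(-L // stride) - 1) * stride + K - L, 0)
        pl, pr = total // 2, total - total // 2
    elif padding == "valid":
        pl = pr = 0
    else:
        pl = pr = int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    Lp = xp.shape[2]
    Lout = (Lp - K) // stride + 1
    # im2col: (B, C, Lout, K) -> (B*Lout, C*K)
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * Lout, C * K)
    wmat = weight.data.reshape(Cout, C * K)
    out = (cols2 @ wmat.T).reshape(B, Lout, Cout).transpose(0, 2, 1)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lout, Cout)
        if weight.requires_grad:
            weight._accumulate((g2.T @ cols2).reshape(Cout, C, K))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = (g2 @ wmat).reshape(B, Lout, C, K).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, :, k : k + stride * Lout : stride] += dcols[:, :, :, k]
            x._accumulate(dxp[:, :, pl : Lp - pr] if pr else dxp[:, :, pl:])

    return Tensor._op(out, parents, bw)


def maxpool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling with stride = kernel; trailing remainder dropped."""
    B, C, L = x.shape
    m = L // kernel
    if m == 0:
        raise ValueError(f"length {L} shorter than pool kernel {kernel}")
    xr = x.data[:, :, : m * kernel].reshape(B, C, m, kernel)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def bw(g):
        gr = np.zeros((B, C, m, kernel), dtype=DTYPE)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=3)
        gx = np.zeros_like(x.data)
        gx[:, :, : m * kernel] = gr.reshape(B, C, m * kernel)
        x._accumulate(gx)

    return Tensor._op(out, (x,), bw)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy over a batch; returns (loss, softmax probabilities)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    targets = np.asarray(targets, dtype=np.int64)
    nll = -np.log(np.maximum(probs[np.arange(n), targets], 1e-12)).mean()

    def bw(g):
        d = probs.copy()
        d[np.arange(n), targets] -= 1.0
        logits._accumulate(g * d / n)

    return Tensor._op(nll, (logits,), bw), probs
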