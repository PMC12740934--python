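"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the primitives needed by the spiking-Transformer
stack are provided (broadcasted arithmetic, batched matmul, reductions,
sigmoid/exp/log, softmax, 1-D convolution via im2col, max-pooling, layer
normalisation, dropout).  Gradients follow the dtype of the data, so float64
inputs give float64 gradients suitable for finite-difference checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
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

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _lift(x, dtype=None) -> "Tensor":
        """Wrap a value; bare float scalars adopt ``dtype`` (weak promotion)."""
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if (
            dtype is not None
            and arr.ndim == 0
            and arr.dtype.kind == "f"
            and np.dtype(dtype).kind == "f"
        ):
            arr = arr.astype(dtype)
        return Tensor(arr)

    def __add__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data + other.data

        def backward(grad):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data * other.data

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data / other.data

        def backward(grad):
            return (
                _unbroadcast(grad / other.data, self.shape),
                _unbroadcast(-grad * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(grad):
            return (grad * p * self.data ** (p - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(grad):
            a, b = self.data, other.data
            ga = grad @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ grad
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._from_op(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(grad):
            g = np.zeros_like(self.data)
            np.add.at(g, idx, grad)
            return (g,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).astype(self.dtype, copy=False),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        out_data = _sigmoid(self.data)
        return Tensor._from_op(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclipped."""
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._from_op(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(grad):
            dot = (grad * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (grad - dot),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- structured primitives ------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Same-padding 1-D convolution.

        ``self``: (B, C_in, L); ``weight``: (C_in*K, C_out) flattened im2col
        layout; ``bias``: (C_out,).  Returns (B, C_out, L).
        """
        B, C, L = self.shape
        CK, F = weight.shape
        K = CK // C
        pad = K // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (pad, K - 1 - pad)))
        # cols[b, l, c, k] = xp[b, c, l + k]
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C,L,K)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, L, CK)
        out = cols @ weight.data + bias.data  # (B, L, F)
        out_data = out.transpose(0, 2, 1)  # (B, F, L)

        def backward(grad):
            g = grad.transpose(0, 2, 1)  # (B, L, F)
            gw = cols.reshape(B * L, CK).T @ g.reshape(B * L, F)
            gb = g.sum(axis=(0, 1))
            dcols = (g @ weight.data.T).reshape(B, L, C, K)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k : k + L] += dcols[:, :, :, k].transpose(0, 2, 1)
            gx = gxp[:, :, pad : pad + L]
            return (gx, gw, gb)

        return Tensor._from_op(out_data, (self, weight, bias), backward)

    def maxpool1d(self, size: int = 2):
        """Non-overlapping max pooling along the last axis (floor division)."""
        B, C, L = self.shape
        Lo = L // size
        x = self.data[:, :, : Lo * size].reshape(B, C, Lo, size)
        arg = x.argmax(axis=3)
        out_data = np.take_along_axis(x, arg[..., None], axis=3)[..., 0]

        def backward(grad):
            g4 = np.zeros((B, C, Lo, size), dtype=self.dtype)
            np.put_along_axis(g4, arg[..., None], grad[..., None], axis=3)
            gx = np.zeros_like(self.data)
            gx[:, :, : Lo * size] = g4.reshape(B, C, Lo * size)
            return (gx,)

        return Tensor._from_op(out_data, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gamma.data + beta.data

        def backward(grad):
            N = self.shape[-1]
            gxhat = grad * gamma.data
            gx = (
                inv
                / N
                * (
                    N * gxhat
                    - gxhat.sum(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
                )
            )
            axes = tuple(range(grad.ndim - 1))
            return (gx, (grad * xhat).sum(axis=axes), grad.sum(axis=axes))

        return Tensor._from_op(out_data, (self, gamma, beta), backward)

    def dropout(self, p: float, rng: np.random.Generator):
        """Inverted dropout; identity when p == 0."""
        if p <= 0.0:
            return self
        keep = (rng.random(self.shape) >= p).astype(self.dtype)
        scale = 1.0 / (1.0 - p)
        mask = keep * scale
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    # -- backward pass --------------------------------------------------------

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            if node is self or node._parents == ():
                node.grad = g if node.grad is None else node.grad + g


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
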