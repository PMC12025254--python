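"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine in the micrograd style, providing exactly the
operations the models in this package need: broadcasting arithmetic,
(batched) matmul, elementwise nonlinearities, axis reductions, reshapes,
fancy indexing, strided 1-D convolution and max-pooling. Gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_shared = False

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        # copy-on-write: adopt the first contribution by reference; make an
        # owned array only if a second contribution arrives
        if self.grad is None:
            self.grad = grad
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + grad
            self._grad_shared = False
        else:
            self.grad += grad

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        )
        self._grad_shared = False
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def __pow__(self, exponent: float) -> "Tensor":
        return self.pow(exponent)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data)
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                elif other.data.ndim == 1:
                    gb = (np.swapaxes(self.data, -1, -2) @ g[..., None])[..., 0]
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def softplus(self) -> "Tensor":
        # numerically stable: log(1 + exp(x)) = max(x, 0) + log1p(exp(-|x|))
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sig)

        return self._make(out_data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            # read-only broadcast view; _accumulate never mutates shared grads
            self._accumulate(np.broadcast_to(g, self.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return self._make(out_data, (self,), backward)


# ---------------------------------------------------------------------------
# Composite and structured operations


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` with the detached-max stabilization."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def conv1d_tokens(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Single-input-channel strided convolution emitting token-major output.

    ``x``: (B, 1, T); ``w``: (C_out, 1, k); output (B, T_out, C_out) — the
    layout the token pipeline consumes, avoiding a transposed copy.
    """
    if x.shape[1] != 1:
        raise ValueError("conv1d_tokens requires a single input channel")
    c_out, _, k = w.shape
    t_out = (x.shape[-1] - k) // stride + 1
    w_mat = w.data.reshape(c_out, k)
    windows = np.lib.stride_tricks.sliding_window_view(x.data[:, 0], k, axis=-1)[:, ::stride]
    out_data = windows @ w_mat.T  # (B, T_out, C_out), contiguous
    if b is not None:
        out_data += b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.tensordot(g, windows, axes=([0, 1], [0, 1])).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = g @ w_mat  # (B, T_out, k)
            gx = np.zeros_like(x.data)
            for j in range(k):
                gx[:, 0, j:j + stride * t_out:stride] += gcols[:, :, j]
            x._accumulate(gx)

    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Strided valid 1-D convolution (cross-correlation).

    ``x``: (B, C_in, T); ``w``: (C_out, C_in, k); output (B, C_out, T_out)
    with ``T_out = (T - k) // stride + 1``.
    """
    batch, c_in, _ = x.shape
    c_out, _, k = w.shape
    t_out = (x.shape[-1] - k) // stride + 1
    w_mat = w.data.reshape(c_out, c_in * k)

    if c_in == 1:
        # batched matmul directly on the strided window view (no im2col copy)
        windows = np.lib.stride_tricks.sliding_window_view(x.data[:, 0], k, axis=-1)[:, ::stride]
        out_data = (windows @ w_mat.T).transpose(0, 2, 1)  # (B, C_out, T_out)
    else:
        windows = np.ascontiguousarray(
            np.lib.stride_tricks.sliding_window_view(x.data, k, axis=-1)[:, :, ::stride]
            .transpose(0, 2, 1, 3)
        ).reshape(batch * t_out, c_in * k)
        out_data = (windows @ w_mat.T).reshape(batch, t_out, c_out).transpose(0, 2, 1)
    if b is not None:
        out_data = out_data + b.data[:, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g_tokens = g.transpose(0, 2, 1)  # (B, T_out, C_out) view
        if w.requires_grad:
            if c_in == 1:
                gw = np.tensordot(g_tokens, windows, axes=([0, 1], [0, 1]))
            else:
                g_flat = np.ascontiguousarray(g_tokens).reshape(batch * t_out, c_out)
                gw = g_flat.T @ windows
            w._accumulate(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            if c_in == 1:
                gcols = (g_tokens @ w_mat)[:, None]  # (B, 1, T_out, k)
            else:
                g_flat = np.ascontiguousarray(g_tokens).reshape(batch * t_out, c_out)
                gcols = (g_flat @ w_mat).reshape(batch, t_out, c_in, k).transpose(0, 2, 1, 3)
            gx = np.zeros_like(x.data)
            for j in range(k):
                gx[:, :, j:j + stride * t_out:stride] += gcols[:, :, :, j]
            x._accumulate(gx)

    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


def maxpool_tokens(x: Tensor, width: int) -> Tensor:
    """Non-overlapping max over the token axis of an (B, T, F) tensor.

    ``T`` must be a multiple of ``width`` (pad first with
    :func:`pad_tokens_edge` if needed).
    """
    b_dim, t, f = x.shape
    if t % width:
        raise ValueError(f"token count {t} not divisible by pool width {width}")
    blocks = x.data.reshape(b_dim, t // width, width, f)
    arg = blocks.argmax(axis=2)
    out_data = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        if x.requires_grad:
            gb = np.zeros_like(blocks)
            np.put_along_axis(gb, arg[:, :, None, :], g[:, :, None, :], axis=2)
            x._accumulate(gb.reshape(x.shape))

    out = Tensor(out_data, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = backward
    return out


def pad_tokens_edge(x: Tensor, n_pad: int) -> Tensor:
    """Right-pad the token axis of an (B, T, F) tensor by edge replication."""
    if n_pad == 0:
        return x
    last = x.data[:, -1:, :]
    out_data = np.concatenate([x.data, np.repeat(last, n_pad, axis=1)], axis=1)
    t = x.shape[1]

    def backward(g):
        if x.requires_grad:
            gx = g[:, :t, :].copy()
            gx[:, -1, :] += g[:, t:, :].sum(axis=1)
            x._accumulate(gx)

    out = Tensor(out_data, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = backward
    return out
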