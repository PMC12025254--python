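"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in vars(self).values():
            for m in (v if isinstance(v, (list, tuple)) else (v,)):
                if isinstance(m, Module):
                    m.set_training(mode)

    def _walk_modules(self, seen: set[int] | None = None):
        seen = set() if seen is None else seen
        if id(self) in seen:
            return
        seen.add(id(self))
        yield self
        for v in vars(self).values():
            for m in (v if isinstance(v, (list, tuple)) else (v,)):
                if isinstance(m, Module):
                    yield from m._walk_modules(seen)

    def _buffer_slots(self) -> list[tuple["Module", str]]:
        return [
            (m, name)
            for m in self._walk_modules()
            for name in getattr(m, "_buffers", ())
        ]

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays needed to restore the module (parameters + buffers)."""
        arrays = [p.data for p in self.parameters()]
        arrays.extend(getattr(m, name) for m, name in self._buffer_slots())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        buffers = self._buffer_slots()
        if len(arrays) != len(params) + len(buffers):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float32)
        for (m, name), a in zip(buffers, arrays[len(params):]):
            setattr(m, name, np.asarray(a, dtype=np.float32))


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(glorot(rng, (d_in, d_out), d_in, d_out))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Strided valid 1-D convolution over (B, C_in, T)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        fan_in = c_in * kernel
        self.weight = Parameter(glorot(rng, (c_out, c_in, kernel), fan_in, c_out))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import conv1d

        return conv1d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm(Module):
    """Batch normalization of feature channels on (B, T, F) tensors.

    Statistics are taken over the batch and token axes per feature; running
    estimates (momentum 0.1) are used in evaluation mode.
    """

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(-1)
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(-1)
            ).astype(np.float32)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only in training mode with an explicit rng."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * Tensor(mask)
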