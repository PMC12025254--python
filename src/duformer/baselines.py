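"""Baseline models for the comparison harness.

Transparent minimal stand-ins sharing DU-former's input/output contract:

* ``SimpleCNN`` — two convolutional layers (temporal then spatial), global
  average pooling, linear softmax head.
* ``EEGNetLike`` — depthwise-separable flavour: shared temporal filters, a
  depthwise spatial filter per temporal filter, average pooling, a second
  (separable-style) temporal convolution, pooled linear head.
* ``PlainTransformer`` — DU-former's convolutional front end and encoder
  depth but with standard quadratic-cost multi-head self-attention and no
  reparameterization head.
"""

from __future__ import annotations

import numpy as np

from .model import ConvBranch, FFN, ModelConfig, ModelOutput
from .nn import (
    BatchNorm,
    Conv1d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    softmax,
)
from .nn.modules import Parameter, glorot

BASELINE_NAMES = ("cnn", "eegnet_like", "plain_transformer")


class _BaselineBase(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.input_scale = 1.0

    def _prepare(self, x) -> Tensor:
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 4:
            arr = arr[:, 0]
        return Tensor(arr / np.float32(self.input_scale))

    def forward(self, x, rng=None, mode: str = "deterministic") -> ModelOutput:
        logits = self._logits(self._prepare(x), rng)
        return ModelOutput(probs=softmax(logits, axis=-1), logits=logits, embedding=None)

    __call__ = forward


class SimpleCNN(_BaselineBase):
    """Two conv layers -> ReLU -> global average pool -> linear head."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        f = config.n_filters
        self.t_conv = Conv1d(1, f, config.temporal_kernel, config.temporal_stride, rng)
        d_spatial = config.n_channels * f
        self.s_weight = Parameter(glorot(rng, (d_spatial, f), d_spatial, f))
        self.s_bias = Parameter(np.zeros(f))
        self.bn = BatchNorm(f)
        self.head = Linear(f, config.n_classes, rng)

    def _logits(self, x: Tensor, rng) -> Tensor:
        b, e, t = x.shape
        f = self.config.n_filters
        h = self.t_conv(x.reshape(b * e, 1, t)).relu()
        t_out = h.shape[-1]
        h = h.reshape(b, e, f, t_out).transpose(0, 3, 1, 2).reshape(b, t_out, e * f)
        h = (h @ self.s_weight + self.s_bias).relu()
        h = self.bn(h)
        return self.head(h.mean(axis=1))


class EEGNetLike(_BaselineBase):
    """Depthwise-separable CNN in the EEGNet spirit, sized down."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        f = config.n_filters
        self.t_conv = Conv1d(1, f, config.temporal_kernel, config.temporal_stride, rng)
        # one spatial filter per temporal filter (depthwise across electrodes)
        self.depthwise = Parameter(
            glorot(rng, (f, config.n_channels), config.n_channels, 1)
        )
        self.bn = BatchNorm(f)
        self.sep_conv = Conv1d(f, f, 8, 4, rng)
        self.ln = LayerNorm(f)
        self.drop = Dropout(config.dropout)
        self.head = Linear(f, config.n_classes, rng)

    def _logits(self, x: Tensor, rng) -> Tensor:
        b, e, t = x.shape
        f = self.config.n_filters
        h = self.t_conv(x.reshape(b * e, 1, t))  # (B*E, F, T')
        t_out = h.shape[-1]
        h = h.reshape(b, e, f, t_out).transpose(0, 3, 2, 1)  # (B, T', F, E)
        h = (h * self.depthwise).sum(axis=-1)  # (B, T', F)
        h = self.bn(h).relu()
        h = self.sep_conv(h.transpose(0, 2, 1)).relu()  # (B, F, T'')
        h = self.ln(h.transpose(0, 2, 1))
        h = self.drop(h, rng)
        return self.head(h.mean(axis=1))


class QuadraticSelfAttention(Module):
    """Standard softmax(QK^T / sqrt(d_h)) V multi-head attention."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = config.embed_dim
        self.n_heads = config.n_heads
        self.head_dim = d // config.n_heads
        self.w_q = Parameter(glorot(rng, (d, d), d, d))
        self.w_k = Parameter(glorot(rng, (d, d), d, d))
        self.w_v = Parameter(glorot(rng, (d, d), d, d))
        self.w_out = Parameter(glorot(rng, (d, d), d, d))
        self.b_out = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.head_dim

        def heads(w):
            return (x @ w).reshape(b, t, h, dh).transpose(0, 2, 1, 3)  # (B, H, T, dh)

        q, k, v = heads(self.w_q), heads(self.w_k), heads(self.w_v)
        scores = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)), axis=-1)
        y = (scores @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return y @ self.w_out + self.b_out


class _QuadraticBlock(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(config.embed_dim)
        self.attn = QuadraticSelfAttention(config, rng)
        self.ln2 = LayerNorm(config.embed_dim)
        self.ffn = FFN(config, rng)
        self.drop = Dropout(config.dropout)

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)), rng)
        return x + self.drop(self.ffn(self.ln2(x)), rng)


class PlainTransformer(_BaselineBase):
    """DU-former front end + conventional quadratic attention, no reparam."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        self.conv_large = ConvBranch(config, "large", rng)
        self.conv_small = ConvBranch(config, "small", rng)
        self.blocks = [_QuadraticBlock(config, rng) for _ in range(config.n_blocks)]
        self.head = Linear(config.embed_dim, config.n_classes, rng)

    def _logits(self, x: Tensor, rng) -> Tensor:
        h = self.conv_large(x) + self.conv_small(x)
        for block in self.blocks:
            h = block(h, rng)
        return self.head(h.mean(axis=1))


def baseline_factory(name: str):
    """Constructor for a named baseline with DU-former's I/O contract."""
    table = {
        "cnn": SimpleCNN,
        "eegnet_like": EEGNetLike,
        "plain_transformer": PlainTransformer,
    }
    try:
        return table[name]
    except KeyError:
        raise ValueError(
            f"unknown baseline {name!r}; valid names: {', '.join(BASELINE_NAMES)}"
        ) from None
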