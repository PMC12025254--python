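"""The DU-former network.

Composition: a dual-branch convolutional front end (shared 1x25 temporal and
16x1 spatial kernels; the "small" branch adds a max-pooling path and layer
normalization) -> elementwise fusion -> two pre-norm Transformer encoder
blocks with separable multi-head self-attention (SMHSA) -> a Gaussian
reparameterization head that models each epoch's embedding as
N(mu, diag(sigma^2)) and samples S = mu + eps * sigma -> linear softmax
classifier.

SMHSA computes, per head, a scalar context logit per token (projection to
one dimension), softmax-normalizes over tokens, pools the K projections into
a single context vector, and gates the (ReLU-activated) V projections with
it — linear in token count, no token x token matrix.

Training minimizes cross-entropy plus an optional KL(N(mu, sigma^2) || N(0, I))
regularizer that keeps the embedding distribution from collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for callers)
    BatchNorm,
    Conv1d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    glorot,
    log_softmax,
    maxpool_tokens,
    pad_tokens_edge,
    softmax,
)
from .nn.modules import Parameter


@dataclass
class ModelConfig:
    """Architecture hyperparameters and ablation switches."""

    n_channels: int = 16
    n_samples: int = 2000
    n_filters: int = 32
    temporal_kernel: int = 25
    spatial_kernel: int = 16
    temporal_stride: int = 5
    small_temporal_stride: int = 1
    embed_dim: int = 32
    n_heads: int = 4
    ffn_expansion: int = 4
    n_blocks: int = 2
    n_classes: int = 2
    dropout: float = 0.0
    kl_weight: float = 1e-4
    sigma_floor: float = 1e-4
    mu_conv_kernel: int = 3
    attention_gate: Literal["relu", "sigmoid"] = "relu"
    fusion: Literal["sum", "concat"] = "sum"
    use_smhsa: bool = True
    use_reparam: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_kernel != self.n_channels:
            raise ValueError("spatial_kernel must equal n_channels")
        if self.embed_dim != self.n_filters:
            raise ValueError("embed_dim must equal n_filters (spatial conv output)")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.small_temporal_stride > self.temporal_stride:
            raise ValueError("small branch stride must not exceed large branch stride")

    @property
    def n_tokens(self) -> int:
        return (self.n_samples - self.temporal_kernel) // self.temporal_stride + 1

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: 16 filters / 16-dim tokens, coarser stride."""
        base = dict(
            n_filters=16, embed_dim=16, temporal_stride=20, small_temporal_stride=5
        )
        base.update(overrides)
        return cls(**base)

    def with_ablation(self, *, use_smhsa: bool | None = None, use_reparam: bool | None = None) -> "ModelConfig":
        return replace(
            self,
            use_smhsa=self.use_smhsa if use_smhsa is None else use_smhsa,
            use_reparam=self.use_reparam if use_reparam is None else use_reparam,
        )


@dataclass
class GaussianEmbedding:
    """The (mu, sigma) feature distribution and its sampled embedding."""

    mu: Tensor
    sigma: Tensor | None
    sample: Tensor


@dataclass
class ModelOutput:
    """Forward-pass result: class probabilities plus the embedding."""

    probs: Tensor
    logits: Tensor
    embedding: GaussianEmbedding | None


def fuse(a: Tensor, b: Tensor) -> Tensor:
    """Fuse the two convolutional branches by elementwise sum."""
    if a.shape != b.shape:
        raise ValueError(f"branch shapes differ: {a.shape} vs {b.shape}")
    return a + b


class ConvBranch(Module):
    """Shared temporal (1 x k) + spatial (n_channels x 1) convolution stack.

    ``variant="large"``: stride ``temporal_stride``, batch norm, ReLU.
    ``variant="small"``: stride ``small_temporal_stride``, ReLU, then a
    max-pooling over tokens whose width is solved so the token count matches
    the large branch, then layer normalization.
    """

    def __init__(self, config: ModelConfig, variant: str, rng: np.random.Generator):
        super().__init__()
        self.variant = variant
        self.config = config
        stride = (
            config.temporal_stride if variant == "large" else config.small_temporal_stride
        )
        self.t_conv = Conv1d(1, config.n_filters, config.temporal_kernel, stride, rng)
        d_spatial = config.n_channels * config.n_filters
        self.s_weight = Parameter(
            glorot(rng, (d_spatial, config.n_filters), d_spatial, config.n_filters)
        )
        self.s_bias = Parameter(np.zeros(config.n_filters))
        if variant == "large":
            self.norm: Module = BatchNorm(config.n_filters)
        else:
            self.norm = LayerNorm(config.n_filters)

    def __call__(self, x: Tensor) -> Tensor:
        from .nn import conv1d_tokens

        b, e, t = x.shape
        f = self.config.n_filters
        h = conv1d_tokens(
            x.reshape(b * e, 1, t), self.t_conv.weight, self.t_conv.bias,
            self.t_conv.stride,
        )  # (B*E, T', F)
        t_out = h.shape[1]
        h = h.reshape(b, e, t_out, f).transpose(0, 2, 1, 3).reshape(b, t_out, e * f)
        h = h @ self.s_weight + self.s_bias  # (B, T', F)
        if self.variant == "large":
            return self.norm(h).relu()
        h = h.relu()
        target = self.config.n_tokens
        if t_out < target:
            raise ValueError("small branch produced fewer tokens than the large branch")
        width = -(-t_out // target)  # ceil
        h = pad_tokens_edge(h, width * target - t_out)
        h = maxpool_tokens(h, width)
        return self.norm(h)


class SMHSA(Module):
    """Separable multi-head self-attention (linear in token count)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d, h = config.embed_dim, config.n_heads
        self.n_heads = h
        self.head_dim = d // h
        self.gate = config.attention_gate
        self.w_i = Parameter(glorot(rng, (d, h), d, 1))
        self.b_i = Parameter(np.zeros(h))
        self.w_k = Parameter(glorot(rng, (d, d), d, d))
        self.b_k = Parameter(np.zeros(d))
        self.w_v = Parameter(glorot(rng, (d, d), d, d))
        self.b_v = Parameter(np.zeros(d))
        self.w_out = Parameter(glorot(rng, (d, d), d, d))
        self.b_out = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        if not np.isfinite(x.data).all():
            raise FloatingPointError("non-finite attention input")
        b, t, d = x.shape
        h, dh = self.n_heads, self.head_dim
        scores = softmax(x @ self.w_i + self.b_i, axis=1)  # (B, T, H)
        k = (x @ self.w_k + self.b_k).reshape(b, t, h, dh)
        v = (x @ self.w_v + self.b_v).reshape(b, t, h, dh)
        context = (scores.reshape(b, t, h, 1) * k).sum(axis=1)  # (B, H, dh)
        gated = v.relu() if self.gate == "relu" else v.sigmoid()
        y = gated * context.reshape(b, 1, h, dh)  # broadcast over tokens
        return y.reshape(b, t, d) @ self.w_out + self.b_out


class FFN(Module):
    """Tokenwise two-layer feed-forward expansion."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = config.embed_dim
        hidden = config.ffn_expansion * d
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class EncoderBlock(Module):
    """Pre-norm residual block: attention sublayer then FFN sublayer.

    With ``use_smhsa=False`` the attention sublayer acts as the identity, so
    the block reduces to a residual FFN.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.use_smhsa = config.use_smhsa
        self.ln1 = LayerNorm(config.embed_dim)
        self.attn = SMHSA(config, rng) if config.use_smhsa else None
        self.ln2 = LayerNorm(config.embed_dim)
        self.ffn = FFN(config, rng)
        self.drop = Dropout(config.dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if self.attn is not None:
            x = x + self.drop(self.attn(self.ln1(x)), rng)
        x = x + self.drop(self.ffn(self.ln2(x)), rng)
        return x


class ReparamHead(Module):
    """Gaussian reparameterization: mu and sigma branches over the tokens.

    mu = LayerNorm(avgpool_tokens(conv1d(features))); sigma =
    softplus(LayerNorm(avgpool_tokens(features))) + floor. In "train"/"mc"
    mode a fresh eps ~ N(0, I) is drawn per sample; "deterministic" mode
    returns S = mu.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = config.embed_dim
        self.floor = config.sigma_floor
        self.mu_conv = Conv1d(d, d, config.mu_conv_kernel, 1, rng)
        self.mu_ln = LayerNorm(d)
        self.sigma_ln = LayerNorm(d)

    def __call__(
        self, x: Tensor, rng: np.random.Generator | None, mode: str
    ) -> GaussianEmbedding:
        h = self.mu_conv(x.transpose(0, 2, 1))  # (B, d, T - k + 1)
        mu = self.mu_ln(h.mean(axis=-1))
        sigma = self.sigma_ln(x.mean(axis=1)).softplus() + self.floor
        if not (np.isfinite(mu.data).all() and np.isfinite(sigma.data).all()):
            raise FloatingPointError("non-finite mu/sigma")
        if mode == "deterministic":
            sample = mu
        else:
            if rng is None:
                raise ValueError(f"mode {mode!r} requires an rng")
            eps = Tensor(rng.standard_normal(mu.shape).astype(np.float32))
            sample = mu + eps * sigma
        return GaussianEmbedding(mu=mu, sigma=sigma, sample=sample)


class DUFormer(Module):
    """The full model. See the module docstring for the composition."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.conv_large = ConvBranch(config, "large", rng)
        self.conv_small = ConvBranch(config, "small", rng)
        self.fusion_proj = (
            Linear(2 * config.embed_dim, config.embed_dim, rng)
            if config.fusion == "concat"
            else None
        )
        self.blocks = [EncoderBlock(config, rng) for _ in range(config.n_blocks)]
        self.reparam = ReparamHead(config, rng) if config.use_reparam else None
        self.head = Linear(config.embed_dim, config.n_classes, rng)
        #: input scale divisor set by the trainer (kept with the checkpoint)
        self.input_scale = 1.0

    # -- forward -----------------------------------------------------------

    def _prepare(self, x) -> Tensor:
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 4:  # (B, 1, E, T)
            arr = arr[:, 0]
        if arr.ndim != 3 or arr.shape[1] != self.config.n_channels:
            raise ValueError(
                f"expected (batch, {self.config.n_channels}, T) input, got {arr.shape}"
            )
        return Tensor(arr / np.float32(self.input_scale))

    def encode(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        a = self.conv_large(x)
        b = self.conv_small(x)
        if self.fusion_proj is not None:
            stacked = np.concatenate([a.data, b.data], axis=-1)
            fused = Tensor(stacked, requires_grad=a.requires_grad or b.requires_grad)
            if fused.requires_grad:  # manual concat backward
                d = a.shape[-1]

                def backward(g, a=a, b=b, d=d):
                    if a.requires_grad:
                        a._accumulate(g[..., :d])
                    if b.requires_grad:
                        b._accumulate(g[..., d:])

                fused._parents = (a, b)
                fused._backward = backward
            h = self.fusion_proj(fused)
        else:
            h = fuse(a, b)
        for block in self.blocks:
            h = block(h, rng)
        return h

    def forward(
        self, x, rng: np.random.Generator | None = None, mode: str = "deterministic"
    ) -> ModelOutput:
        """Classify a batch of epochs.

        ``mode``: "train" / "mc" draw a fresh Gaussian eps per sample;
        "deterministic" uses S = mu. Returns probabilities, logits and the
        Gaussian embedding (``None`` when the reparameterization module is
        ablated, in which case the token-average feature feeds the head).
        """
        if mode not in ("train", "deterministic", "mc"):
            raise ValueError(f"unknown mode {mode!r}")
        xt = self._prepare(x)
        h = self.encode(xt, rng if mode == "train" else None)
        if self.reparam is not None:
            emb = self.reparam(h, rng, mode)
            feats = emb.sample
        else:
            emb = None
            feats = h.mean(axis=1)
        logits = self.head(feats)
        return ModelOutput(probs=softmax(logits, axis=-1), logits=logits, embedding=emb)

    __call__ = forward


# ---------------------------------------------------------------------------
# Loss


def gaussian_kl(mu: Tensor, sigma: Tensor) -> Tensor:
    """Mean over the batch of KL(N(mu, diag sigma^2) || N(0, I))."""
    s2 = sigma * sigma
    per_sample = 0.5 * (s2 + mu * mu - 1.0 - s2.log()).sum(axis=-1)
    return per_sample.mean()


def model_loss(
    output: ModelOutput, labels: np.ndarray, kl_weight: float = 1e-4
) -> Tensor:
    """Cross-entropy plus ``kl_weight`` times the Gaussian KL regularizer.

    With ``kl_weight=0`` (or without a Gaussian embedding) this is plain
    cross-entropy.
    """
    labels = np.asarray(labels, dtype=int)
    logp = log_softmax(output.logits, axis=-1)
    ce = -logp[np.arange(len(labels)), labels].mean()
    if kl_weight and output.embedding is not None and output.embedding.sigma is not None:
        ce = ce + kl_weight * gaussian_kl(output.embedding.mu, output.embedding.sigma)
    return ce
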