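"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with explicit loops and
materialized intermediates, staying independent of the vectorized
implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def smhsa_bruteforce(x: np.ndarray, module) -> np.ndarray:
    """Separable attention evaluated head by head, token by token.

    Explicitly materializes the per-token softmax context scores and the
    weighted sum over tokens, then gates V with the pooled context vector.
    ``module`` supplies the projection parameters.
    """
    w_i = module.w_i.data.astype(np.float64)
    b_i = module.b_i.data.astype(np.float64)
    w_k = module.w_k.data.astype(np.float64)
    b_k = module.b_k.data.astype(np.float64)
    w_v = module.w_v.data.astype(np.float64)
    b_v = module.b_v.data.astype(np.float64)
    w_out = module.w_out.data.astype(np.float64)
    b_out = module.b_out.data.astype(np.float64)
    n_heads, dh = module.n_heads, module.head_dim
    x = x.astype(np.float64)
    batch, tokens, dim = x.shape

    out = np.zeros((batch, tokens, dim))
    for b in range(batch):
        per_head = []
        for h in range(n_heads):
            logits = np.array([x[b, t] @ w_i[:, h] + b_i[h] for t in range(tokens)])
            e = np.exp(logits - logits.max())
            scores = e / e.sum()
            cols = slice(h * dh, (h + 1) * dh)
            k_rows = np.array([x[b, t] @ w_k[:, cols] + b_k[cols] for t in range(tokens)])
            v_rows = np.array([x[b, t] @ w_v[:, cols] + b_v[cols] for t in range(tokens)])
            context = np.zeros(dh)
            for t in range(tokens):
                context += scores[t] * k_rows[t]
            gated = np.maximum(v_rows, 0.0) if module.gate == "relu" else 1 / (1 + np.exp(-v_rows))
            per_head.append(gated * context[None, :])
        concat = np.concatenate(per_head, axis=1)  # (tokens, dim)
        out[b] = concat @ w_out + b_out
    return out


def smhsa_context_vectors(x: np.ndarray, module) -> np.ndarray:
    """Per-head pooled context vectors (batch, heads, head_dim)."""
    w_i = module.w_i.data.astype(np.float64)
    b_i = module.b_i.data.astype(np.float64)
    w_k = module.w_k.data.astype(np.float64)
    b_k = module.b_k.data.astype(np.float64)
    n_heads, dh = module.n_heads, module.head_dim
    x = x.astype(np.float64)
    batch, tokens, _ = x.shape
    out = np.zeros((batch, n_heads, dh))
    for b in range(batch):
        for h in range(n_heads):
            logits = x[b] @ w_i[:, h] + b_i[h]
            e = np.exp(logits - logits.max())
            scores = e / e.sum()
            cols = slice(h * dh, (h + 1) * dh)
            out[b, h] = (scores[:, None] * (x[b] @ w_k[:, cols] + b_k[cols])).sum(axis=0)
    return out


def mwu_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    from scipy.stats import rankdata

    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    offset = n * (n + 1) / 2.0
    u_obs = ranks[:n].sum() - offset
    u_min = min(u_obs, n * m - u_obs)
    count, total = 0, 0
    for group in combinations(range(n + m), n):
        total += 1
        u = ranks[list(group)].sum() - offset
        if min(u, n * m - u) <= u_min + 1e-9:
            count += 1
    return float(u_obs), min(1.0, count / total)
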