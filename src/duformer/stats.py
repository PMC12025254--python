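"""Mann-Whitney U test with exact small-sample p-values.

U is computed from midranks (so ties are handled). The two-sided p-value is
exact for small samples — by the standard count-distribution recurrence
when the pooled data are tie-free, or by full enumeration of group
assignments when ties are present and the combination count is tractable —
and otherwise uses the normal approximation with tie correction and
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy.stats import rankdata

_EXACT_NM_LIMIT = 400  # use an exact p whenever n*m is at most this
_ENUM_LIMIT = 200_000  # full-enumeration budget (number of assignments)


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # "exact", "enumeration" or "asymptotic"


def _exact_cdf_counts(n: int, m: int) -> np.ndarray:
    """Null distribution counts of U over 0..n*m for tie-free samples.

    f(u; n, m) = f(u - m; n - 1, m) + f(u; n, m - 1): either the largest
    observation belongs to the first sample (contributing m to U) or not.
    """
    prev = [np.ones(1) for _ in range(m + 1)]  # i = 0 row: f(0; 0, j) = 1
    for i in range(1, n + 1):
        cur = [np.ones(1)]  # j = 0: f(0; i, 0) = 1
        for j in range(1, m + 1):
            a = np.zeros(i * j + 1)
            a[j:j + prev[j].size] += prev[j]  # largest obs from sample 1
            a[: cur[j - 1].size] += cur[j - 1]  # largest obs from sample 2
            cur.append(a)
        prev = cur
    return prev[m]


def _u_from_ranks(ranks_x: np.ndarray, n: int, m: int) -> float:
    return float(ranks_x.sum() - n * (n + 1) / 2.0)


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test for a location difference.

    Returns U for the first sample and the two-sided p-value. Identical
    samples give U = n*m/2 by midrank symmetry.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = _u_from_ranks(ranks[:n], n, m)
    u2 = n * m - u1
    has_ties = np.unique(pooled).size < pooled.size

    if n * m <= _EXACT_NM_LIMIT and not has_ties:
        counts = _exact_cdf_counts(n, m)
        total = counts.sum()
        u_min = min(u1, u2)
        p = 2.0 * counts[: int(u_min) + 1].sum() / total
        return MannWhitneyResult(u1, min(1.0, p), "exact")

    if n * m <= _EXACT_NM_LIMIT and has_ties and comb(n + m, n) <= _ENUM_LIMIT:
        u_min = min(u1, u2)
        count_le = 0
        total = 0
        idx = np.arange(n + m)
        offset = n * (n + 1) / 2.0
        for group in combinations(idx, n):
            total += 1
            u_g = ranks[list(group)].sum() - offset
            if min(u_g, n * m - u_g) <= u_min + 1e-9:
                count_le += 1
        return MannWhitneyResult(u1, min(1.0, count_le / total), "enumeration")

    # normal approximation with tie correction and continuity correction
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
    var_u = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var_u <= 0:
        return MannWhitneyResult(u1, 1.0, "asymptotic")
    z = (abs(u1 - n * m / 2.0) - 0.5) / sqrt(var_u)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(max(z, 0.0) / sqrt(2.0))))
    return MannWhitneyResult(u1, min(1.0, p), "asymptotic")
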