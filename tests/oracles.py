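"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own interval/score/statistics code:
interval operations are checked against per-base boolean arrays, region
scores against explicit bin enumeration, Poisson tails against direct series
summation, and hypergeometric tails against combinatorial enumeration.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


def base_mask(intervals: Sequence[Interval], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def overlapping_oracle(
    a: Sequence[Interval], b: Sequence[Interval], length: int
) -> List[Interval]:
    mask = base_mask(b, length)
    return [(s, e) for s, e in a if mask[s:e].any()]


def exclusive_oracle(
    a: Sequence[Interval], b: Sequence[Interval], length: int
) -> List[Interval]:
    mask = base_mask(b, length)
    return [(s, e) for s, e in a if not mask[s:e].any()]


def merge_oracle(
    intervals: Sequence[Interval], length: int, max_gap: int = 0
) -> List[Interval]:
    """Union via base painting; gaps <= max_gap bridged by dilation."""
    mask = np.zeros(length + 2 * max_gap + 2, dtype=bool)
    for s, e in intervals:
        mask[s:e + max_gap] = True  # right-dilate, then trim run ends
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    # undo the dilation on each run's right edge using the true base mask
    true_mask = base_mask(intervals, length)
    fixed = []
    for s, e in out:
        e_true = min(e, length)
        while e_true > s and not true_mask[e_true - 1]:
            e_true -= 1
        fixed.append((s, e_true))
    return fixed


def jaccard_oracle(
    a: Sequence[Interval], b: Sequence[Interval], length: int
) -> float:
    ma, mb = base_mask(a, length), base_mask(b, length)
    union = (ma | mb).sum()
    return float((ma & mb).sum() / union) if union else 0.0


def region_score_oracle(
    values: np.ndarray, binsize: int, start: int, end: int
) -> float:
    """Sum of full bin values for every bin overlapping [start, end) >= 1 bp."""
    total = 0.0
    for b in range(len(values)):
        if b * binsize < end and (b + 1) * binsize > start:
            total += values[b]
    return total


def poisson_tail_oracle(k: int, lam: float, terms: int = 2000) -> float:
    """P(X >= k) by direct series summation of the Poisson pmf."""
    if k <= 0:
        return 1.0
    below = 0.0
    term = math.exp(-lam)
    for j in range(0, k):
        below += term
        term *= lam / (j + 1)
    return max(0.0, 1.0 - below)


def hypergeom_tail_oracle(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n) by enumeration."""
    denom = math.comb(M, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(M - K, n - j)
    return total / denom


def bh_oracle(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg by the definitional min-over-larger-p formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    ranks = {}
    for r, i in enumerate(order, 1):
        ranks[i] = r
    out = []
    for i in range(m):
        q = min(
            min(m * pvalues[j] / ranks[j]
                for j in range(m) if pvalues[j] >= pvalues[i]),
            1.0,
        )
        out.append(q)
    return out


def random_interval_list(
    rng: np.random.Generator, n: int, length: int, max_len: int = 2_000
) -> List[Interval]:
    starts = rng.integers(0, length - 1, size=n)
    lens = rng.integers(1, max_len, size=n)
    return [(int(s), int(min(s + l, length))) for s, l in zip(starts, lens)]
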