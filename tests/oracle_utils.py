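"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exact rational hypergeometric tails,
enumeration over all arrangements, and column-wise AND counting.  These
routines never call the package's own DP/matrix-multiplication paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def exact_tail(n: int, m: int, t: int, k: int) -> Fraction:
    """Exact P(H >= k) for H ~ Hypergeometric(n, m, t)."""
    total = math.comb(n, t)
    acc = sum(
        math.comb(m, j) * math.comb(n - m, t - j)
        for j in range(max(k, 0), min(t, m) + 1)
    )
    return Fraction(acc, total)


@lru_cache(maxsize=None)
def all_arrangements(n: int, m: int) -> tuple[tuple[int, ...], ...]:
    return tuple(
        a for a in itertools.product((0, 1), repeat=n) if sum(a) == m
    )


def oracle_statistic(
    labels: tuple[int, ...], X: int, L: int
) -> tuple[Fraction, int]:
    """Exact XL-constrained minimal tail and smallest attaining threshold."""
    n = len(labels)
    m = sum(labels)
    tails = []
    k = 0
    for t in range(1, min(L, n) + 1):
        k += labels[t - 1]
        if k >= X:
            tails.append((exact_tail(n, m, t, k), t))
    if not tails:
        return Fraction(1), 0
    best = min(f for f, _ in tails)
    t_star = min(t for f, t in tails if f == best)
    return best, t_star


def oracle_pvalue(stat: Fraction, n: int, m: int, X: int, L: int) -> Fraction:
    """Exact P(S <= stat) by enumerating every arrangement."""
    arrs = all_arrangements(n, m)
    hits = sum(1 for a in arrs if oracle_statistic(a, X, L)[0] <= stat)
    return Fraction(hits, len(arrs))


def brute_force_panel_counts(
    binary: np.ndarray, member: np.ndarray, genes: tuple[int, ...]
) -> tuple[int, int]:
    """(total positives, positives in cluster) by direct column-wise AND."""
    mask = np.ones(binary.shape[1], dtype=bool)
    for g in genes:
        mask &= binary[g].astype(bool)
    return int(mask.sum()), int(mask[member].sum())
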