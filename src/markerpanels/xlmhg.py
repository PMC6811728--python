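"""XL-constrained minimal-hypergeometric (XL-mHG) threshold test.

Given a binary cluster-membership vector sorted by decreasing expression of a
gene, the test scans prefixes ("thresholds") of the sorted vector, scores each
prefix with a hypergeometric upper-tail probability, and takes the minimum as
the test statistic.  Two integer parameters constrain the scan: ``X`` is the
minimum number of in-cluster cells that must sit above an admissible
threshold, and ``L`` is the deepest threshold examined.  An exact p-value for
the minimized statistic is computed by dynamic programming over the lattice of
(position, ones-seen) states under the null of a uniformly random arrangement
of the ones.

All tail probabilities are handled in log-space so the test stays usable for
tens of thousands of cells without underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

__all__ = [
    "RankedMembership",
    "XLParams",
    "XlmhgResult",
    "rank_membership",
    "hg_tail_pvalue",
    "mhg_statistic",
    "mhg_pvalue",
    "mhg_pvalue_batch",
    "default_xl",
    "xlmhg_test",
]

# Boundary tolerance (log-space) when matching lattice tails against the
# observed statistic; covers float round-off on exactly tied tail values.
_LOG_TOL = 1e-9
# Largest full tail grid kept in memory / LRU-cached, in cells.
_MAX_CACHED_CELLS = 30_000_000
_BLOCK_ROWS = 1024
_TINY = 1e-300

TIE_BACKGROUND_FIRST = "background_first"
TIE_CLUSTER_FIRST = "cluster_first"


# ---------------------------------------------------------------------------
# log hypergeometric upper-tail table
# ---------------------------------------------------------------------------

def _tail_rows(n: int, m: int, t0: int, t1: int) -> np.ndarray:
    """Rows ``t0 .. t1-1`` of the table ``T[t, k] = log P(H >= k)`` where
    ``H ~ Hypergeometric(n, m, t)`` (t draws, m marked among n)."""
    t = np.arange(t0, t1, dtype=np.float64)[:, None]
    k = np.arange(0, m + 1, dtype=np.float64)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = (
            gammaln(m + 1.0) - gammaln(k + 1.0) - gammaln(m - k + 1.0)
            + gammaln(n - m + 1.0) - gammaln(t - k + 1.0)
            - gammaln(n - m - t + k + 1.0)
            + gammaln(t + 1.0) + gammaln(n - t + 1.0) - gammaln(n + 1.0)
        )
    support = (k >= np.maximum(0.0, t - (n - m))) & (k <= np.minimum(t, float(m)))
    logpmf = np.where(support, logpmf, -np.inf)
    out = np.logaddexp.accumulate(logpmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(out, 0.0)


@lru_cache(maxsize=8)
def _full_grid(n: int, m: int, L: int) -> np.ndarray:
    return _tail_rows(n, m, 0, L + 1)


def _grid_provider(n: int, m: int, L: int):
    """Return ``fetch(t0, t1) -> rows t0..t1-1`` of the tail table,
    backed by an LRU-cached full grid when it fits in memory."""
    if (L + 1) * (m + 1) <= _MAX_CACHED_CELLS:
        grid = _full_grid(n, m, L)
        return lambda t0, t1: grid[t0:t1]
    return lambda t0, t1: _tail_rows(n, m, t0, t1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class RankedMembership:
    """Cluster-membership indicators sorted by decreasing expression.

    ``labels[i]`` is 1 when the cell at sorted position ``i`` belongs to the
    cluster of interest; ``values`` are the matching (non-increasing)
    expression values and ``order`` maps sorted positions back to the original
    cell positions.
    """

    labels: np.ndarray
    values: np.ndarray
    order: np.ndarray

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def m(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class XLParams:
    """Threshold-scan constraints: at least ``X`` ones above an admissible
    threshold, thresholds no deeper than ``L``."""

    X: int
    L: int

    def __post_init__(self) -> None:
        if self.X < 0:
            raise ValueError(f"X must be non-negative, got {self.X}")
        if self.L < 0:
            raise ValueError(f"L must be non-negative, got {self.L}")

    def validate(self, n: int, m: int) -> None:
        if self.X > m:
            raise ValueError(f"X={self.X} exceeds cluster size m={m}")
        if self.L > n:
            raise ValueError(f"L={self.L} exceeds number of cells n={n}")
        if self.X > self.L:
            raise ValueError(f"X={self.X} exceeds L={self.L}")


@dataclass(frozen=True)
class XlmhgResult:
    stat: float
    threshold_index: int
    pvalue: float
    log_stat: float = field(default=0.0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rank_membership(
    expression: Sequence[float],
    membership: Sequence[int],
    tie_policy: str = TIE_BACKGROUND_FIRST,
) -> RankedMembership:
    """Sort cells by decreasing expression and return the sorted membership.

    The default tie policy places out-of-cluster cells before in-cluster
    cells within a run of tied expression values, which can only deflate
    apparent enrichment (reported p-values are then upper bounds under ties).
    ``tie_policy='cluster_first'`` gives the opposite, optimistic ordering.
    The sort is stable: cells tied on both keys keep their input order.
    """
    expr = np.asarray(expression, dtype=np.float64)
    member = np.asarray(membership)
    if expr.ndim != 1 or member.ndim != 1 or expr.size != member.size:
        raise ValueError("expression and membership must be 1-D and equal length")
    if np.isnan(expr).any():
        raise ValueError("expression contains NaN")
    if not np.isin(member, (0, 1)).all():
        raise ValueError("membership must contain only 0/1")
    member = member.astype(np.int8)
    m = int(member.sum())
    if m == 0 or m == member.size:
        raise ValueError("degenerate membership: need at least one 0 and one 1")
    if tie_policy == TIE_BACKGROUND_FIRST:
        tie_key = member
    elif tie_policy == TIE_CLUSTER_FIRST:
        tie_key = 1 - member
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    order = np.lexsort((tie_key, -expr))
    return RankedMembership(labels=member[order], values=expr[order], order=order)


def hg_tail_pvalue(t: int, ranked: RankedMembership) -> float:
    """Hypergeometric upper-tail probability P(X >= k_t) for the top-``t``
    prefix, where ``k_t`` is the number of in-cluster cells among the top t."""
    n, m = ranked.n, ranked.m
    if not 0 <= t <= n:
        raise ValueError(f"t={t} outside [0, {n}]")
    if t == 0:
        return 1.0
    k = int(ranked.labels[:t].sum())
    return float(hypergeom.sf(k - 1, n, m, t))


def _log_statistic_from_kcum(
    kcum: np.ndarray, n: int, m: int, X: int, L: int
) -> tuple[float, int]:
    """(log statistic, threshold index) from a cumulative-ones vector."""
    L = min(L, n)
    if L < 1:
        return 0.0, 0
    head = kcum[:L]
    admissible = head >= X
    if not admissible.any():
        return 0.0, 0
    if (L + 1) * (m + 1) <= _MAX_CACHED_CELLS:
        grid = _full_grid(n, m, L)
        tails = grid[np.arange(1, L + 1), head]
    else:
        tails = hypergeom.logsf(head - 1, n, m, np.arange(1, L + 1))
    tails = np.where(admissible, tails, np.inf)
    best = float(tails.min())
    # smallest t attaining the minimum; the tolerance keeps exactly tied
    # rational tails (equal up to float round-off) from shadowing earlier t
    t_star = int(np.argmax(tails <= best + 1e-12))
    return min(best, 0.0), t_star + 1


def mhg_statistic(ranked: RankedMembership, params: XLParams) -> tuple[float, int]:
    """Minimum hypergeometric tail over admissible thresholds.

    Returns ``(stat, threshold_index)`` where ``threshold_index`` is the
    smallest t attaining the minimum; ``(1.0, 0)`` when no threshold
    ``t <= L`` has at least ``X`` in-cluster cells above it.
    """
    n, m = ranked.n, ranked.m
    params.validate(n, m)
    kcum = np.cumsum(ranked.labels)
    log_stat, t_star = _log_statistic_from_kcum(kcum, n, m, params.X, params.L)
    return math.exp(log_stat), t_star


def mhg_pvalue_batch(
    log_stats: np.ndarray,
    n: int,
    m: int,
    X: int,
    L: int,
    tol: float = _LOG_TOL,
) -> np.ndarray:
    """Exact XL-mHG p-values for a batch of log statistics sharing (n, m, X, L).

    Under the null every arrangement of the m ones among n positions is
    equally likely.  Paths on the (position, ones-seen) lattice are absorbed
    the first time they enter a cell whose tail probability is at or below
    the observed statistic (subject to the X/L constraints); the absorbed
    mass is the p-value.
    """
    log_stats = np.atleast_1d(np.asarray(log_stats, dtype=np.float64))
    L = min(L, n)
    out = np.ones(log_stats.shape[0])
    active = log_stats < 0.0
    if L < 1 or X > m or not active.any():
        return out
    thr = log_stats[active] + tol
    na = thr.shape[0]
    karr = np.arange(m + 1)
    p = np.zeros((na, m + 1))
    p[:, 0] = 1.0
    absorbed = np.zeros(na)
    fetch = _grid_provider(n, m, L)
    for t0 in range(1, L + 1, _BLOCK_ROWS):
        t1 = min(t0 + _BLOCK_ROWS - 1, L)
        rows = fetch(t0, t1 + 1)
        for t in range(t0, t1 + 1):
            take = p * ((m - karr) / (n - t + 1.0))
            p -= take
            p[:, 1:] += take[:, :-1]
            rmask = rows[t - t0][None, :] <= thr[:, None]
            if X > 0:
                rmask = rmask & (karr[None, :] >= X)
            absorbed += (p * rmask).sum(axis=1)
            p[rmask] = 0.0
    out[active] = np.clip(absorbed, _TINY, 1.0)
    return out


def mhg_pvalue(
    stat: float,
    n: int,
    m: int,
    params: XLParams,
    log_stat: float | None = None,
) -> float:
    """Exact p-value for an observed XL-mHG statistic.

    ``log_stat`` may be supplied when the raw statistic underflows double
    precision (it overrides ``stat``).
    """
    params.validate(n, m)
    if log_stat is None:
        if not 0.0 < stat <= 1.0:
            raise ValueError(f"stat must be in (0, 1], got {stat}")
        log_stat = math.log(stat)
    return float(mhg_pvalue_batch(np.array([log_stat]), n, m, params.X, params.L)[0])


def default_xl(cluster_size: int, n: int) -> XLParams:
    """Default scan constraints: X = ceil(0.15 |K|), L = min(2 |K|, n)."""
    if cluster_size <= 0:
        raise ValueError(f"cluster_size must be positive, got {cluster_size}")
    if cluster_size >= n:
        raise ValueError(f"cluster_size {cluster_size} must be below n={n}")
    # integer ceil of 3|K|/20 avoids float round-off (0.15 * 100 != 15.0)
    x = (3 * cluster_size + 19) // 20
    return XLParams(X=x, L=min(2 * cluster_size, n))


def xlmhg_test(
    expression: Sequence[float],
    membership: Sequence[int],
    X: int | None = None,
    L: int | None = None,
    tie_policy: str = TIE_BACKGROUND_FIRST,
) -> XlmhgResult:
    """Convenience wrapper: rank, minimize, and compute the exact p-value.

    ``X`` and ``L`` default to the 15%-of-cluster / twice-cluster rule.
    """
    ranked = rank_membership(expression, membership, tie_policy=tie_policy)
    n, m = ranked.n, ranked.m
    defaults = default_xl(m, n)
    params = XLParams(
        X=defaults.X if X is None else X,
        L=defaults.L if L is None else L,
    )
    params.validate(n, m)
    kcum = np.cumsum(ranked.labels)
    log_stat, t_star = _log_statistic_from_kcum(kcum, n, m, params.X, params.L)
    pvalue = float(
        mhg_pvalue_batch(np.array([log_stat]), n, m, params.X, params.L)[0]
    )
    return XlmhgResult(
        stat=math.exp(log_stat),
        threshold_index=t_star,
        pvalue=pvalue,
        log_stat=log_stat,
    )
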