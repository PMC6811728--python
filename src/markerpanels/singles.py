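"""Per-cluster single-gene marker statistics.

For a chosen cluster K every gene (and its negation track, the gene's
expression times -1) is scored with the XL-mHG threshold test against the
merged background of all other clusters.  The chosen threshold index is
converted to an expression cutoff with a "slide-up" policy -- a cell is called
positive only when its expression strictly exceeds the cutoff, so tied
boundary values are excluded -- yielding a cluster-specific binary gene-by-
cell matrix together with true-positive/true-negative rates and a rank
aggregation of p-value and absolute log2 fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import xlmhg
from .xlmhg import XLParams, default_xl

__all__ = [
    "NEGATION_SUFFIX",
    "ExpressionMatrix",
    "ClusterAssignment",
    "GeneStats",
    "BinaryMatrix",
    "add_negations",
    "compute_gene_stats",
    "rank_single_genes",
]

NEGATION_SUFFIX = "_negation"

#: pseudocount used in log2 fold changes of means
FC_PSEUDOCOUNT = 1e-6

TABLE_COLUMNS = [
    "gene",
    "rank",
    "xlmhg_pvalue",
    "threshold_index",
    "cutoff",
    "tp_rate",
    "tn_rate",
    "log2_fc",
    "pvalue_rank",
    "fc_rank",
]


@dataclass(eq=False)
class ExpressionMatrix:
    """Genes-by-cells numeric matrix with unique gene and cell identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in set(self.gene_ids)]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(self.values[rows], keep, self.cell_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=np.float64), list(df.index), list(df.columns))


@dataclass(eq=False)
class ClusterAssignment:
    """Cell-to-cluster label mapping; every cell has exactly one label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = dict(self.assignments)
        if not self.assignments:
            raise ValueError("empty cluster assignment")

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def mask(self, cell_ids: Iterable[str], label: str) -> np.ndarray:
        return np.array([self.assignments[c] == label for c in cell_ids], dtype=bool)

    def labels_for(self, cell_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.assignments[c] for c in cell_ids], dtype=object)

    def size(self, label: str) -> int:
        return sum(1 for v in self.assignments.values() if v == label)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ClusterAssignment":
        return cls(dict(mapping))


@dataclass
class GeneStats:
    """Single-gene XL-mHG record for one gene in one cluster-centred run."""

    gene_id: str
    xlmhg_pvalue: float
    threshold_index: int
    expression_cutoff: float
    tp_rate: float
    tn_rate: float
    log2_fold_change: float
    log_stat: float = 0.0
    pvalue_rank: float | None = None
    fc_rank: float | None = None
    aggregated_rank: float | None = None

    @property
    def is_negation(self) -> bool:
        return self.gene_id.endswith(NEGATION_SUFFIX)


@dataclass(eq=False)
class BinaryMatrix:
    """Cluster-specific 0/1 matrix: entry is 1 iff expression strictly
    exceeds the gene's cluster-specific cutoff."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cutoffs: np.ndarray
    cluster: str


def add_negations(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Append a ``<gene>_negation`` track (expression times -1) per gene."""
    neg_ids = [g + NEGATION_SUFFIX for g in matrix.gene_ids]
    clash = set(neg_ids) & set(matrix.gene_ids)
    if clash:
        raise ValueError(f"negation id collision: {sorted(clash)[:3]}")
    values = np.vstack([matrix.values, -matrix.values])
    return ExpressionMatrix(values, matrix.gene_ids + neg_ids, matrix.cell_ids)


def _has_negations(matrix: ExpressionMatrix) -> bool:
    return any(g.endswith(NEGATION_SUFFIX) for g in matrix.gene_ids)


def compute_gene_stats(
    matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    K: str,
    params: XLParams | None = None,
    tie_policy: str = xlmhg.TIE_BACKGROUND_FIRST,
    include_negations: bool = True,
    pseudocount: float = FC_PSEUDOCOUNT,
) -> tuple[list[GeneStats], BinaryMatrix]:
    """XL-mHG statistics and binarization for every gene (plus negations).

    The background is the union of all clusters other than ``K``.  The cutoff
    for a gene is the sorted expression value at rank ``threshold_index + 1``
    (``-inf`` when the threshold is the full list), and positivity is strict
    inequality, so a tie spanning the threshold boundary slides the cutoff up
    past the tied block.
    """
    if K not in clusters.clusters:
        raise ValueError(f"cluster {K!r} not present")
    member = clusters.mask(matrix.cell_ids, K)
    n = matrix.n_cells
    m = int(member.sum())
    if m == 0:
        raise ValueError(f"cluster {K!r} has no cells in the matrix")
    if m == n:
        raise ValueError(f"cluster {K!r} has empty background")
    if include_negations and not _has_negations(matrix):
        work = add_negations(matrix)
    else:
        work = matrix
    if params is None:
        params = default_xl(m, n)
    params.validate(n, m)

    p_work = work.n_genes
    t_stars = np.zeros(p_work, dtype=np.int64)
    log_stats = np.zeros(p_work)
    cutoffs = np.zeros(p_work)
    degenerate = np.zeros(p_work, dtype=bool)
    binary = np.zeros((p_work, n), dtype=np.uint8)

    for i in range(p_work):
        row = work.values[i]
        if row.max() == row.min():
            degenerate[i] = True
            t_stars[i] = 0
            log_stats[i] = 0.0
            cutoffs[i] = row[0]
            continue
        ranked = xlmhg.rank_membership(row, member, tie_policy=tie_policy)
        kcum = np.cumsum(ranked.labels)
        log_stats[i], t_stars[i] = xlmhg._log_statistic_from_kcum(
            kcum, n, m, params.X, params.L
        )
        t = t_stars[i]
        cutoffs[i] = ranked.values[t] if t < n else -np.inf
        binary[i] = row > cutoffs[i]

    pvalues = xlmhg.mhg_pvalue_batch(log_stats, n, m, params.X, params.L)
    pvalues[degenerate] = 1.0

    tp = binary[:, member].sum(axis=1) / m
    tn = (binary[:, ~member] == 0).sum(axis=1) / (n - m)

    # fold changes on the original (non-negated) scale; a negation track
    # inherits its parent's value with the sign flipped
    orig_idx = [i for i, g in enumerate(work.gene_ids) if not g.endswith(NEGATION_SUFFIX)]
    fc_by_gene: dict[str, float] = {}
    for i in orig_idx:
        row = work.values[i]
        # clip at the pseudocount floor so inputs that dip below zero
        # (e.g. already log-scaled data) cannot break the log
        mean_k = max(row[member].mean() + pseudocount, pseudocount)
        mean_bg = max(row[~member].mean() + pseudocount, pseudocount)
        fc_by_gene[work.gene_ids[i]] = math.log2(mean_k / mean_bg)

    stats: list[GeneStats] = []
    for i, gid in enumerate(work.gene_ids):
        if gid.endswith(NEGATION_SUFFIX):
            fc = -fc_by_gene.get(gid[: -len(NEGATION_SUFFIX)], 0.0)
        else:
            fc = fc_by_gene[gid]
        stats.append(
            GeneStats(
                gene_id=gid,
                xlmhg_pvalue=float(pvalues[i]),
                threshold_index=int(t_stars[i]),
                expression_cutoff=float(cutoffs[i]),
                tp_rate=float(tp[i]) if not degenerate[i] else 0.0,
                tn_rate=float(tn[i]) if not degenerate[i] else 1.0,
                log2_fold_change=fc,
                log_stat=float(log_stats[i]),
            )
        )
    bm = BinaryMatrix(
        values=binary,
        gene_ids=list(work.gene_ids),
        cell_ids=list(work.cell_ids),
        cutoffs=cutoffs,
        cluster=K,
    )
    return stats, bm


def _stats_frame(stats: list[GeneStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [s.gene_id for s in stats],
            "rank": [s.aggregated_rank for s in stats],
            "xlmhg_pvalue": [s.xlmhg_pvalue for s in stats],
            "threshold_index": [s.threshold_index for s in stats],
            "cutoff": [s.expression_cutoff for s in stats],
            "tp_rate": [s.tp_rate for s in stats],
            "tn_rate": [s.tn_rate for s in stats],
            "log2_fc": [s.log2_fold_change for s in stats],
            "pvalue_rank": [s.pvalue_rank for s in stats],
            "fc_rank": [s.fc_rank for s in stats],
        },
        columns=TABLE_COLUMNS,
    )


def rank_single_genes(
    stats: list[GeneStats],
    tp_min: float = 0.15,
    negation_tn_min: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Filter, rank, and tabulate single-gene statistics.

    Genes with a true-positive rate below ``tp_min`` are dropped, as are
    negation tracks with a true-negative rate below ``negation_tn_min``.
    Within the surviving set, competition ranks (``1, 2, 2, 4``) are assigned
    by p-value and by absolute log2 fold change, and the reported rank is
    their arithmetic mean.  Returns ``(ranked_all, ranked_positive, full)``
    where ``full`` lists every gene unranked and unfiltered.
    """
    full = _stats_frame(stats)

    kept = [
        s
        for s in stats
        if s.tp_rate >= tp_min
        and (not s.is_negation or s.tn_rate >= negation_tn_min)
    ]
    if not kept:
        empty = full.iloc[0:0].copy()
        return empty, empty.copy(), full

    pvals = np.array([s.xlmhg_pvalue for s in kept])
    absfc = np.array([abs(s.log2_fold_change) for s in kept])
    p_ranks = rankdata(pvals, method="min")
    fc_ranks = rankdata(-absfc, method="min")
    for s, pr, fr in zip(kept, p_ranks, fc_ranks):
        s.pvalue_rank = float(pr)
        s.fc_rank = float(fr)
        s.aggregated_rank = (float(pr) + float(fr)) / 2.0

    kept.sort(key=lambda s: (s.aggregated_rank, s.xlmhg_pvalue, s.gene_id))
    ranked_all = _stats_frame(kept)
    ranked_pos = ranked_all[~ranked_all["gene"].str.endswith(NEGATION_SUFFIX)]
    ranked_pos = ranked_pos.reset_index(drop=True)
    return ranked_all, ranked_pos, full
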