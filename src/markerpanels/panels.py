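"""Exact and heuristic enumeration of 2/3/4-gene AND-panels.

Works on the cluster-specific binarized matrix restricted to genes whose
true-positive rate is at least 15%.  Pair counts come from one matrix product
(A @ A.T); triples and quads reuse a pair-by-cell AND matrix Q, giving counts
from Q @ A.T and Q @ Q.T respectively.  Panels are ranked by hypergeometric
enrichment of all-positive cells in the cluster; pairs additionally receive a
Cluster-Clear-Score measuring how many percentage points of true negatives
the panel gains over its lead gene in each contaminating cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, rankdata

from .singles import BinaryMatrix, GeneStats

__all__ = [
    "FilteredBinaryMatrix",
    "PanelRecord",
    "filter_binary",
    "positives_matrices",
    "panel_hypergeom",
    "cluster_clear_score",
    "rank_pairs",
    "rank_triples",
    "rank_quads",
    "heuristic_candidates",
    "output_limits",
]

#: number of top hypergeometric-ranked pairs that receive a CCS
CCS_TOP = 1000

DEFAULT_CORE_SIZE = 50


@dataclass(eq=False)
class FilteredBinaryMatrix:
    """Binary gene-by-cell matrix restricted to genes with TP rate >= 15%."""

    values: np.ndarray  # (p~, n) uint8
    gene_ids: list[str]
    member: np.ndarray  # bool mask of cells in K
    single_pvalues: dict[str, float]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def m(self) -> int:
        return int(self.member.sum())


def filter_binary(
    binary: BinaryMatrix,
    stats: Sequence[GeneStats],
    member: np.ndarray,
    tp_min: float = 0.15,
) -> FilteredBinaryMatrix:
    by_gene = {s.gene_id: s for s in stats}
    keep = [
        i
        for i, g in enumerate(binary.gene_ids)
        if by_gene[g].tp_rate >= tp_min
    ]
    genes = [binary.gene_ids[i] for i in keep]
    return FilteredBinaryMatrix(
        values=binary.values[keep].astype(np.uint8),
        gene_ids=genes,
        member=np.asarray(member, dtype=bool),
        single_pvalues={g: by_gene[g].xlmhg_pvalue for g in genes},
    )


def positives_matrices(fbm: FilteredBinaryMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(R, R_K): co-positive cell counts for every gene pair, over all cells
    and over cluster cells.  Diagonals hold single-gene positive counts."""
    a = fbm.values.astype(np.int64)
    ak = a[:, fbm.member]
    return a @ a.T, ak @ ak.T


def panel_hypergeom(
    positives_in_k: int, positives_total: int, m: int, n: int
) -> float:
    """Upper-tail P(X >= positives_in_k), X ~ Hypergeometric(n, m, total)."""
    if not 0 <= positives_in_k <= min(positives_total, m):
        raise ValueError(
            f"inconsistent counts: in_K={positives_in_k}, total={positives_total}, m={m}"
        )
    if positives_total > n:
        raise ValueError(f"positives_total={positives_total} exceeds n={n}")
    return float(hypergeom.sf(positives_in_k - 1, n, m, positives_total))


def cluster_clear_score(
    tn_before: Mapping[str, float], tn_after: Mapping[str, float]
) -> float:
    """Sum over contaminating clusters of TN%(panel) - TN%(lead gene)."""
    return float(sum(tn_after[c] - tn_before[c] for c in tn_before))


@dataclass
class PanelRecord:
    """One multi-gene AND-panel with its enrichment statistics."""

    genes: tuple[str, ...]
    positives_total: int
    positives_in_k: int
    hypergeom_pvalue: float
    tp_rate: float
    tn_rate: float
    ccs: float | None = None
    lead_gene: str | None = None
    hg_rank: float | None = None
    ccs_rank: float | None = None
    final_rank: float | None = None


def _finish_records(
    fbm: FilteredBinaryMatrix,
    gene_sets: list[tuple[int, ...]],
    totals: np.ndarray,
    in_k: np.ndarray,
) -> list[PanelRecord]:
    n, m = fbm.n_cells, fbm.m
    pvals = hypergeom.sf(in_k - 1, n, m, totals)
    records = []
    for idx, tot, kin, pv in zip(gene_sets, totals, in_k, pvals):
        genes = tuple(sorted(fbm.gene_ids[i] for i in idx))
        records.append(
            PanelRecord(
                genes=genes,
                positives_total=int(tot),
                positives_in_k=int(kin),
                hypergeom_pvalue=float(pv),
                tp_rate=float(kin) / m,
                tn_rate=1.0 - (float(tot) - float(kin)) / (n - m),
            )
        )
    records.sort(key=lambda r: (r.hypergeom_pvalue, r.genes))
    pv_sorted = np.array([r.hypergeom_pvalue for r in records])
    hg_ranks = rankdata(pv_sorted, method="min")
    for r, hr in zip(records, hg_ranks):
        r.hg_rank = float(hr)
        r.final_rank = float(hr)
    return records


def _candidate_index_sets(
    fbm: FilteredBinaryMatrix, candidates: Iterable[tuple[str, ...]] | None
) -> set[tuple[int, ...]] | None:
    if candidates is None:
        return None
    idx = {g: i for i, g in enumerate(fbm.gene_ids)}
    out = set()
    for cand in candidates:
        if all(g in idx for g in cand):
            out.add(tuple(sorted(idx[g] for g in cand)))
    return out


def rank_pairs(
    fbm: FilteredBinaryMatrix,
    cluster_labels: np.ndarray | None = None,
    K: str | None = None,
    R: np.ndarray | None = None,
    R_K: np.ndarray | None = None,
    candidates: Iterable[tuple[str, ...]] | None = None,
    ccs_top: int = CCS_TOP,
) -> list[PanelRecord]:
    """All (or candidate) unordered gene pairs, ranked.

    The final rank of a pair within the top ``ccs_top`` hypergeometric ranks
    is the average of its hypergeometric rank and its CCS rank (CCS ranks are
    computed within that subset); beyond it the hypergeometric rank stands
    alone.  ``cluster_labels`` (a per-cell label array) enables the
    per-contaminating-cluster CCS; without it the merged background is
    treated as a single cluster.
    """
    p = len(fbm.gene_ids)
    if p < 2:
        return []
    if R is None or R_K is None:
        R, R_K = positives_matrices(fbm)
    cand_idx = _candidate_index_sets(fbm, candidates)
    iu, ju = np.triu_indices(p, k=1)
    if cand_idx is not None:
        keep = [x for x, (i, j) in enumerate(zip(iu, ju)) if (i, j) in cand_idx]
        iu, ju = iu[keep], ju[keep]
    if iu.size == 0:
        return []
    gene_sets = list(zip(iu.tolist(), ju.tolist()))
    records = _finish_records(fbm, gene_sets, R[iu, ju], R_K[iu, ju])

    # CCS for the leading subset of the hypergeometric ranking
    top = records[: min(ccs_top, len(records))]
    if cluster_labels is None or K is None:
        labels = np.where(fbm.member, "__K__", "__background__")
        k_label = "__K__"
    else:
        labels = np.asarray(cluster_labels, dtype=object)
        k_label = K
    other = [c for c in sorted(set(labels.tolist())) if c != k_label]
    cluster_masks = {c: labels == c for c in other}
    gidx = {g: i for i, g in enumerate(fbm.gene_ids)}
    for r in records:
        r.lead_gene = min(
            r.genes, key=lambda g: (fbm.single_pvalues[g], g)
        )
    for r in top:
        lead_row = fbm.values[gidx[r.lead_gene]]
        panel_row = fbm.values[gidx[r.genes[0]]] & fbm.values[gidx[r.genes[1]]]
        ccs = 0.0
        for c, mask in cluster_masks.items():
            denom = mask.sum()
            before = 100.0 * (lead_row[mask] == 0).sum() / denom
            after = 100.0 * (panel_row[mask] == 0).sum() / denom
            ccs += after - before
        r.ccs = ccs
    ccs_vals = np.array([r.ccs for r in top])
    ccs_ranks = rankdata(-ccs_vals, method="min")
    for r, cr in zip(top, ccs_ranks):
        r.ccs_rank = float(cr)
        r.final_rank = (r.hg_rank + r.ccs_rank) / 2.0
    records.sort(key=lambda r: (r.final_rank, r.hypergeom_pvalue, r.genes))
    return records


def _pair_rows(
    a: np.ndarray, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    i = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
    j = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
    return a[i] * a[j]


def rank_triples(
    fbm: FilteredBinaryMatrix,
    candidates: Iterable[tuple[str, ...]] | None = None,
    block_pairs: int = 2048,
) -> list[PanelRecord]:
    """Unique 3-gene panels ranked by hypergeometric p-value.

    Counts come from the product of the pair-AND matrix Q with the binary
    matrix; a triple {a<b<c} is represented once, by pair (a, b) and third
    gene c.  Evaluation is blocked over pairs; results are independent of the
    block size.
    """
    p = len(fbm.gene_ids)
    if p < 3:
        return []
    a = fbm.values.astype(np.int64)
    ak = a[:, fbm.member]
    cand_idx = _candidate_index_sets(fbm, candidates)
    if cand_idx is not None:
        pairs = sorted({(c[0], c[1]) for c in cand_idx})
    else:
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    gene_sets: list[tuple[int, ...]] = []
    totals: list[int] = []
    in_k: list[int] = []
    for b0 in range(0, len(pairs), block_pairs):
        block = pairs[b0 : b0 + block_pairs]
        q = _pair_rows(a, block)
        counts = q @ a.T
        counts_k = q[:, fbm.member] @ ak.T
        for r, (i, j) in enumerate(block):
            for k in range(j + 1, p):
                trip = (i, j, k)
                if cand_idx is not None and trip not in cand_idx:
                    continue
                gene_sets.append(trip)
                totals.append(int(counts[r, k]))
                in_k.append(int(counts_k[r, k]))
    if not gene_sets:
        return []
    return _finish_records(
        fbm, gene_sets, np.asarray(totals), np.asarray(in_k)
    )


def rank_quads(
    fbm: FilteredBinaryMatrix,
    candidates: Iterable[tuple[str, ...]] | None = None,
    block_pairs: int = 1024,
) -> list[PanelRecord]:
    """Unique 4-gene panels ranked by hypergeometric p-value.

    Counts are entries of Q @ Q.T; a quad {a<b<c<d} is represented once, by
    the disjoint pairs (a, b) and (c, d) with b < c.
    """
    p = len(fbm.gene_ids)
    if p < 4:
        return []
    a = fbm.values.astype(np.int64)
    cand_idx = _candidate_index_sets(fbm, candidates)
    if cand_idx is not None:
        first = sorted({(c[0], c[1]) for c in cand_idx})
        second = sorted({(c[2], c[3]) for c in cand_idx})
    else:
        first = [(i, j) for i in range(p) for j in range(i + 1, p)]
        second = first
    member = fbm.member
    gene_sets: list[tuple[int, ...]] = []
    totals: list[int] = []
    in_k: list[int] = []
    for b0 in range(0, len(first), block_pairs):
        blk1 = first[b0 : b0 + block_pairs]
        q1 = _pair_rows(a, blk1)
        for b1 in range(0, len(second), block_pairs):
            blk2 = second[b1 : b1 + block_pairs]
            q2 = _pair_rows(a, blk2)
            counts = q1 @ q2.T
            counts_k = q1[:, member] @ q2[:, member].T
            for r1, (i, j) in enumerate(blk1):
                for r2, (k, l) in enumerate(blk2):
                    if j >= k:
                        continue
                    quad = (i, j, k, l)
                    if cand_idx is not None and quad not in cand_idx:
                        continue
                    gene_sets.append(quad)
                    totals.append(int(counts[r1, r2]))
                    in_k.append(int(counts_k[r1, r2]))
    if not gene_sets:
        return []
    return _finish_records(
        fbm, gene_sets, np.asarray(totals), np.asarray(in_k)
    )


def heuristic_candidates(
    ranked_single: Sequence[str],
    core_size: int,
    panel_size: int,
    all_genes: Sequence[str],
) -> set[tuple[str, ...]]:
    """Candidate panels with at least ``panel_size - 1`` genes from the core.

    The core is the top ``core_size`` entries of ``ranked_single`` (best
    single-gene performers first); 4-gene candidates are drawn entirely from
    the core.
    """
    if core_size < 1:
        raise ValueError("core_size must be >= 1")
    if panel_size not in (2, 3, 4):
        raise ValueError(f"panel_size must be 2, 3 or 4, got {panel_size}")
    core = list(ranked_single)[:core_size]
    core_set = set(core)
    pool = list(all_genes)
    out: set[tuple[str, ...]] = set()
    if panel_size == 4:
        return {tuple(sorted(c)) for c in combinations(core, 4)}
    for part in combinations(core, panel_size - 1):
        for g in pool:
            if g in part:
                continue
            out.add(tuple(sorted(part + (g,))))
    # drop combinations with fewer than panel_size-1 core members (cannot
    # occur by construction) and keep all-core combinations (already covered
    # when pool includes core genes)
    for c in combinations(core, panel_size):
        out.add(tuple(sorted(c)))
    return out


def output_limits(
    records: Sequence[PanelRecord],
    max_lead: int = 10,
    max_gene_occurrences: int = 200,
) -> list[PanelRecord]:
    """Greedy top-down pass capping lead-gene appearances and total
    appearances of any one gene in the emitted list."""
    lead_counts: dict[str, int] = {}
    gene_counts: dict[str, int] = {}
    kept = []
    for r in records:
        lead = r.lead_gene if r.lead_gene is not None else r.genes[0]
        if lead_counts.get(lead, 0) >= max_lead:
            continue
        if any(gene_counts.get(g, 0) >= max_gene_occurrences for g in r.genes):
            continue
        kept.append(r)
        lead_counts[lead] = lead_counts.get(lead, 0) + 1
        for g in r.genes:
            gene_counts[g] = gene_counts.get(g, 0) + 1
    return kept
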