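import math
from itertools import combinations

import numpy as np
import pytest

from markerpanels.panels import (
    FilteredBinaryMatrix,
    PanelRecord,
    cluster_clear_score,
    heuristic_candidates,
    output_limits,
    panel_hypergeom,
    positives_matrices,
    rank_pairs,
    rank_quads,
    rank_triples,
)
from oracle_utils import brute_force_panel_counts


def make_fbm(binary, member, pvalues=None, gene_ids=None):
    binary = np.asarray(binary, dtype=np.uint8)
    genes = gene_ids or [f"g{i:02d}" for i in range(binary.shape[0])]
    if pvalues is None:
        pvalues = {g: (i + 1) / 100 for i, g in enumerate(genes)}
    return FilteredBinaryMatrix(
        values=binary,
        gene_ids=genes,
        member=np.asarray(member, dtype=bool),
        single_pvalues=pvalues,
    )


def random_fbm(rng, p=10, n=30, m=9):
    binary = (rng.random((p, n)) < 0.4).astype(np.uint8)
    member = np.zeros(n, dtype=bool)
    member[:m] = True
    return make_fbm(binary, member)


class TestPositivesMatrices:
    def test_hand_example(self):
        fbm = make_fbm([[1, 1, 0], [1, 0, 1]], [True, False, False])
        r, rk = positives_matrices(fbm)
        assert r.tolist() == [[2, 1], [1, 2]]
        assert rk.tolist() == [[1, 1], [1, 1]]

    def test_symmetric_and_bounded(self, rng):
        fbm = random_fbm(rng)
        r, rk = positives_matrices(fbm)
        assert np.array_equal(r, r.T)
        assert (rk <= r).all()

    def test_zero_row(self):
        fbm = make_fbm([[0, 0, 0], [1, 1, 0]], [True, False, False])
        r, _ = positives_matrices(fbm)
        assert r[0].tolist() == [0, 0]
        assert r[:, 0].tolist() == [0, 0]


class TestPanelHypergeom:
    def test_closed_form(self):
        assert panel_hypergeom(4, 5, 4, 10) == pytest.approx(6 / 252)

    def test_empty_panel(self):
        assert panel_hypergeom(0, 0, 3, 10) == 1.0

    def test_matches_enumeration(self):
        # P(all m cluster cells among the drawn total) for n <= 10
        for n in range(4, 11):
            for m in range(1, n // 2):
                total = m + 1
                count = sum(
                    1
                    for draw in combinations(range(n), total)
                    if set(range(m)) <= set(draw)
                )
                expected = count / math.comb(n, total)
                assert panel_hypergeom(m, total, m, n) == pytest.approx(expected)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            panel_hypergeom(5, 4, 10, 20)


class TestClusterClearScore:
    def test_direct_sum(self):
        before = {"C1": 40.0, "C2": 60.0}
        after = {"C1": 90.0, "C2": 60.0}
        assert cluster_clear_score(before, after) == 50.0

    def test_nothing_cleared(self):
        before = {"C1": 10.0}
        assert cluster_clear_score(before, dict(before)) == 0.0

    def test_ccs_nonnegative_on_random_fixtures(self, rng):
        for _ in range(10):
            fbm = random_fbm(rng, p=6, n=20, m=6)
            records = rank_pairs(fbm)
            for r in records:
                if r.ccs is not None:
                    assert r.ccs >= -1e-9


class TestRankPairs:
    def test_cardinality(self, rng):
        fbm = random_fbm(rng, p=8)
        records = rank_pairs(fbm)
        assert len(records) == math.comb(8, 2)
        assert len({r.genes for r in records}) == len(records)

    def test_no_repeated_genes(self, rng):
        fbm = random_fbm(rng, p=6)
        for r in rank_pairs(fbm):
            assert len(set(r.genes)) == 2

    def test_counts_match_brute_force(self, rng):
        fbm = random_fbm(rng, p=10, n=25, m=8)
        for r in rank_pairs(fbm):
            idx = tuple(fbm.gene_ids.index(g) for g in r.genes)
            tot, kin = brute_force_panel_counts(fbm.values, fbm.member, idx)
            assert (r.positives_total, r.positives_in_k) == (tot, kin)

    def test_ccs_promotes_clearing_pair(self):
        # gene A marks K plus contaminating cluster C1; gene B clears C1
        member = np.array([True] * 4 + [False] * 8)
        labels = np.array(["K"] * 4 + ["C1"] * 4 + ["C2"] * 4, dtype=object)
        gene_a = [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0]
        gene_b = [1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1]
        gene_c = [1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 0]
        fbm = make_fbm(
            [gene_a, gene_b, gene_c],
            member,
            pvalues={"A": 0.001, "B": 0.02, "C": 0.01},
            gene_ids=["A", "B", "C"],
        )
        records = rank_pairs(fbm, cluster_labels=labels, K="K")
        by_genes = {r.genes: r for r in records}
        ab = by_genes[("A", "B")]
        assert ab.lead_gene == "A"
        # B clears all four C1 cells that A left positive
        assert ab.ccs == pytest.approx(100.0)
        assert records[0].genes == ("A", "B")

    def test_fewer_than_two_genes(self):
        fbm = make_fbm([[1, 0, 1]], [True, False, False])
        assert rank_pairs(fbm) == []

    def test_final_rank_average_within_ccs_subset(self, rng):
        fbm = random_fbm(rng, p=6, n=20, m=6)
        for r in rank_pairs(fbm):
            assert r.final_rank == pytest.approx((r.hg_rank + r.ccs_rank) / 2)

    def test_hg_rank_alone_beyond_ccs_subset(self, rng):
        fbm = random_fbm(rng, p=8, n=30, m=9)
        records = rank_pairs(fbm, ccs_top=5)
        with_ccs = [r for r in records if r.ccs is not None]
        without = [r for r in records if r.ccs is None]
        assert len(with_ccs) == 5
        for r in without:
            assert r.final_rank == r.hg_rank


class TestTriplesQuads:
    @pytest.mark.parametrize("p,size,expected", [(4, 3, 4), (5, 4, 5)])
    def test_cardinality(self, rng, p, size, expected):
        fbm = random_fbm(rng, p=p, n=20, m=6)
        runner = rank_triples if size == 3 else rank_quads
        records = runner(fbm)
        assert len(records) == expected
        assert len({r.genes for r in records}) == expected

    @pytest.mark.parametrize("size", [3, 4])
    def test_counts_match_brute_force(self, rng, size):
        fbm = random_fbm(rng, p=10, n=20, m=6)
        runner = rank_triples if size == 3 else rank_quads
        for r in runner(fbm):
            idx = tuple(fbm.gene_ids.index(g) for g in r.genes)
            tot, kin = brute_force_panel_counts(fbm.values, fbm.member, idx)
            assert (r.positives_total, r.positives_in_k) == (tot, kin)

    def test_zero_row_gene(self, rng):
        binary = (np.random.default_rng(5).random((5, 12)) < 0.5).astype(np.uint8)
        binary[2] = 0
        fbm = make_fbm(binary, [True] * 4 + [False] * 8)
        for r in rank_triples(fbm):
            if fbm.gene_ids[2] in r.genes:
                assert r.positives_total == 0
                assert r.hypergeom_pvalue == 1.0

    def test_block_size_independence(self, rng):
        fbm = random_fbm(rng, p=9, n=25, m=8)
        small = rank_triples(fbm, block_pairs=3)
        large = rank_triples(fbm, block_pairs=10_000)
        assert [(r.genes, r.positives_total) for r in small] == [
            (r.genes, r.positives_total) for r in large
        ]
        qs = rank_quads(fbm, block_pairs=2)
        ql = rank_quads(fbm, block_pairs=10_000)
        assert [(r.genes, r.positives_total) for r in qs] == [
            (r.genes, r.positives_total) for r in ql
        ]

    def test_and_monotonicity_along_nested_panels(self, rng):
        fbm = random_fbm(rng, p=7, n=24, m=8)
        pairs = {r.genes: r for r in rank_pairs(fbm)}
        triples = {r.genes: r for r in rank_triples(fbm)}
        quads = {r.genes: r for r in rank_quads(fbm)}
        for genes, quad in quads.items():
            for sub in combinations(genes, 3):
                tri = triples[tuple(sorted(sub))]
                assert quad.tp_rate <= tri.tp_rate + 1e-12
                assert quad.tn_rate >= tri.tn_rate - 1e-12
                assert quad.positives_total <= tri.positives_total
        for genes, tri in triples.items():
            for sub in combinations(genes, 2):
                pair = pairs[tuple(sorted(sub))]
                assert tri.tp_rate <= pair.tp_rate + 1e-12
                assert tri.tn_rate >= pair.tn_rate - 1e-12


class TestHeuristic:
    def test_pair_candidate_count(self):
        genes = [f"g{i}" for i in range(10)]
        cands = heuristic_candidates(genes, 3, 2, genes)
        assert len(cands) == math.comb(3, 2) + 3 * 7

    def test_triple_candidate_count(self):
        genes = [f"g{i}" for i in range(10)]
        cands = heuristic_candidates(genes, 3, 3, genes)
        assert len(cands) == math.comb(3, 2) * 7 + math.comb(3, 3)

    def test_quads_all_core(self):
        genes = [f"g{i}" for i in range(10)]
        cands = heuristic_candidates(genes, 5, 4, genes)
        assert len(cands) == math.comb(5, 4)
        assert heuristic_candidates(genes, 3, 4, genes) == set()

    def test_core_covers_everything(self):
        genes = [f"g{i}" for i in range(8)]
        cands = heuristic_candidates(genes, 8, 2, genes)
        assert len(cands) == math.comb(8, 2)

    def test_candidate_spaces_nested_in_core_size(self):
        genes = [f"g{i}" for i in range(9)]
        prev = set()
        for n_core in range(1, 10):
            cur = heuristic_candidates(genes, n_core, 3, genes)
            assert prev <= cur
            prev = cur

    def test_heuristic_equals_exhaustive_at_full_core(self, rng):
        fbm = random_fbm(rng, p=8, n=25, m=8)
        ranked = sorted(fbm.gene_ids, key=lambda g: fbm.single_pvalues[g])
        for runner, size in [(rank_pairs, 2), (rank_triples, 3)]:
            cands = heuristic_candidates(ranked, len(ranked), size, fbm.gene_ids)
            full = runner(fbm)
            heur = runner(fbm, candidates=cands)
            assert [r.genes for r in full] == [r.genes for r in heur]


class TestOutputLimits:
    @staticmethod
    def record(genes, lead):
        return PanelRecord(
            genes=tuple(genes),
            positives_total=1,
            positives_in_k=1,
            hypergeom_pvalue=0.5,
            tp_rate=0.5,
            tn_rate=0.5,
            lead_gene=lead,
        )

    def test_lead_cap(self):
        records = [self.record((f"x{i}", "lead"), "lead") for i in range(30)]
        assert len(output_limits(records, max_lead=10)) == 10

    def test_gene_occurrence_cap(self):
        records = [self.record(("g", f"y{i}"), f"y{i}") for i in range(500)]
        kept = output_limits(records, max_lead=10, max_gene_occurrences=200)
        assert sum(1 for r in kept if "g" in r.genes) == 200

    def test_empty(self):
        assert output_limits([]) == []
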