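"""Anchor chaining, cluster validation and coverage summaries."""

import itertools

import numpy as np
import pytest

from paleokaryo.synteny import (
    Anchor,
    SyntenyBlock,
    chain_anchors,
    classify_duplications,
    coverage_summary,
    make_block,
    montecarlo_pvalue,
    scan_pvalue,
    validate_block,
)


def anchors_at(pairs):
    return [
        Anchor(f"a{i}", f"b{i}", rank_a=ra, rank_b=rb)
        for i, (ra, rb) in enumerate(pairs)
    ]


# --------------------------------------------------------------------------
# Independent oracle: exhaustive monotone-chain enumeration
# --------------------------------------------------------------------------

def _gap_ok(a, b, direction, max_gap):
    da = b.rank_a - a.rank_a
    db = (b.rank_b - a.rank_b) * direction
    return 1 <= da <= max_gap and 1 <= db <= max_gap


def _all_chains(anchors, direction, max_gap):
    """Every maximal-extension chain as an index sequence (DFS)."""
    n = len(anchors)
    chains = []

    def extend(seq):
        chains.append(seq)
        last = seq[-1]
        for j in range(last + 1, n):
            if _gap_ok(anchors[last], anchors[j], direction, max_gap):
                extend(seq + [j])

    for i in range(n):
        extend([i])
    return chains


def oracle_partition(anchors, max_gap):
    """Greedy best-chain-first partition by brute-force enumeration."""
    pool = sorted(anchors, key=lambda x: (x.rank_a, x.rank_b, x.gene_a, x.gene_b))
    partition = []
    while pool:
        candidates = []
        for direction in (1, -1):
            chains = _all_chains(pool, direction, max_gap)
            best_len = max(len(c) for c in chains)
            best = min(c for c in chains if len(c) == best_len)
            candidates.append((len(best), best, direction))
        candidates.sort(key=lambda c: (-c[0], c[1], -c[2]))
        _, idx, _ = candidates[0]
        partition.append([pool[i] for i in idx])
        picked = set(idx)
        pool = [a for i, a in enumerate(pool) if i not in picked]
    return partition


class TestChaining:
    def test_perfect_collinearity_single_direct_block(self):
        chains = chain_anchors(anchors_at([(1, 1), (2, 2), (3, 3)]), max_gap=5)
        assert len(chains) == 1
        assert len(chains[0]) == 3
        block = make_block("b", "orthologous", ("A", "c", "B", "c"), chains[0])
        assert block.orientation == "direct"

    def test_monotone_decreasing_gives_inverted_block(self):
        chains = chain_anchors(anchors_at([(1, 9), (2, 8), (3, 7)]), max_gap=5)
        assert len(chains) == 1
        block = make_block("b", "orthologous", ("A", "c", "B", "c"), chains[0])
        assert block.orientation == "inverted"

    def test_gap_limit_splits_chains(self):
        chains = chain_anchors(
            anchors_at([(1, 1), (2, 2), (30, 30), (31, 31)]), max_gap=5
        )
        assert sorted(len(c) for c in chains) == [2, 2]

    def test_empty_input(self):
        assert chain_anchors([]) == []

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(202)
        for trial in range(30):
            n = int(rng.integers(2, 13))
            pairs = [
                (int(rng.integers(0, 15)), int(rng.integers(0, 15)))
                for _ in range(n)
            ]
            anchors = anchors_at(pairs)
            max_gap = int(rng.integers(2, 8))
            got = chain_anchors(anchors, max_gap)
            expected = oracle_partition(anchors, max_gap)
            got_ranks = [[(a.rank_a, a.rank_b) for a in c] for c in got]
            exp_ranks = [[(a.rank_a, a.rank_b) for a in c] for c in expected]
            assert got_ranks == exp_ranks, f"trial {trial}"

    def test_blocks_are_strictly_monotone_both_sides(self):
        rng = np.random.default_rng(7)
        pairs = [
            (int(rng.integers(0, 40)), int(rng.integers(0, 40)))
            for _ in range(25)
        ]
        for chain in chain_anchors(anchors_at(pairs), max_gap=10):
            ras = [a.rank_a for a in chain]
            rbs = [a.rank_b for a in chain]
            assert ras == sorted(ras) and len(set(ras)) == len(ras)
            assert rbs == sorted(rbs) or rbs == sorted(rbs, reverse=True)
            assert len(set(rbs)) == len(rbs)


class TestValidation:
    def _block(self, rank_pairs):
        return make_block(
            "b", "orthologous", ("A", "c1", "B", "c1"), anchors_at(rank_pairs)
        )

    def test_dense_cluster_validates(self):
        block = self._block([(0, 0), (2, 2), (4, 4), (7, 7), (9, 9)])
        ratio, p, verdict = validate_block(
            block, background=0.02, n_shuffles=1000, seed=7,
            n_genes_a=1000, n_null_anchors=20,
        )
        assert ratio == pytest.approx((5 / 10) / 0.02)  # 25
        assert p < 0.05
        assert verdict
        # Monte-Carlo p bounded by (a small multiple of) the closed form
        assert p <= scan_pvalue(20, 1000, 10, 5) + 0.01

    def test_match_number_rule(self):
        block = self._block([(0, 0), (1, 1), (2, 2), (3, 3)])
        _, _, verdict = validate_block(
            block, background=0.001, n_shuffles=200, seed=1,
            n_genes_a=1000,
        )
        assert not verdict

    def test_density_rule(self):
        # 5 anchors spread over a 1000-gene chromosome, background 0.005
        block = self._block([(0, 0), (249, 249), (499, 499), (749, 749), (999, 999)])
        ratio, _, verdict = validate_block(
            block, background=0.005, n_shuffles=200, seed=1,
            n_genes_a=1000,
        )
        assert ratio == pytest.approx((5 / 1000) / 0.005)  # 1 < 2
        assert not verdict

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            montecarlo_pvalue(5, 100, 10, 3, n_shuffles=50, seed=0)

    def test_pvalue_deterministic_given_seed(self):
        a = montecarlo_pvalue(8, 500, 20, 3, 1000, seed=11)
        b = montecarlo_pvalue(8, 500, 20, 3, 1000, seed=11)
        assert a == b


class TestDuplicationCalls:
    def test_uncorroborated_paralog_block_is_lineage_specific(self):
        par = make_block(
            "p1", "paralogous", ("A", "A_c1", "A", "A_c2"),
            anchors_at([(i, i) for i in range(5)]),
        )
        calls = classify_duplications([par], [])
        assert calls[0].status == "lineage_specific"
        assert calls[0].evidence == []

    def test_orthologous_positions_in_second_genome_make_ancestral(self):
        par_a = make_block(
            "pa", "paralogous", ("A", "A_c1", "A", "A_c2"),
            anchors_at([(i, i) for i in range(5)]),
        )
        par_b = make_block(
            "pb", "paralogous", ("B", "B_c1", "B", "B_c2"),
            anchors_at([(i, i) for i in range(5)]),
        )
        orth1 = make_block(
            "o1", "orthologous", ("A", "A_c1", "B", "B_c1"),
            anchors_at([(i, i) for i in range(5)]),
        )
        orth2 = make_block(
            "o2", "orthologous", ("A", "A_c2", "B", "B_c2"),
            anchors_at([(i, i) for i in range(5)]),
        )
        calls = classify_duplications([par_a, par_b], [orth1, orth2])
        by_id = {c.block.block_id: c for c in calls}
        assert by_id["pa"].status == "ancestral"
        assert "pb" in by_id["pa"].evidence
        assert by_id["pb"].status == "ancestral"


class TestCoverage:
    def _bp_block(self, bid, span_a):
        b = make_block(
            bid, "orthologous", ("A", "c1", "B", "c1"),
            anchors_at([(i, i) for i in range(5)]),
        )
        b.bp_span_a = span_a
        b.bp_span_b = (1, 2)
        return b

    def test_single_block_fraction(self):
        blocks = [self._bp_block("b1", (1, 810_000))]
        assert coverage_summary(blocks, "A", 1_000_000) == (5, 1, 81)

    def test_disjoint_blocks_sum(self):
        blocks = [
            self._bp_block("b1", (1, 300_000)),
            self._bp_block("b2", (500_001, 700_000)),
        ]
        assert coverage_summary(blocks, "A", 1_000_000)[2] == 50

    def test_overlapping_blocks_use_union(self):
        blocks = [
            self._bp_block("b1", (1, 600_000)),
            self._bp_block("b2", (400_001, 1_000_000)),
        ]
        assert coverage_summary(blocks, "A", 1_000_000)[2] == 100
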