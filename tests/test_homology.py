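"""CIP/CALP arithmetic, threshold filtering and best-hit selection."""

import pytest
from hypothesis import given, settings, strategies as st

from paleokaryo.formats import HspRecord
from paleokaryo.homology import (
    PairAlignment,
    call_homologs,
    classify_pair,
    compute_calp,
    compute_cip,
    merge_hsps,
    summarize_pair,
)


def hsp(length, identities, qstart, subject="s"):
    return HspRecord(
        "q", subject, length, identities, qstart, qstart + length - 1
    )


class TestCipCalp:
    def test_single_perfect_hsp(self):
        assert compute_cip([hsp(100, 100, 1)]) == 100.0

    def test_cumulative_identity_over_cumulative_length(self):
        hsps = [hsp(50, 40, 1), hsp(150, 90, 100)]
        assert compute_cip(hsps) == pytest.approx(100 * 130 / 200)

    def test_cip_matches_bruteforce_summation(self):
        # disjoint HSPs: CIP must equal the plain ratio of sums
        import random

        rnd = random.Random(7)
        hsps = []
        pos = 1
        for _ in range(10):
            length = rnd.randint(20, 300)
            ident = rnd.randint(0, length)
            hsps.append(hsp(length, ident, pos))
            pos += length + rnd.randint(1, 50)
        expected = 100 * sum(h.identities for h in hsps) / sum(
            h.hsp_length for h in hsps
        )
        assert compute_cip(hsps) == pytest.approx(expected)

    def test_calp_is_aligned_fraction_of_query(self):
        hsps = [hsp(200, 150, 1), hsp(150, 100, 300)]
        assert compute_calp(hsps, 700) == pytest.approx(100 * 350 / 700)

    def test_full_coverage_gives_100(self):
        assert compute_calp([hsp(500, 400, 1)], 500) == 100.0

    def test_fully_overlapping_hsps_do_not_double_count(self):
        hsps = [hsp(300, 250, 1), hsp(300, 240, 1)]
        assert compute_calp(hsps, 300) == 100.0
        # the better HSP's identities win on the shared span
        al, ids = merge_hsps(hsps)
        assert al == pytest.approx(300)
        assert ids == pytest.approx(250)

    def test_zero_query_length_rejected(self):
        with pytest.raises(ValueError):
            compute_calp([hsp(10, 5, 1)], 0)

    def test_no_hsps_rejected(self):
        with pytest.raises(ValueError):
            compute_cip([])

    @given(
        st.lists(
            st.tuples(
                st.integers(10, 200),  # length
                st.integers(1, 2000),  # start
                st.floats(0.0, 1.0),  # identity fraction
            ),
            min_size=1,
            max_size=8,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_hsp_permutation(self, raw, rnd):
        hsps = [
            HspRecord("q", "s", ln, int(frac * ln), start, start + ln - 1)
            for ln, start, frac in raw
        ]
        shuffled = hsps[:]
        rnd.shuffle(shuffled)
        assert compute_cip(hsps) == pytest.approx(compute_cip(shuffled))
        assert compute_calp(hsps, 5000) == pytest.approx(
            compute_calp(shuffled, 5000)
        )


class TestClassification:
    @pytest.mark.parametrize(
        "cip, calp, dclass, expected",
        [
            (70.0, 70.0, "close", True),  # inclusive boundary
            (69.9, 95.0, "close", False),
            (95.0, 69.9, "close", False),
            (55.0, 52.0, "distant", True),
            (50.0, 50.0, "distant", True),
            (49.9, 80.0, "distant", False),
        ],
    )
    def test_divergence_dependent_thresholds(self, cip, calp, dclass, expected):
        assert classify_pair(cip, calp, dclass) is expected

    def test_unknown_divergence_class_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(80, 80, "medium")

    def test_raising_threshold_never_admits_more_pairs(self):
        import random

        rnd = random.Random(0)
        pairs = [(rnd.uniform(0, 100), rnd.uniform(0, 100)) for _ in range(500)]
        counts = []
        for t in (40, 50, 60, 70, 80):
            thresholds = {"close": float(t)}
            counts.append(
                sum(classify_pair(c, a, "close", thresholds) for c, a in pairs)
            )
        assert counts == sorted(counts, reverse=True)


def _pa(query, subject, cip, calp, qlen=1000):
    return PairAlignment(query, subject, qlen, calp * qlen / 100, cip, calp, 1)


class TestCallHomologs:
    genome_map = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    divergence = {("A", "B"): "close", ("A", "A"): "close", ("B", "B"): "close"}

    def test_single_passing_candidate_retained(self):
        out = call_homologs(
            [_pa("a1", "b1", 90, 90)], self.genome_map, self.divergence
        )
        assert len(out) == 1
        assert out[0].relation == "ortholog"

    def test_best_hit_maximises_cip(self):
        out = call_homologs(
            [_pa("a1", "b1", 80, 90), _pa("a1", "b2", 75, 99)],
            self.genome_map,
            self.divergence,
        )
        assert [p.gene_b for p in out] == ["b1"]

    def test_failing_candidates_dropped(self):
        out = call_homologs(
            [_pa("a1", "b1", 60, 90)], self.genome_map, self.divergence
        )
        assert out == []

    def test_self_hits_removed_and_paralogs_deduplicated(self):
        out = call_homologs(
            [
                _pa("a1", "a1", 100, 100),
                _pa("a1", "a2", 85, 85),
                _pa("a2", "a1", 85, 85),
            ],
            self.genome_map,
            self.divergence,
        )
        assert len(out) == 1
        assert out[0].relation == "paralog"

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            call_homologs(
                [_pa("zz", "b1", 90, 90)], self.genome_map, self.divergence
            )

    def test_reciprocal_mode_requires_mutual_best(self):
        # a1's best is b1, but b1's best is a2: the a1-b1 call dies
        alignments = [
            _pa("a1", "b1", 85, 85),
            _pa("b1", "a2", 95, 95),
            _pa("a2", "b1", 95, 95),
        ]
        out = call_homologs(
            alignments, self.genome_map, self.divergence, reciprocal=True
        )
        assert {(p.gene_a, p.gene_b) for p in out} == {
            ("a2", "b1"), ("b1", "a2")
        }


class TestSummarizePair:
    def test_fields_consistent(self):
        hsps = [hsp(200, 180, 1), hsp(100, 80, 500)]
        pa = summarize_pair("q", "s", hsps, 600)
        assert pa.al == pytest.approx(300)
        assert pa.cip == pytest.approx(100 * 260 / 300)
        assert pa.calp == pytest.approx(50.0)
        assert pa.n_hsps == 2
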