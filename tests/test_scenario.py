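"""The karyotype event calculus: count laws, fusion modes, parsimony."""

import numpy as np
import pytest

from paleokaryo import scenario as sc
from paleokaryo.history import load_scenario_library, replay_library
from paleokaryo.simulate import random_scenario_instance


def kary(*chroms):
    return sc.karyotype_from_colors(list(chroms))


class TestApplyEvent:
    def test_wgd_doubles_chromosome_number(self):
        k = kary(["a"], ["b"], ["c"], ["d"], ["e"])
        assert sc.apply_event(k, sc.Event("WGD")).n == 10

    def test_wgd_doubles_every_colour_count(self):
        k = kary(["a", "b"], ["c"])
        k2 = sc.apply_event(k, sc.Event("WGD"))
        before = k.segment_multiset()
        after = k2.segment_multiset()
        assert sum(after.values()) == 2 * sum(before.values())
        for color in ("a", "b", "c"):
            assert sum(v for (c, _), v in after.items() if c == color) == 2

    def test_fission_and_fusion_count_laws(self):
        k = kary(["a", "b"], ["c"])
        k_fis = sc.apply_event(k, sc.Event("Cfis", {"chrom": 0, "pos": 1}))
        assert k_fis.n == 3
        k_fus = sc.apply_event(
            k, sc.Event("Cfus_TCF", {"chrom_a": 0, "chrom_b": 1})
        )
        assert k_fus.n == 1

    def test_inversion_conserves_count_and_content(self):
        k = kary(["a", "b", "c", "d"])
        k2 = sc.apply_event(
            k, sc.Event("inversion", {"chrom": 0, "start": 1, "end": 3})
        )
        assert k2.n == k.n
        assert k2.segment_multiset() == k.segment_multiset()
        assert k2.chromosomes[0].colors() == ("a", "c", "b", "d")
        assert k2.chromosomes[0].segments[1].orient == -1

    def test_reciprocal_translocation_is_count_neutral(self):
        k = kary(["a", "b"], ["c", "d"])
        k2 = sc.apply_event(
            k,
            sc.Event(
                "translocation",
                {"chrom_a": 0, "chrom_b": 1, "pos_a": 1, "pos_b": 1},
            ),
        )
        assert k2.n == 2
        assert k2.segment_multiset() == k.segment_multiset()
        assert k2.chromosomes[0].colors() == ("a", "d")

    def test_deletion_keeps_count_drops_content(self):
        k = kary(["a", "b", "c"])
        k2 = sc.apply_event(
            k, sc.Event("deletion", {"chrom": 0, "start": 1, "end": 2})
        )
        assert k2.n == 1
        assert k2.chromosomes[0].colors() == ("a", "c")

    def test_breakpoint_outside_chromosome_rejected(self):
        k = kary(["a", "b"])
        with pytest.raises(sc.EventError):
            sc.apply_event(k, sc.Event("Cfis", {"chrom": 0, "pos": 2}))

    def test_self_fusion_rejected(self):
        k = kary(["a", "b"])
        with pytest.raises(sc.EventError):
            sc.apply_event(k, sc.Event("Cfus_TCF", {"chrom_a": 0, "chrom_b": 0}))


class TestReplayAndCountTrace:
    def test_empty_event_list_is_identity(self):
        k = kary(["a"], ["b"])
        final, trace = sc.replay(k, [])
        assert final is k and trace == [2]

    def test_replay_error_names_step(self):
        k = kary(["a", "b"])
        events = [
            sc.Event("Cfis", {"chrom": 0, "pos": 1}),
            sc.Event("Cfis", {"chrom": 0, "pos": 5}),
        ]
        with pytest.raises(sc.EventError, match="event 1"):
            sc.replay(k, events)

    @pytest.mark.parametrize(
        "n0, steps, expected",
        [
            # eudicot intermediates: 21 chromosomes reshaped by fis/fus
            (21, [("fis", 6), ("fus", 15)], 12),
            (21, [("fis", 3), ("fus", 15)], 9),
            # vertebrate ancestral rounds
            (10, ["WGD", ("fis", 3)], 23),
            (23, ["WGD", ("fus", 6)], 40),
            (30, [("fis", 57), ("fus", 22)], 65),
            (39, [("fis", 31), ("fus", 50)], 20),
        ],
    )
    def test_count_trace_arithmetic(self, n0, steps, expected):
        assert sc.count_trace(n0, steps)[0] == expected

    def test_count_cannot_reach_zero(self):
        with pytest.raises(ValueError):
            sc.count_trace(2, [("fus", 2)])

    def test_count_trace_agrees_with_segment_replay(self):
        rng = np.random.default_rng(17)
        for i in range(10):
            start, target, events = random_scenario_instance(seed=300 + i)
            final, trace = sc.replay(start, events)
            steps = []
            for e in events:
                if e.kind == "WGD":
                    steps.append("WGD")
                elif e.kind == "Cfis":
                    steps.append(("fis", 1))
                elif e.kind in ("Cfus_TCF", "Cfus_CCF"):
                    steps.append(("fus", 1))
                else:
                    steps.append(("fis", 0))
            n, count_tr = sc.count_trace(start.n, steps)
            assert n == final.n
            assert count_tr == trace


class TestFusionModes:
    def test_end_to_end_pattern_is_telomeric(self):
        pre = [
            sc.Chromosome((sc.Segment("red"), sc.Segment("red"))),
            sc.Chromosome((sc.Segment("blue"), sc.Segment("blue"))),
        ]
        post = sc.Chromosome(tuple(sc.Segment(c) for c in
                                   ("red", "red", "blue", "blue")))
        assert sc.classify_fusion(pre, post) == "TCF"

    def test_nested_pattern_is_centromeric(self):
        pre = [
            sc.Chromosome((sc.Segment("red"), sc.Segment("red"))),
            sc.Chromosome((sc.Segment("blue"), sc.Segment("blue"))),
        ]
        post = sc.Chromosome(tuple(sc.Segment(c) for c in
                                   ("red", "blue", "blue", "red")))
        assert sc.classify_fusion(pre, post) == "CCF"

    def test_interleaved_pattern_is_complex(self):
        pre = [
            sc.Chromosome((sc.Segment("red"), sc.Segment("red"))),
            sc.Chromosome((sc.Segment("blue"), sc.Segment("blue"))),
        ]
        post = sc.Chromosome(tuple(sc.Segment(c) for c in
                                   ("red", "blue", "red", "blue")))
        assert sc.classify_fusion(pre, post) == "complex"

    def test_nested_fusion_decomposes_into_one_fission_two_fusions(self):
        assert sc.CCF_ELEMENTARY_STEPS == {"Cfis": 1, "Cfus": 2}
        # performing the decomposition explicitly reproduces a CCF product
        k = kary(["a1", "a2"], ["b1", "b2"])
        ccf = sc.apply_event(
            k, sc.Event("Cfus_CCF", {"chrom_a": 0, "chrom_b": 1, "pos": 1})
        )
        elementary = [
            sc.Event("Cfis", {"chrom": 0, "pos": 1}),      # a1 | a2
            sc.Event("Cfus_TCF", {"chrom_a": 0, "chrom_b": 1}),  # a1+b1b2
            sc.Event("Cfus_TCF", {"chrom_a": 1, "chrom_b": 0}),  # +a2
        ]
        via_steps, trace = sc.replay(k, elementary)
        assert via_steps.canonical() == ccf.canonical()
        n_fis = sum(e.kind == "Cfis" for e in elementary)
        n_fus = sum(e.kind.startswith("Cfus") for e in elementary)
        assert (n_fis, n_fus) == (1, 2)


class TestScenarioLibrary:
    def test_every_lineage_replays_to_its_expected_count(self):
        for kingdom in ("plant", "animal"):
            for name, (got, expected) in replay_library(kingdom).items():
                assert got == expected, name

    def test_known_count_law_discrepancies_are_preserved(self):
        animal = load_scenario_library("animal")
        mismatched = {
            name: (s.expected_n, s.stated_n)
            for name, s in animal.items()
            if s.stated_n is not None
        }
        assert mismatched == {
            "chicken": (28, 33),
            "human": (22, 23),
            "chimpanzee": (23, 24),
        }
        plant = load_scenario_library("plant")
        assert all(s.stated_n is None for s in plant.values())


class TestParsimony:
    def test_identical_karyotypes_need_zero_events(self):
        k = kary(["a", "b"], ["c"])
        res = sc.infer_min_events(k, k, budget=3)
        assert res.n_events == 0

    def test_single_fusion_detected(self):
        start = kary(["a", "b"], ["c", "d"])
        target = kary(["a", "b", "c", "d"])
        res = sc.infer_min_events(start, target, budget=3)
        assert res.n_events == 1
        assert res.events[0].kind == "Cfus_TCF"
        assert res.verify()

    def test_mismatched_segment_content_rejected(self):
        with pytest.raises(ValueError):
            sc.infer_min_events(kary(["a"]), kary(["b"]), budget=2)

    def test_unreachable_within_budget_reports_none(self):
        start = kary(["a"], ["b"], ["c"], ["d"])
        target = kary(["a", "b", "c", "d"])  # needs 3 fusions
        assert sc.infer_min_events(start, target, budget=2) is None

    def test_exact_beats_or_ties_heuristic_on_random_instances(self):
        for i in range(8):
            start, target, events = random_scenario_instance(
                seed=600 + i, max_events=3, max_chromosomes=4
            )
            exact = sc.infer_min_events(start, target, budget=len(events))
            heur = sc.infer_min_events(start, target, mode="heuristic")
            assert exact is not None
            assert exact.n_events <= len(events)
            assert heur.verify()
            assert heur.n_events >= exact.n_events
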