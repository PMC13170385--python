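"""Hairpin-element enumeration and stem-loop classification."""

import random

import pytest

from scrscreen.folding import SecondaryStructure
from scrscreen.hairpins import (
    HairpinCriteria,
    DEFAULT_CRITERIA,
    classify_structure,
    enumerate_hairpin_elements,
    evaluate_hairpin,
)
from scrscreen.simulate import PlantSpec, plant_hairpin
from oracles import (
    hairpin_elements_oracle,
    random_nested_dotbracket,
    stemloop_verdict_oracle,
)


def _structure(db: str) -> SecondaryStructure:
    return SecondaryStructure.from_dotbracket("N" * len(db), db)


def _planted(stem, loop, bulges=()) -> SecondaryStructure:
    seq, db = plant_hairpin(PlantSpec(stem_length=stem, loop_length=loop,
                                      bulges=tuple(bulges)))
    return SecondaryStructure.from_dotbracket(seq, db)


class TestEnumeration:
    def test_single_perfect_hairpin(self):
        (e,) = enumerate_hairpin_elements(_structure("((((...))))"))
        assert e.span == 11 and e.loop_length == 3 and not e.bulge_runs

    def test_two_hairpins(self):
        els = enumerate_hairpin_elements(_structure("((((...))))..((((....))))"))
        assert len(els) == 2
        assert [e.loop_length for e in els] == [3, 4]

    def test_bulged_element_hand_parsed(self):
        # outer helix 10, 3-nt 5' bulge, inner helix 8, loop 4:
        # hand-parsing with a stack gives one element spanning all 43
        # positions with a single 5' bulge run of 3.
        db = "((((((((((...((((((((....))))))))))))))))))"
        assert len(db) == 43
        (e,) = enumerate_hairpin_elements(_structure(db))
        assert e.outer_pair == (0, 42)
        assert e.span == 43
        assert e.loop_length == 4
        assert e.bulge_runs == [("5prime", 3)]
        # cross-check against the independent closure oracle
        (o,) = hairpin_elements_oracle(db)
        assert o["outer"] == e.outer_pair and o["bulges"] == [("5prime", 3)]

    def test_unpaired_structure_gives_no_elements(self):
        assert enumerate_hairpin_elements(_structure("............")) == []

    def test_elements_stop_at_multiloop_junction(self):
        db = "((((....)).((....))))"
        els = enumerate_hairpin_elements(_structure(db))
        assert len(els) == 2
        assert {e.outer_pair for e in els} == {(2, 9), (11, 18)}

    def test_oracle_equivalence_random(self):
        rng = random.Random(101)
        for _ in range(400):
            db = random_nested_dotbracket(rng, rng.randint(0, 100))
            ours = enumerate_hairpin_elements(_structure(db))
            oracle = hairpin_elements_oracle(db)
            assert len(ours) == len(oracle)
            for e, o in zip(
                sorted(ours, key=lambda e: e.outer_pair),
                sorted(oracle, key=lambda o: o["outer"]),
            ):
                assert e.outer_pair == o["outer"]
                assert e.span == o["span"]
                assert e.loop_length == o["loop"]
                assert sorted(e.bulge_runs) == o["bulges"]

    def test_completeness_element_count_equals_terminal_loops(self):
        rng = random.Random(55)
        for _ in range(200):
            db = random_nested_dotbracket(rng, rng.randint(0, 80))
            table = {}
            stack = []
            terminal = 0
            for idx, ch in enumerate(db):
                if ch == "(":
                    stack.append(idx)
                elif ch == ")":
                    i = stack.pop()
                    table[i] = idx
            for i, j in table.items():
                if all(k not in db[i + 1:j] for k in "()"):
                    terminal += 1
            assert len(enumerate_hairpin_elements(_structure(db))) == terminal


class TestCriteriaBoundaries:
    def test_span_boundary(self):
        # 16 bp stem + 3 nt loop = 35 nt: passes exactly at the bound
        assert classify_structure(_planted(16, 3)).passed
        # 15 bp + 4 nt loop = 34 nt: one short
        call = classify_structure(_planted(15, 4))
        assert not call.passed and call.failure_reasons == {"span"}

    @pytest.mark.parametrize("loop,ok", [(3, True), (10, True), (2, False), (11, False)])
    def test_loop_boundaries(self, loop, ok):
        call = classify_structure(_planted(16, loop))
        if ok:
            assert call.passed
        else:
            assert "loop" in call.failure_reasons

    @pytest.mark.parametrize("bulge,ok", [(2, True), (3, False)])
    def test_bulge_boundaries(self, bulge, ok):
        s = _planted(18, 4, bulges=[(10, "5prime", bulge)])
        call = classify_structure(s)
        assert call.passed is ok
        if not ok:
            assert call.failure_reasons == {"bulge"}

    def test_evaluate_reports_each_reason(self):
        (e,) = enumerate_hairpin_elements(_planted(16, 11))
        assert evaluate_hairpin(e).failure_reasons == {"loop"}
        (e,) = enumerate_hairpin_elements(_planted(10, 4, bulges=[(5, "3prime", 3)]))
        assert evaluate_hairpin(e).failure_reasons >= {"span", "bulge"}

    def test_joint_bulge_mode(self):
        # 1x2 internal loop: passes individually, fails jointly at max 2
        s = _planted(18, 4, bulges=[(9, "5prime", 1), (9, "3prime", 2)])
        assert classify_structure(s, HairpinCriteria(bulge_mode="individual")).passed
        assert not classify_structure(s, HairpinCriteria(bulge_mode="joint")).passed

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            HairpinCriteria(loop_min=0)
        with pytest.raises(ValueError):
            HairpinCriteria(loop_min=8, loop_max=4)


class TestClassifyStructure:
    def test_best_element_is_the_qualifying_one(self):
        # one qualifying hairpin next to one sub-span hairpin
        q_seq, q_db = plant_hairpin(PlantSpec(stem_length=17, loop_length=4))
        s_seq, s_db = plant_hairpin(PlantSpec(stem_length=5, loop_length=4))
        s = SecondaryStructure.from_dotbracket(
            q_seq + "AA" + s_seq, q_db + ".." + s_db
        )
        els = enumerate_hairpin_elements(s)
        verdicts = [evaluate_hairpin(e).passed for e in els]
        assert verdicts == [True, False]
        call = classify_structure(s)
        assert call.passed and call.best_element.outer_pair == els[0].outer_pair

    def test_fully_unpaired_fails_no_hairpin(self):
        call = classify_structure(_structure("............"))
        assert call.failure_reasons == {"no_hairpin"}

    def test_branched_only_reported(self):
        db = "((((....)).((....))))"
        call = classify_structure(_structure(db))
        assert not call.passed
        assert "branched_only" in call.failure_reasons

    def test_monotonicity_stricter_never_passes_more(self):
        rng = random.Random(77)
        structs = [
            _structure(random_nested_dotbracket(rng, 60)) for _ in range(150)
        ]
        base = sum(classify_structure(s, DEFAULT_CRITERIA).passed for s in structs)
        for stricter in [
            HairpinCriteria(min_span=40),
            HairpinCriteria(loop_min=4, loop_max=8),
            HairpinCriteria(bulge_max=1),
        ]:
            n = sum(classify_structure(s, stricter).passed for s in structs)
            assert n <= base
        # and per structure: no fail flips to pass
        for s in structs:
            if not classify_structure(s, DEFAULT_CRITERIA).passed:
                assert not classify_structure(s, HairpinCriteria(min_span=40)).passed

    def test_verdict_matches_independent_oracle(self):
        rng = random.Random(13)
        for _ in range(300):
            db = random_nested_dotbracket(rng, rng.randint(30, 90))
            assert classify_structure(_structure(db)).passed == stemloop_verdict_oracle(db)

    def test_determinism(self):
        s = _planted(16, 3)
        c1, c2 = classify_structure(s), classify_structure(s)
        assert c1.passed == c2.passed
        assert c1.best_element.outer_pair == c2.best_element.outer_pair
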