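"""DV/DVC/SV/SVC variant design and the stem shift/deletion series."""

import itertools

import pytest

from scrscreen.folding import SecondaryStructure, can_pair, fold_maxpair
from scrscreen.hairpins import classify_structure
from scrscreen.simulate import PlantSpec, plant_hairpin
from scrscreen.stop_context import StopContext
from scrscreen.variants import (
    design_compensatory,
    design_destabilizing,
    design_stabilized_compensatory,
    design_stabilizing,
    shift_or_delete_stem,
    stem_gaps,
)


def _planted(stem=16, loop=3, bulges=(), flanks=(0, 0)) -> SecondaryStructure:
    seq, db = plant_hairpin(
        PlantSpec(stem_length=stem, loop_length=loop, bulges=tuple(bulges),
                  flank_lengths=flanks)
    )
    return fold_maxpair(seq)


def _ctx(window: str) -> StopContext:
    return StopContext(
        gene_id="g", transcript_id="t", stop_codon="UAG", window=window,
        window_length_requested=len(window), strand="+", truncated=False,
        genomic_positions=tuple(range(100, 100 + len(window))),
    )


class TestDestabilizing:
    def test_break_gc_pair_gives_identical_bases(self):
        s = _planted()
        i, j = s.pairs[0]  # C-G outer pair
        dv = design_destabilizing(s, [(i, j)])
        assert dv.variant_sequence[j] == dv.variant_sequence[i] == "C"
        assert not can_pair(dv.variant_sequence[i], dv.variant_sequence[j])
        assert dv.stability_delta > 0

    def test_break_au_pair(self):
        s = fold_maxpair("AGGGAAACCCU")  # outer A-U plus G-C stem
        assert (0, 10) in s.pairs
        dv = design_destabilizing(s, [(0, 10)])
        (sub,) = dv.substitutions
        assert sub == (10, "U", "A")
        assert dv.variant_sequence[0] == dv.variant_sequence[10] == "A"

    def test_break_gu_wobble_documented_rule(self):
        s = fold_maxpair("GGGGAAACCCU")  # G0 pairs U10 (wobble) in optimum
        assert (0, 10) in s.pairs
        dv = design_destabilizing(s, [(0, 10)])
        (pos, frm, to) = dv.substitutions[0]
        # the chosen substitute must abolish pairing under WC+GU
        assert not can_pair(s.sequence[0], to)
        assert to != frm
        # and must be what exhaustive enumeration of single substitutions
        # at j admits (G opposite G is the identity-rule outcome)
        admissible = {b for b in "ACGU" if not can_pair(s.sequence[0], b) and b != frm}
        assert to in admissible
        assert dv.stability_delta > 0

    def test_unknown_pair_rejected(self):
        s = _planted()
        with pytest.raises(ValueError, match="not present"):
            design_destabilizing(s, [(0, 1)])

    def test_all_designs_abolish_the_pair(self):
        s = _planted(stem=10, loop=4)
        for pair in s.pairs:
            dv = design_destabilizing(s, [pair])
            i, j = pair
            assert not can_pair(dv.variant_sequence[i], dv.variant_sequence[j])


class TestCompensatory:
    def test_gc_break_then_restore(self):
        s = _planted()
        i, j = s.pairs[0]
        dv = design_destabilizing(s, [(i, j)])
        dvc = design_compensatory(dv, s)
        # C->G at j (DV), then G->C ... here outer pair is C-G: DV turns
        # G into C, compensation turns the 5' C into G: G-C restored
        vi, vj = dvc.variant_sequence[i], dvc.variant_sequence[j]
        assert can_pair(vi, vj)
        assert (vi, vj) != (s.sequence[i], s.sequence[j])  # diverged at both
        assert (i, j) in dvc.predicted_structure.pairs

    def test_two_broken_pairs_both_restored(self):
        s = _planted()
        pairs = s.pairs[:2]
        dvc = design_compensatory(design_destabilizing(s, pairs), s)
        assert len(dvc.substitutions) == 4
        for p in pairs:
            assert p in dvc.predicted_structure.pairs

    def test_score_restored_on_unique_optimum_fixture(self):
        s = _planted()
        dvc = design_compensatory(design_destabilizing(s, s.pairs[:3]), s)
        assert dvc.predicted_structure.mfe == s.mfe
        assert dvc.stability_delta == 0.0

    def test_requires_dv_input(self):
        s = _planted()
        sv_like = design_destabilizing(s, [s.pairs[0]])
        sv_like.variant_class = "SV"
        with pytest.raises(ValueError, match="expected a DV"):
            design_compensatory(sv_like, s)


class TestStabilizing:
    def test_1x1_internal_loop_closed(self):
        s = _planted(stem=18, loop=4, bulges=[(9, "5prime", 1), (9, "3prime", 1)])
        gaps = stem_gaps(fold_maxpair(s.sequence))
        assert any(g5 and g3 for g5, g3 in gaps)
        sv = design_stabilizing(s, [next(i for i, (a, b) in enumerate(gaps) if a and b)])
        (sub,) = sv.substitutions
        assert sub[1] == "A" and sub[2] == "U"  # A opposite A -> new A-U pair
        assert sv.stability_delta < 0

    def test_2x2_loop_two_new_pairs(self):
        s = _planted(stem=18, loop=4, bulges=[(9, "5prime", 2), (9, "3prime", 2)])
        gaps = stem_gaps(s)
        idx = next(i for i, (a, b) in enumerate(gaps) if a and b)
        sv = design_stabilizing(s, [idx])
        assert len(sv.substitutions) == 2
        assert len(sv.pairs_changed) == 2
        for i, j in sv.pairs_changed:
            assert can_pair(sv.variant_sequence[i], sv.variant_sequence[j])

    def test_one_sided_bulge_not_closable(self):
        s = _planted(stem=18, loop=4, bulges=[(9, "5prime", 3)])
        gaps = stem_gaps(s)
        idx = next(i for i, (a, b) in enumerate(gaps) if not (a and b))
        with pytest.raises(ValueError, match="not closable"):
            design_stabilizing(s, [idx])


class TestStabilizedCompensatory:
    def _sv_fixture(self):
        s = _planted(stem=18, loop=4, bulges=[(9, "5prime", 1), (9, "3prime", 1)])
        gaps = stem_gaps(s)
        idx = next(i for i, (a, b) in enumerate(gaps) if a and b)
        return s, design_stabilizing(s, [idx])

    def test_svc_reopens_with_unpairable_base(self):
        s, sv = self._sv_fixture()
        svc = design_stabilized_compensatory(sv, s)
        ((i, j),) = sv.pairs_changed
        # SV closed A/A -> A-U; SVC replaces the 5' A with a base that
        # cannot pair the mutated U (C/U or U/U), keeping the sequence
        # diverged from the original at both positions
        assert svc.variant_sequence[i] != s.sequence[i]
        assert not can_pair(svc.variant_sequence[i], svc.variant_sequence[j])
        assert svc.variant_sequence != s.sequence

    def test_svc_picks_first_nonpairing_base_on_mixed_stem(self):
        # mixed-composition stem with a 1x1 A/A internal loop: the first
        # candidate (C) does not recruit a new partner, so the
        # documented order yields A -> C, giving C/U unpaired
        seq = "GGCCAGCGAAACGCAGGCC"
        db_ = "((((.(((...))).))))"
        s = SecondaryStructure.from_dotbracket(seq, db_)
        assert fold_maxpair(seq).dotbracket == db_
        gaps = stem_gaps(s)
        idx = next(i for i, (a, b) in enumerate(gaps) if a and b)
        sv = design_stabilizing(s, [idx])
        svc = design_stabilized_compensatory(sv, s)
        ((i, j),) = sv.pairs_changed
        assert svc.variant_sequence[i] == "C"
        assert svc.variant_sequence[j] == "U"
        assert svc.predicted_structure.dotbracket == db_

    def test_svc_restores_original_topology(self):
        s, sv = self._sv_fixture()
        svc = design_stabilized_compensatory(sv, s)
        assert svc.predicted_structure.dotbracket == s.dotbracket
        assert svc.stability_delta == -0.0 or svc.stability_delta == 0.0

    def test_zero_pairs_is_identity(self):
        s = _planted()
        sv = design_stabilizing(s, [])
        assert sv.substitutions == []
        svc = design_stabilized_compensatory(sv, s)
        assert svc.substitutions == [] and svc.variant_sequence == s.sequence

    def test_delta_antisymmetry_on_perfect_fixture(self):
        s, sv = self._sv_fixture()
        svc = design_stabilized_compensatory(sv, s)
        assert svc.stability_delta - sv.stability_delta == -sv.stability_delta


class TestRoundTripsAndSigns:
    SPECS = [
        PlantSpec(16, 3), PlantSpec(17, 5), PlantSpec(20, 8),
        PlantSpec(16, 3, flank_lengths=(4, 4)),
        PlantSpec(18, 4, bulges=((7, "3prime", 2),)),
    ]

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: f"stem{s.stem_length}")
    def test_dv_dvc_round_trip_exact(self, spec):
        seq, db = plant_hairpin(spec)
        s = fold_maxpair(seq)
        assert s.dotbracket == db  # unique optimum by construction
        for k in (1, 2, 3):
            dv = design_destabilizing(s, s.pairs[:k])
            assert dv.stability_delta > 0
            dvc = design_compensatory(dv, s)
            assert dvc.predicted_structure.dotbracket == db
            assert dvc.variant_sequence != seq

    def test_sign_concordance_all_designs(self):
        s = _planted(stem=18, loop=4, bulges=[(9, "5prime", 1), (9, "3prime", 1)])
        signs_ok = []
        for pair in s.pairs:
            dv = design_destabilizing(s, [pair])
            signs_ok.append(dv.stability_delta > 0)
        gaps = stem_gaps(s)
        for idx, (g5, g3) in enumerate(gaps):
            if g5 and g3:
                signs_ok.append(design_stabilizing(s, [idx]).stability_delta < 0)
        assert all(signs_ok) and len(signs_ok) > 10


class TestShiftAndDelete:
    def test_insert3_coordinates(self):
        seq, _ = plant_hairpin(PlantSpec(16, 3, flank_lengths=(5, 20)))
        ctx = _ctx(seq)
        d = shift_or_delete_stem(ctx, "insert3", "AAA")
        assert len(d.variant_sequence) == len(seq) + 3
        assert d.offset_remap[9] == 9
        assert d.offset_remap[10] == 13  # former +10 becomes +13

    def test_insert_length_mismatch(self):
        seq, _ = plant_hairpin(PlantSpec(16, 3, flank_lengths=(5, 20)))
        with pytest.raises(ValueError, match="6 nt"):
            shift_or_delete_stem(_ctx(seq), "insert6", "AAA")

    def test_delete_stem_span_arithmetic(self):
        seq, _ = plant_hairpin(PlantSpec(16, 3, flank_lengths=(5, 20)))
        assert len(seq) == 60
        d = shift_or_delete_stem(_ctx(seq), "delete_stem")
        assert len(d.variant_sequence) == 60 - 46  # +12..+57 spans 46 nt
        assert d.offset_remap[11] == 11
        assert d.offset_remap[58] == 12  # first surviving base after the cut
        assert all(c not in d.offset_remap for c in range(12, 58))

    def test_insert6_displaces_but_preserves_classification(self):
        seq, _ = plant_hairpin(PlantSpec(16, 3, flank_lengths=(6, 19)))
        ctx = _ctx(seq)
        base_call = classify_structure(fold_maxpair(seq))
        assert base_call.passed
        d = shift_or_delete_stem(ctx, "insert6", "AAAAAA")
        var_call = classify_structure(d.predicted_structure)
        assert var_call.passed
        shift = (var_call.best_element.outer_pair[0]
                 - base_call.best_element.outer_pair[0])
        assert shift == 6

    def test_deletion_removes_the_stemloop(self):
        seq, _ = plant_hairpin(PlantSpec(16, 3, flank_lengths=(5, 20)))
        d = shift_or_delete_stem(_ctx(seq), "delete_stem")
        assert not classify_structure(d.predicted_structure).passed
        assert d.stability_delta > 0  # structure lost = destabilized
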