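"""Stem-loop variant design.

Implements the four substitution strategies used to probe how hairpin
stability controls stop-codon readthrough:

* **DV** (destabilizing): break selected stem pairs by mutating the
  3'-side base to the identity of its 5' partner (two identical bases
  never pair under Watson-Crick + G·U rules).
* **DVC** (compensatory): on top of a DV, mutate the 5' partner to the
  Watson-Crick complement of the mutated 3' base, restoring every broken
  pair while leaving the sequence different from the original at both
  positions.
* **SV** (stabilizing): close an internal loop by mutating its 3'-side
  bases to Watson-Crick complements of the opposing 5'-side bases.
* **SVC** (stabilized-compensatory): reopen SV-created pairs by mutating
  the 5'-side partner to a base that cannot pair with the mutated
  3' base, restoring the original loop topology.

Plus the position/deletion series on a stop-codon context window:
3/6/9-nt insertions immediately after stop-relative position +9, and deletion of
the stem-forming segment +12..+57.

``stability_delta`` is variant score minus base score on the MFE sign
convention (positive = destabilized) under the active folding backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from scrscreen.folding import (
    PairScoring,
    SecondaryStructure,
    can_pair,
    fold_maxpair,
)
from scrscreen.hairpins import enumerate_hairpin_elements
from scrscreen.stop_context import StopContext, WINDOW_OFFSET

__all__ = [
    "VariantDesign",
    "design_destabilizing",
    "design_compensatory",
    "design_stabilizing",
    "design_stabilized_compensatory",
    "shift_or_delete_stem",
    "stem_gaps",
]

VariantClass = Literal["DV", "DVC", "SV", "SVC", "shift", "deletion"]

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Deterministic preference order when a non-pairing substitute is needed.
_FALLBACK_ORDER = "CAGU"

Substitution = Tuple[int, str, str]  # (0-based position, from_base, to_base)


@dataclass
class VariantDesign:
    """A set of substitutions (or an indel edit) on a base sequence."""

    base_sequence: str
    substitutions: List[Substitution]
    variant_class: VariantClass
    variant_sequence: str
    predicted_structure: SecondaryStructure
    stability_delta: float
    pairs_changed: List[Tuple[int, int]] = field(default_factory=list)
    offset_remap: Optional[Dict[int, int]] = None

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("substitutions reference a position twice")
        if self.variant_class in {"DV", "DVC", "SV", "SVC"}:
            seq = list(self.base_sequence)
            for p, frm, to in self.substitutions:
                if seq[p] != frm:
                    raise ValueError(
                        f"substitution at {p}: from_base {frm} does not match "
                        f"sequence base {seq[p]}"
                    )
                seq[p] = to
            if "".join(seq) != self.variant_sequence:
                raise ValueError("substitutions do not reproduce variant_sequence")


def _apply(seq: str, subs: Sequence[Substitution]) -> str:
    out = list(seq)
    for p, frm, to in subs:
        if out[p] != frm:
            raise ValueError(f"from_base mismatch at position {p}")
        out[p] = to
    return "".join(out)


def _nonpairing_substitute(opposite: str, avoid: str) -> str:
    """First base (in a fixed order) unpairable with *opposite* and
    different from *avoid*."""
    for b in _FALLBACK_ORDER:
        if b != avoid and not can_pair(b, opposite):
            return b
    raise RuntimeError("no non-pairing substitute exists")  # unreachable


def _delta(base: str, variant: str, scoring: Optional[PairScoring]) -> Tuple[SecondaryStructure, float]:
    folded_base = fold_maxpair(base, scoring)
    folded_var = fold_maxpair(variant, scoring)
    assert folded_base.mfe is not None and folded_var.mfe is not None
    return folded_var, folded_var.mfe - folded_base.mfe


def _normalize_pairs(
    s: SecondaryStructure, pairs: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    norm = []
    for i, j in pairs:
        i, j = min(i, j), max(i, j)
        if s.pair_table.get(i) != j:
            raise ValueError(f"pair ({i}, {j}) not present in the structure")
        norm.append((i, j))
    return norm


def design_destabilizing(
    s: SecondaryStructure,
    pairs_to_break: Sequence[Tuple[int, int]],
    scoring: Optional[PairScoring] = None,
    mutate_side: Literal["3prime", "5prime"] = "3prime",
) -> VariantDesign:
    """Break stem pairs by point substitution (class DV).

    For each pair (i, j) the 3'-side base j is substituted with the
    identity of the 5' base i (identical bases cannot pair under WC+G·U
    rules); if that substitution could still pair — it cannot under the
    standard rules, but the check is never skipped — a documented
    fallback base is chosen instead.  ``mutate_side='5prime'`` mirrors
    the rule.  The stability delta must come out positive
    (destabilized); anything else raises.
    """
    pairs = _normalize_pairs(s, pairs_to_break)
    subs: List[Substitution] = []
    for i, j in pairs:
        keep, change = (i, j) if mutate_side == "3prime" else (j, i)
        new_base = s.sequence[keep]
        if can_pair(new_base, s.sequence[keep]) or new_base == s.sequence[change]:
            new_base = _nonpairing_substitute(s.sequence[keep], s.sequence[change])
        subs.append((change, s.sequence[change], new_base))
    variant = _apply(s.sequence, subs)
    structure, delta = _delta(s.sequence, variant, scoring)
    if pairs and delta <= 0:
        raise ValueError(
            f"destabilizing design did not raise the folding score "
            f"(delta = {delta:g})"
        )
    return VariantDesign(
        base_sequence=s.sequence,
        substitutions=subs,
        variant_class="DV",
        variant_sequence=variant,
        predicted_structure=structure,
        stability_delta=delta,
        pairs_changed=pairs,
    )


def design_compensatory(
    dv: VariantDesign,
    original: SecondaryStructure,
    scoring: Optional[PairScoring] = None,
) -> VariantDesign:
    """Restore DV-broken pairs by mutating the untouched partner (class
    DVC).

    Each broken pair (i, j) with j mutated to b gets i substituted by
    the Watson-Crick complement of b, recreating a WC pair while both
    positions now differ from the original sequence.
    """
    if dv.variant_class != "DV":
        raise ValueError(f"expected a DV design, got {dv.variant_class}")
    dv_by_pos = {p: to for p, _, to in dv.substitutions}
    subs: List[Substitution] = list(dv.substitutions)
    for i, j in dv.pairs_changed:
        if j in dv_by_pos:
            partner, mutated = i, dv_by_pos[j]
        else:
            partner, mutated = j, dv_by_pos[i]
        subs.append((partner, original.sequence[partner], _WC[mutated]))
    variant = _apply(original.sequence, subs)
    structure, delta = _delta(original.sequence, variant, scoring)
    return VariantDesign(
        base_sequence=original.sequence,
        substitutions=subs,
        variant_class="DVC",
        variant_sequence=variant,
        predicted_structure=structure,
        stability_delta=delta,
        pairs_changed=list(dv.pairs_changed),
    )


def stem_gaps(s: SecondaryStructure) -> List[Tuple[List[int], List[int]]]:
    """Helix interruptions of all hairpin elements, 5'→3'.

    Each entry is (5'-side unpaired positions, 3'-side unpaired
    positions) between two consecutive helix pairs; one of the two lists
    is empty for a one-sided bulge.  These are the identifiers accepted
    by :func:`design_stabilizing`.
    """
    gaps: List[Tuple[List[int], List[int]]] = []
    for e in enumerate_hairpin_elements(s):
        gaps.extend(g for g in e.gaps if g[0] or g[1])
    gaps.sort(key=lambda g: (g[0] or g[1])[0])
    return gaps


def design_stabilizing(
    s: SecondaryStructure,
    loops_to_close: Sequence[int],
    scoring: Optional[PairScoring] = None,
) -> VariantDesign:
    """Close internal loops by creating new WC pairs (class SV).

    ``loops_to_close`` indexes into :func:`stem_gaps`.  For each
    selected loop, min(k5, k3) opposing base pairs are formed aligned
    innermost-out: the 3'-side base is substituted with the WC
    complement of the opposing 5'-side base.  One-sided bulges cannot be
    closed by substitution and raise.  The stability delta must come out
    negative (stabilized).
    """
    gaps = stem_gaps(s)
    subs: List[Substitution] = []
    created: List[Tuple[int, int]] = []
    for idx in loops_to_close:
        g5, g3 = gaps[idx]
        if not g5 or not g3:
            raise ValueError(
                f"loop {idx} is a one-sided bulge: not closable by substitution"
            )
        k = min(len(g5), len(g3))
        for m in range(k):
            i = g5[len(g5) - 1 - m]  # innermost-out on the 5' side
            j = g3[m]                # innermost-out on the 3' side
            target = _WC[s.sequence[i]]
            if s.sequence[j] == target:
                raise ValueError(
                    f"positions {i}/{j} already complementary; nothing to close"
                )
            subs.append((j, s.sequence[j], target))
            created.append((i, j))
    variant = _apply(s.sequence, subs)
    structure, delta = _delta(s.sequence, variant, scoring)
    if subs and delta >= 0:
        raise ValueError(
            f"stabilizing design did not lower the folding score (delta = {delta:g})"
        )
    return VariantDesign(
        base_sequence=s.sequence,
        substitutions=subs,
        variant_class="SV",
        variant_sequence=variant,
        predicted_structure=structure,
        stability_delta=delta,
        pairs_changed=created,
    )


def design_stabilized_compensatory(
    sv: VariantDesign,
    original: SecondaryStructure,
    scoring: Optional[PairScoring] = None,
) -> VariantDesign:
    """Reopen SV-created pairs by mutating the 5'-side partner (class
    SVC).

    For each pair the SV created, the 5' base is substituted with the
    first base (fixed order C, A, G, U) that cannot pair with the
    SV-mutated 3' base and differs from the original base, restoring the
    original loop topology while keeping the sequence diverged.  An SV
    with zero created pairs yields the identity design.
    """
    if sv.variant_class != "SV":
        raise ValueError(f"expected an SV design, got {sv.variant_class}")
    sv_by_pos = {p: to for p, _, to in sv.substitutions}

    # Per reopened pair, the admissible substitutes in preference order:
    # unpairable with the SV-mutated 3' base and different from the
    # original 5' base.  Among admissible combinations, the first whose
    # refold restores the original topology is kept (the substitute
    # itself could otherwise recruit a new partner elsewhere in the stem).
    options: List[List[str]] = []
    for i, j in sv.pairs_changed:
        mutated_j = sv_by_pos[j]
        cand = [
            b
            for b in _FALLBACK_ORDER
            if b != original.sequence[i] and not can_pair(b, mutated_j)
        ]
        if not cand:
            raise RuntimeError("no non-pairing substitute exists")  # unreachable
        options.append(cand)

    def build(choice: Sequence[str]) -> List[Substitution]:
        subs = list(sv.substitutions)
        for (i, _), b in zip(sv.pairs_changed, choice):
            subs.append((i, original.sequence[i], b))
        return subs

    from itertools import product

    chosen: Optional[List[Substitution]] = None
    structure = delta = None
    for choice in product(*options) if options else [()]:
        subs = build(choice)
        variant = _apply(original.sequence, subs)
        structure, delta = _delta(original.sequence, variant, scoring)
        chosen = subs
        if structure.dotbracket == original.dotbracket:
            break
    assert chosen is not None and structure is not None and delta is not None
    subs = chosen
    variant = _apply(original.sequence, subs)
    return VariantDesign(
        base_sequence=original.sequence,
        substitutions=subs,
        variant_class="SVC",
        variant_sequence=variant,
        predicted_structure=structure,
        stability_delta=delta,
        pairs_changed=list(sv.pairs_changed),
    )


_INSERT_LENGTH = {"insert3": 3, "insert6": 6, "insert9": 9}

#: Paper coordinates of the stem-forming segment removed by delete_stem.
DELETE_SPAN = (12, 57)


def shift_or_delete_stem(
    ctx: StopContext,
    mode: Literal["insert3", "insert6", "insert9", "delete_stem"],
    insert_text: str = "",
    scoring: Optional[PairScoring] = None,
) -> VariantDesign:
    """Displace or remove the stem-forming segment of a context window.

    Insertion modes place 3/6/9 given nucleotides immediately after
    stop-relative position +9 (pushing the stem away from the stop codon);
    ``delete_stem`` removes stop-relative positions +12..+57 inclusive.  The
    returned design carries ``offset_remap`` mapping each surviving
    original stop-relative coordinate to its new stop-relative coordinate.
    """
    w = ctx.window
    if mode == "delete_stem":
        lo = ctx.window_index(DELETE_SPAN[0])
        hi = ctx.window_index(DELETE_SPAN[1])
        if insert_text:
            raise ValueError("delete_stem takes no insert_text")
        variant = w[:lo] + w[hi + 1:]
        removed = hi - lo + 1
        remap = {}
        for idx in range(len(w)):
            coord = idx + WINDOW_OFFSET
            if idx < lo:
                remap[coord] = coord
            elif idx > hi:
                remap[coord] = coord - removed
        variant_class: VariantClass = "deletion"
    elif mode in _INSERT_LENGTH:
        k = _INSERT_LENGTH[mode]
        insert_rna = insert_text.upper().replace("T", "U")
        if len(insert_rna) != k:
            raise ValueError(
                f"{mode} requires {k} nt of insert_text, got {len(insert_rna)}"
            )
        at = ctx.window_index(9) + 1  # immediately after stop-relative +9
        variant = w[:at] + insert_rna + w[at:]
        remap = {}
        for idx in range(len(w)):
            coord = idx + WINDOW_OFFSET
            remap[coord] = coord if idx < at else coord + k
        variant_class = "shift"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    structure, delta = _delta(w, variant, scoring)
    return VariantDesign(
        base_sequence=w,
        substitutions=[],
        variant_class=variant_class,
        variant_sequence=variant,
        predicted_structure=structure,
        stability_delta=delta,
        offset_remap=remap,
    )
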