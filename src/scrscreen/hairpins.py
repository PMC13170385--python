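"""Hairpin-element enumeration and the stem-loop classifier.

A *hairpin element* is one terminal loop plus the helix that closes it,
extended outward through consecutive base pairs.  Interruptions where at
least one strand side is unpaired (bulges and internal loops) are
absorbed into the element and recorded as per-side bulge runs; the
element stops at a multiloop junction (a pair enclosing two or more
sibling helices) or at the exterior loop.

A sequence is called a stem-loop when its predicted structure contains
at least one element with span >= 35 nt, a terminal loop of 3-10 nt and
no bulge run longer than 2 nt (the ``paper2026`` preset); every
threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Set, Tuple

from scrscreen.folding import SecondaryStructure

__all__ = [
    "HairpinCriteria",
    "HairpinElement",
    "HairpinCall",
    "DEFAULT_CRITERIA",
    "CRITERIA_PRESETS",
    "enumerate_hairpin_elements",
    "evaluate_hairpin",
    "classify_structure",
]

FailureReason = Literal["no_hairpin", "span", "loop", "bulge", "branched_only"]


@dataclass(frozen=True)
class HairpinCriteria:
    """Stem-loop acceptance thresholds.

    ``min_span`` is the length of the whole element, outer pair to outer
    pair, in nucleotides.  ``bulge_mode`` controls whether the two sides
    of an internal loop are limited individually (default) or jointly by
    ``bulge_max``.
    """

    min_span: int = 35
    loop_min: int = 3
    loop_max: int = 10
    bulge_max: int = 2
    bulge_mode: Literal["individual", "joint"] = "individual"

    def __post_init__(self) -> None:
        if not (0 < self.loop_min <= self.loop_max):
            raise ValueError("need 0 < loop_min <= loop_max")
        if self.min_span < self.loop_min + 2:
            raise ValueError("min_span must be >= loop_min + 2")
        if self.bulge_max < 0:
            raise ValueError("bulge_max must be >= 0")


#: The criteria used for the genome-wide screen.
DEFAULT_CRITERIA = HairpinCriteria()

CRITERIA_PRESETS: Dict[str, HairpinCriteria] = {"paper2026": DEFAULT_CRITERIA}


@dataclass
class HairpinElement:
    """One hairpin: closing helix, terminal loop, bulge runs.

    ``helix_pairs`` runs outer to innermost; ``bulge_runs`` lists
    ``(side, length)`` with side ``"5prime"`` or ``"3prime"``;
    ``gaps`` keeps, per helix interruption, the unpaired positions on
    each side (needed by variant design to close internal loops).
    """

    outer_pair: Tuple[int, int]
    terminal_loop: Tuple[int, int]  # first/last unpaired position, inclusive
    helix_pairs: List[Tuple[int, int]]
    bulge_runs: List[Tuple[str, int]] = field(default_factory=list)
    gaps: List[Tuple[List[int], List[int]]] = field(default_factory=list)

    @property
    def span(self) -> int:
        i, j = self.outer_pair
        return j - i + 1

    @property
    def loop_length(self) -> int:
        a, b = self.terminal_loop
        return b - a + 1

    def internal_loops(self) -> List[Tuple[List[int], List[int]]]:
        """Helix interruptions unpaired on *both* sides."""
        return [(g5, g3) for g5, g3 in self.gaps if g5 and g3]


@dataclass
class HairpinCall:
    """Pass/fail verdict for one structure (or one element)."""

    passed: bool
    best_element: Optional[HairpinElement] = None
    failure_reasons: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.passed != (not self.failure_reasons):
            raise ValueError("passed must be equivalent to empty failure_reasons")


def _children_forest(
    pairs: List[Tuple[int, int]]
) -> Tuple[Dict[Tuple[int, int], List[Tuple[int, int]]], Dict[Tuple[int, int], Optional[Tuple[int, int]]]]:
    """Nesting forest of pairs: children and parent maps."""
    children: Dict[Tuple[int, int], List[Tuple[int, int]]] = {p: [] for p in pairs}
    parent: Dict[Tuple[int, int], Optional[Tuple[int, int]]] = {}
    stack: List[Tuple[int, int]] = []
    for p in sorted(pairs):
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent[p] = stack[-1] if stack else None
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)
    return children, parent


def enumerate_hairpin_elements(s: SecondaryStructure) -> List[HairpinElement]:
    """Enumerate hairpin elements, one per terminal loop.

    Each element starts at the innermost pair closing a run of unpaired
    positions and extends outward through consecutive pairs, absorbing
    one-sided bulges and two-sided internal loops (recorded per side as
    ``bulge_runs``) and stopping at a multiloop junction or the
    exterior.  Elements are disjoint in their helix pairs; fully
    unpaired structures give an empty list.
    """
    pairs = s.pairs
    if not pairs:
        return []
    children, parent = _children_forest(pairs)

    elements: List[HairpinElement] = []
    for p in pairs:
        if children[p]:
            continue  # not a terminal loop
        helix_inner_out = [p]
        gaps_inner_out: List[Tuple[List[int], List[int]]] = []
        cur = p
        while True:
            par = parent[cur]
            if par is None or len(children[par]) != 1:
                break
            g5 = list(range(par[0] + 1, cur[0]))
            g3 = list(range(cur[1] + 1, par[1]))
            gaps_inner_out.append((g5, g3))
            helix_inner_out.append(par)
            cur = par
        helix = list(reversed(helix_inner_out))
        gaps = list(reversed(gaps_inner_out))
        bulges: List[Tuple[str, int]] = []
        for g5, g3 in gaps:
            if g5:
                bulges.append(("5prime", len(g5)))
            if g3:
                bulges.append(("3prime", len(g3)))
        elements.append(
            HairpinElement(
                outer_pair=helix[0],
                terminal_loop=(p[0] + 1, p[1] - 1),
                helix_pairs=helix,
                bulge_runs=bulges,
                gaps=gaps,
            )
        )
    elements.sort(key=lambda e: e.outer_pair)
    return elements


def evaluate_hairpin(e: HairpinElement, c: HairpinCriteria = DEFAULT_CRITERIA) -> HairpinCall:
    """Evaluate one element against the criteria.

    Passes iff span >= ``min_span``, the terminal loop length lies in
    ``[loop_min, loop_max]`` and every bulge run is <= ``bulge_max``
    (in joint mode: the two sides of each interruption sum to
    <= ``bulge_max``).
    """
    reasons: Set[str] = set()
    if e.span < c.min_span:
        reasons.add("span")
    if not (c.loop_min <= e.loop_length <= c.loop_max):
        reasons.add("loop")
    if c.bulge_mode == "joint":
        if any(len(g5) + len(g3) > c.bulge_max for g5, g3 in e.gaps):
            reasons.add("bulge")
    else:
        if any(length > c.bulge_max for _, length in e.bulge_runs):
            reasons.add("bulge")
    return HairpinCall(
        passed=not reasons,
        best_element=e if not reasons else None,
        failure_reasons=reasons,
    )


def classify_structure(
    s: SecondaryStructure, c: HairpinCriteria = DEFAULT_CRITERIA
) -> HairpinCall:
    """Label a structure as a stem-loop if any element qualifies.

    ``best_element`` is the passing element of greatest span (ties go to
    the 5'-most).  When nothing passes, failure reasons are aggregated
    over all elements; a fully unpaired structure fails with
    ``no_hairpin``, and ``branched_only`` is added when the structure
    contains a multiloop junction and no element qualified.
    """
    elements = enumerate_hairpin_elements(s)
    if not elements:
        return HairpinCall(passed=False, failure_reasons={"no_hairpin"})
    passing = [e for e in elements if evaluate_hairpin(e, c).passed]
    if passing:
        best = max(passing, key=lambda e: (e.span, -e.outer_pair[0]))
        return HairpinCall(passed=True, best_element=best)
    reasons: Set[str] = set()
    for e in elements:
        reasons |= evaluate_hairpin(e, c).failure_reasons
    children, _ = _children_forest(s.pairs)
    if any(len(kids) >= 2 for kids in children.values()):
        reasons.add("branched_only")
    return HairpinCall(passed=False, failure_reasons=reasons)
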