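"""Independent brute-force oracles used only by the tests.

Deliberately written with different algorithms and data layouts than the
package code they check: structure enumeration instead of dynamic
programming, direct closure scans instead of a nesting forest.
"""

from __future__ import annotations

import random
from typing import Dict, Iterator, List, Optional, Set, Tuple

_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_WEIGHTS = {frozenset("GC"): 3.0, frozenset("AU"): 2.0, frozenset("GU"): 1.0}


def pair_weight(a: str, b: str) -> float:
    if (a, b) not in _PAIRABLE:
        return 0.0
    return _WEIGHTS[frozenset((a, b))]


def all_nested_structures(
    seq: str, min_loop: int = 3
) -> Iterator[Tuple[Tuple[int, int], ...]]:
    """Yield every nested, pairing-rule-respecting structure of *seq* as
    a sorted tuple of (i, j) pairs (exhaustive; small n only)."""
    n = len(seq)

    def rec(i: int, j: int) -> Iterator[Tuple[Tuple[int, int], ...]]:
        # structures of seq[i..j] inclusive
        if i > j:
            yield ()
            return
        # i unpaired
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if pair_weight(seq[i], seq[k]) > 0.0:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield ((i, k),) + inner + outer

    for s in rec(0, n - 1):
        yield tuple(sorted(s))


def best_score_bruteforce(seq: str, min_loop: int = 3) -> float:
    """Maximum total pair weight over all nested structures, by plain
    recursion with no memoization (explores the full structure space)."""

    def rec(i: int, j: int) -> float:
        if i >= j:
            return 0.0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            w = pair_weight(seq[i], seq[k])
            if w > 0.0:
                cand = w + rec(i + 1, k - 1) + rec(k + 1, j)
                if cand > best:
                    best = cand
        return best

    return rec(0, len(seq) - 1)


def score_structure(seq: str, pairs) -> float:
    return sum(pair_weight(seq[i], seq[j]) for i, j in pairs)


def random_sequence(rng: random.Random, n: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def random_nested_dotbracket(rng: random.Random, n: int, min_loop: int = 3) -> str:
    """Random valid nested dot-bracket of length *n* (seeded): every
    pair encloses at least *min_loop* positions."""

    def build(length: int) -> str:
        if length == 0:
            return ""
        if length < min_loop + 2 or rng.random() < 0.3:
            k = rng.randint(1, min(3, length))
            return "." * k + build(length - k)
        inner = rng.randint(min_loop, length - 2)
        return "(" + build(inner) + ")" + build(length - 2 - inner)

    db = build(n)
    assert len(db) == n
    return db


# ---------------------------------------------------------------------------
# hairpin-element oracle: maximal closure around each terminal pair


def _pair_map(db: str) -> Dict[int, int]:
    stack: List[int] = []
    table: Dict[int, int] = {}
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            i = stack.pop()
            table[i] = idx
            table[idx] = i
    return table


def hairpin_elements_oracle(db: str) -> List[dict]:
    """Enumerate hairpin elements directly from the dot-bracket string.

    For every terminal closing pair (nothing paired strictly inside),
    grow the maximal closure outward: the next enclosing pair is
    accepted while every position between the two pairs, on both sides,
    is unpaired; growth stops when the gap region contains another pair
    (multiloop junction) or no enclosing pair exists.
    """
    table = _pair_map(db)
    pairs = sorted((i, j) for i, j in table.items() if i < j)
    elements = []
    for (i, j) in pairs:
        if any(i < k < j for k in table):
            continue  # not a terminal loop
        out_i, out_j = i, j
        bulges: List[Tuple[str, int]] = []
        while True:
            # candidate enclosing pair: nearest paired position left of out_i
            cand = None
            for a in range(out_i - 1, -1, -1):
                if a in table:
                    cand = (a, table[a])
                    break
                # keep scanning through unpaired positions
            if cand is None or not (cand[0] < out_i and cand[1] > out_j):
                break
            a, b = cand
            between_left = [p for p in range(a + 1, out_i) if p in table]
            between_right = [p for p in range(out_j + 1, b) if p in table]
            if between_left or between_right:
                break  # junction: another helix intervenes
            if out_i - a - 1 > 0:
                bulges.append(("5prime", out_i - a - 1))
            if b - out_j - 1 > 0:
                bulges.append(("3prime", b - out_j - 1))
            out_i, out_j = a, b
        elements.append(
            {
                "outer": (out_i, out_j),
                "span": out_j - out_i + 1,
                "loop": j - i - 1,
                "bulges": sorted(bulges),
            }
        )
    return elements


def stemloop_verdict_oracle(
    db: str,
    min_span: int = 35,
    loop_min: int = 3,
    loop_max: int = 10,
    bulge_max: int = 2,
) -> bool:
    """Independent pass/fail verdict for the stem-loop criteria."""
    for e in hairpin_elements_oracle(db):
        if (
            e["span"] >= min_span
            and loop_min <= e["loop"] <= loop_max
            and all(l <= bulge_max for _, l in e["bulges"])
        ):
            return True
    return False
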