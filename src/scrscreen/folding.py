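"""RNA secondary structures as pair tables, dot-bracket interconversion,
and a self-contained maximum base-pairing folder.

Two folding backends exist side by side and are never mixed silently:

* ``maxpair`` — a Nussinov-style dynamic program over intervals that
  maximizes a weighted count of base pairs (GC > AU > GU by default)
  subject to a minimum hairpin-loop length.  It is fully deterministic,
  dependency-free, and is the backend used for synthetic fixtures whose
  ground-truth structure is the provably unique optimum.
* ``external`` — thermodynamic minimum-free-energy structures computed by
  ViennaRNA's ``RNAfold`` and ingested from its text output (see
  :func:`scrscreen.io.read_rnafold_file`), or obtained directly via
  :func:`fold_rnafold` when the binary is on ``PATH``.

The ``maxpair`` score is reported negated (``mfe = -total_weight``) so
that "lower = more stable" holds for both backends.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

__all__ = [
    "PairScoring",
    "SecondaryStructure",
    "can_pair",
    "pairs_from_dotbracket",
    "dotbracket_from_pairs",
    "fold_maxpair",
    "fold_rnafold",
    "rnafold_available",
]

RNA_ALPHABET = frozenset("ACGUN")

#: Watson-Crick plus wobble pairs.
_PAIRABLE = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


def can_pair(a: str, b: str) -> bool:
    """True if bases *a* and *b* can form a Watson-Crick or G·U wobble pair."""
    return (a, b) in _PAIRABLE


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    for pos, ch in enumerate(s):
        if ch not in RNA_ALPHABET:
            raise ValueError(f"illegal base {ch!r} at position {pos}")
    return s


@dataclass(frozen=True)
class PairScoring:
    """Weights for the max-pair folder, one per pair class.

    The defaults (GC=3, AU=2, GU=1) rank pair stability in the
    conventional order without attempting thermodynamics; ``min_loop``
    is the minimum number of unpaired bases closed by any pair.
    """

    gc: float = 3.0
    au: float = 2.0
    gu: float = 1.0
    min_loop: int = 3
    allow_gu: bool = True

    def __post_init__(self) -> None:
        if self.gc <= 0 or self.au <= 0 or self.gu <= 0:
            raise ValueError("pair weights must be positive")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def weight(self, a: str, b: str) -> float:
        if not can_pair(a, b):
            return 0.0
        if {a, b} == {"G", "C"}:
            return self.gc
        if {a, b} == {"A", "U"}:
            return self.au
        return self.gu if self.allow_gu else 0.0

    def weight_matrix(self) -> np.ndarray:
        w = np.zeros((5, 5), dtype=np.float64)
        for (a, b) in _PAIRABLE:
            w[_ENC[a], _ENC[b]] = self.weight(a, b)
        return w


@dataclass
class SecondaryStructure:
    """A sequence with one nested secondary structure.

    ``pair_table`` maps every paired 0-based position to its partner and
    is symmetric; unpaired positions are absent.  ``mfe`` is in kcal/mol
    for the external backend and ``-total_pair_weight`` for ``maxpair``.
    """

    sequence: str
    dotbracket: str
    pair_table: Dict[int, int] = field(repr=False)
    mfe: Optional[float] = None
    backend_tag: str = "external"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError(
                f"sequence length {len(self.sequence)} != structure length "
                f"{len(self.dotbracket)}"
            )
        for i, j in self.pair_table.items():
            if self.pair_table.get(j) != i:
                raise ValueError(f"pair table not symmetric at ({i}, {j})")

    @classmethod
    def from_dotbracket(
        cls,
        sequence: str,
        dotbracket: str,
        mfe: Optional[float] = None,
        backend_tag: str = "external",
    ) -> "SecondaryStructure":
        seq = normalize_rna(sequence)
        return cls(
            sequence=seq,
            dotbracket=dotbracket,
            pair_table=pairs_from_dotbracket(dotbracket),
            mfe=mfe,
            backend_tag=backend_tag,
        )

    @property
    def pairs(self) -> list[Tuple[int, int]]:
        """Sorted list of (i, j) pairs with i < j."""
        return sorted((i, j) for i, j in self.pair_table.items() if i < j)

    def n_pairs(self) -> int:
        return len(self.pair_table) // 2

    def validate(self, scoring: Optional[PairScoring] = None) -> None:
        """Check nesting, minimum loop and (optionally) pairing rules."""
        min_loop = scoring.min_loop if scoring is not None else 0
        open_spans: list[Tuple[int, int]] = []
        for i, j in self.pairs:
            if j - i - 1 < min_loop:
                raise ValueError(f"pair ({i}, {j}) closes a loop shorter than {min_loop}")
            for k, l in open_spans:
                if k < i <= l < j:
                    raise ValueError(f"crossing pairs ({k}, {l}) and ({i}, {j})")
            open_spans.append((i, j))
            if scoring is not None and not can_pair(self.sequence[i], self.sequence[j]):
                raise ValueError(
                    f"bases {self.sequence[i]}-{self.sequence[j]} at ({i}, {j}) cannot pair"
                )


def pairs_from_dotbracket(db: str) -> Dict[int, int]:
    """Parse dot-bracket text into a symmetric pair table by stack matching.

    Raises ``ValueError`` (with the offending index) on a premature ``)``
    or an unclosed ``(`` at end of string; pseudoknot bracket levels are
    not supported.
    """
    table: Dict[int, int] = {}
    stack: list[int] = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at index {idx}")
            i = stack.pop()
            table[i] = idx
            table[idx] = i
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r} at index {idx}")
    if stack:
        raise ValueError(f"unmatched '(' at index {stack[-1]} (end of string reached)")
    return table


def dotbracket_from_pairs(pairs: Dict[int, int] | Iterable[Tuple[int, int]], n: int) -> str:
    """Render a nested pair table as dot-bracket text (inverse of
    :func:`pairs_from_dotbracket`).

    Crossing pairs raise ``ValueError`` — pseudoknots are unsupported
    throughout the package.
    """
    if isinstance(pairs, dict):
        plist = sorted((i, j) for i, j in pairs.items() if i < j)
    else:
        plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    out = ["."] * n
    prev: list[Tuple[int, int]] = []
    for i, j in plist:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i}, {j}) out of range for length {n}")
        if out[i] != "." or out[j] != ".":
            raise ValueError(f"position reused by pair ({i}, {j})")
        for k, l in prev:
            if k < i <= l < j:
                raise ValueError("pseudoknot unsupported: crossing pairs "
                                 f"({k}, {l}) and ({i}, {j})")
        prev.append((i, j))
        out[i] = "("
        out[j] = ")"
    return "".join(out)


# ---------------------------------------------------------------------------
# max-pair dynamic program


def _fill_py(code: np.ndarray, w: np.ndarray, min_loop: int) -> np.ndarray:
    n = code.shape[0]
    m = np.zeros((n + 1, n + 1), dtype=np.float64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = m[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                wk = w[code[i], code[k]]
                if wk > 0.0:
                    cand = wk + m[i + 1, k - 1] + m[k + 1, j]
                    if cand > best:
                        best = cand
            m[i, j] = best
    return m


try:  # compiled fill: genome-scale screens fold thousands of 60-80 nt windows
    from numba import njit

    _fill_nb = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover - numba always present in practice
    _fill_nb = None


def _fill(code: np.ndarray, w: np.ndarray, min_loop: int) -> np.ndarray:
    if _fill_nb is not None:
        return _fill_nb(code, w, min_loop)
    return _fill_py(code, w, min_loop)


def fold_maxpair(seq: str, scoring: PairScoring | None = None) -> SecondaryStructure:
    """Fold *seq* by weighted base-pair maximization.

    Dynamic program over intervals: ``M[i, j]`` is the best total pair
    weight on ``seq[i..j]`` with position ``i`` either unpaired or paired
    to some ``k`` (``k - i - 1 >= min_loop``).  The traceback is
    deterministic: whenever pairing ``i`` attains the optimum, ``i`` is
    paired with the smallest admissible partner; N never pairs.

    Returns a :class:`SecondaryStructure` with ``backend_tag='maxpair'``
    and ``mfe`` set to the negated total weight so that more stable
    structures score lower, matching the MFE sign convention.
    """
    if scoring is None:
        scoring = PairScoring()
    s = normalize_rna(seq)
    if not s:
        raise ValueError("empty sequence")
    n = len(s)
    code = np.fromiter((_ENC[c] for c in s), dtype=np.int8, count=n)
    w = scoring.weight_matrix()
    m = _fill(code, w, scoring.min_loop)

    table: Dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < scoring.min_loop + 1:
            continue
        target = m[i, j]
        if target == 0.0:
            continue
        paired = False
        for k in range(i + scoring.min_loop + 1, j + 1):
            wk = w[code[i], code[k]]
            if wk > 0.0 and wk + m[i + 1, k - 1] + m[k + 1, j] == target:
                table[i] = k
                table[k] = i
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    total = float(m[0, n - 1])
    return SecondaryStructure(
        sequence=s,
        dotbracket=dotbracket_from_pairs(table, n),
        pair_table=table,
        mfe=-total,
        backend_tag="maxpair",
    )


# ---------------------------------------------------------------------------
# external thermodynamic backend (ViennaRNA RNAfold on PATH)


def rnafold_available() -> bool:
    """True if the ``RNAfold`` executable is on PATH."""
    return shutil.which("RNAfold") is not None


def fold_rnafold(seq: str, identifier: str = "seq") -> SecondaryStructure:
    """Fold with the external thermodynamic folder (``RNAfold`` subprocess).

    Requires ViennaRNA's ``RNAfold`` on PATH; raises ``RuntimeError``
    otherwise.  The returned structure carries ``backend_tag='external'``
    and the MFE in kcal/mol parsed from RNAfold's output.
    """
    if not rnafold_available():
        raise RuntimeError("RNAfold executable not found on PATH")
    s = normalize_rna(seq)
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input=f">{identifier}\n{s}\n",
        capture_output=True,
        text=True,
        check=True,
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    # header, sequence, "dotbracket ( mfe)"
    struct_line = lines[2]
    db = struct_line.split(None, 1)[0]
    lparen = struct_line.rfind("(")
    mfe = float(struct_line[lparen + 1:].rstrip(")").strip())
    return SecondaryStructure.from_dotbracket(s, db, mfe=mfe, backend_tag="external")


def structure_score(s: SecondaryStructure, scoring: PairScoring | None = None) -> float:
    """Total pair weight of an existing structure under *scoring*."""
    if scoring is None:
        scoring = PairScoring()
    return sum(scoring.weight(s.sequence[i], s.sequence[j]) for i, j in s.pairs)
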