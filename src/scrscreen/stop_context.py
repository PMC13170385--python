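"""Stop-codon context extraction.

Selects each gene's most-upstream 3'UTR (the transcript whose stop codon
lies most 5' in gene orientation), excises the first W nucleotides of
the spliced 3'UTR after the stop codon, and exposes the +1-at-stop
coordinate convention: position +1 is the first base of the stop codon,
so the window occupies +4 ... +(3+W) and the +4..+9 hexamer is the
readthrough motif context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from scrscreen.io import TranscriptModel

__all__ = [
    "GeneSkipped",
    "StopCodonError",
    "StopContext",
    "select_primary_utr",
    "extract_stop_context",
    "scr_motif_context",
    "reverse_complement",
    "WINDOW_OFFSET",
]

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: Paper coordinate of window index 0 (+1..+3 is the stop codon itself).
WINDOW_OFFSET = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GeneSkipped(Exception):
    """Raised when a gene cannot be screened (no 3'UTR, bad stop, ...)."""


class StopCodonError(GeneSkipped):
    """The last CDS triplet is not a stop codon (strict mode)."""


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class StopContext:
    """One gene's stop codon plus the first W nt of its 3'UTR.

    ``window`` is RNA in transcript orientation; ``genomic_positions``
    holds, per window index, the 0-based genomic coordinate of that
    base.  ``offset_map`` maps each window index to its stop-relative
    coordinate (+4, +5, ...) and genomic coordinate.
    """

    gene_id: str
    transcript_id: str
    stop_codon: str
    window: str
    window_length_requested: int
    strand: str
    truncated: bool
    genomic_positions: Tuple[int, ...]
    chromosome: str = ""

    def __post_init__(self) -> None:
        if len(self.window) > self.window_length_requested:
            raise ValueError("window longer than requested length")
        if len(self.genomic_positions) != len(self.window):
            raise ValueError("genomic_positions length mismatch")

    @property
    def offset_map(self) -> Dict[int, Tuple[int, int]]:
        return {
            i: (i + WINDOW_OFFSET, g)
            for i, g in enumerate(self.genomic_positions)
        }

    def stop_coord(self, window_index: int) -> int:
        if not 0 <= window_index < len(self.window):
            raise IndexError(f"window index {window_index} out of range")
        return window_index + WINDOW_OFFSET

    def window_index(self, stop_coord: int) -> int:
        idx = stop_coord - WINDOW_OFFSET
        if not 0 <= idx < len(self.window):
            raise IndexError(f"stop-relative coordinate +{stop_coord} outside window")
        return idx


def _utr_rank(t: TranscriptModel) -> int:
    """Position of the 3'UTR start, increasing 3'-ward in gene orientation."""
    start = t.utr3_start_transcript_orientation()
    assert start is not None
    return start if t.strand == "+" else -start


def select_primary_utr(transcripts_of_gene: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick the transcript whose stop codon lies most 5' in gene
    orientation (the most upstream annotated 3'UTR).

    Ties are broken by longer annotated 3'UTR, then lexicographic
    transcript_id.  Raises :class:`GeneSkipped` when no transcript has a
    3'UTR.
    """
    if not transcripts_of_gene:
        raise ValueError("no transcripts given")
    with_utr = [t for t in transcripts_of_gene if t.utr3_segments]
    if not with_utr:
        raise GeneSkipped(
            f"gene {transcripts_of_gene[0].gene_id}: no transcript with a 3'UTR"
        )
    strands = {t.strand for t in with_utr}
    if len(strands) > 1:
        raise ValueError("transcripts of one gene on both strands")
    return min(with_utr, key=lambda t: (_utr_rank(t), -t.utr3_length(), t.transcript_id))


def _spliced(genome_seq: str, segments: Sequence[Tuple[int, int]], strand: str) -> str:
    """Concatenate exonic segments in transcript orientation (DNA)."""
    parts: List[str] = []
    for s, e in segments:
        piece = genome_seq[s:e]
        parts.append(piece if strand == "+" else reverse_complement(piece))
    return "".join(parts)


def _positions(segments: Sequence[Tuple[int, int]], strand: str) -> List[int]:
    pos: List[int] = []
    for s, e in segments:
        pos.extend(range(s, e) if strand == "+" else range(e - 1, s - 1, -1))
    return pos


def extract_stop_context(
    genome: Mapping[str, str],
    transcript: TranscriptModel,
    W: int = 60,
    strict: bool = True,
) -> StopContext:
    """Extract the stop codon and the first W nt of the spliced 3'UTR.

    The stop codon is the last 3 CDS nucleotides in transcript
    orientation (Ensembl convention: the CDS includes the stop).  The
    window is the spliced 3'UTR's first W bases, reverse-complemented
    for minus-strand genes and converted to RNA.  UTRs shorter than W
    yield shorter windows flagged ``truncated``.

    In strict mode a non-stop last triplet raises
    :class:`StopCodonError`; set ``strict=False`` to permit it.
    """
    if not transcript.utr3_segments:
        raise GeneSkipped(f"gene {transcript.gene_id}: transcript has no 3'UTR")
    chrom_seq = genome[transcript.chromosome]
    if transcript.cds_length() < 3:
        raise ValueError(
            f"transcript {transcript.transcript_id}: CDS shorter than 3 nt"
        )
    cds = _spliced(chrom_seq, transcript.cds_segments, transcript.strand)
    stop_codon = cds[-3:].upper().replace("T", "U")
    if strict and stop_codon not in STOP_CODONS:
        raise StopCodonError(
            f"gene {transcript.gene_id}: last CDS triplet {stop_codon} "
            f"is not a stop codon"
        )
    utr = _spliced(chrom_seq, transcript.utr3_segments, transcript.strand)
    window_dna = utr[:W]
    positions = _positions(transcript.utr3_segments, transcript.strand)[:W]
    return StopContext(
        gene_id=transcript.gene_id,
        transcript_id=transcript.transcript_id,
        stop_codon=stop_codon,
        window=window_dna.upper().replace("T", "U"),
        window_length_requested=W,
        strand=transcript.strand,
        truncated=len(window_dna) < W,
        genomic_positions=tuple(positions),
        chromosome=transcript.chromosome,
    )


def scr_motif_context(ctx: StopContext) -> Tuple[str, str]:
    """Return the stop triplet and the +4..+9 hexamer (the readthrough
    motif context).  Raises on windows shorter than 6 nt."""
    if len(ctx.window) < 6:
        raise ValueError(
            f"gene {ctx.gene_id}: context too short ({len(ctx.window)} nt < 6)"
        )
    return ctx.stop_codon, ctx.window[:6]
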