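"""Reading and writing the formats the pipeline touches.

FASTA, GFF3 (Ensembl dialect), RNAfold-style structure files and tabular
outputs.  Coordinates are 1-based inclusive on disk (GFF3) and 0-based
half-open everywhere inside the package; the conversion happens in this
module only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO

from scrscreen.folding import pairs_from_dotbracket

__all__ = [
    "SequenceRecord",
    "TranscriptModel",
    "StructureFileEntry",
    "read_fasta",
    "write_fasta",
    "read_gff_transcripts",
    "read_rnafold_file",
    "write_rnafold_file",
    "write_screen_table",
    "write_gff3",
    "write_bed6",
    "SCREEN_TABLE_COLUMNS",
]

_NUCLEOTIDES = frozenset("ACGTUN")

Interval = Tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; residues stored uppercase.

    ``softmask[i]`` is True where the input letter was lowercase
    (softmasked).  Softmasked bases are treated as ordinary bases by all
    downstream operations; the flags are retained only so FASTA
    round-trips preserve the input.
    """

    identifier: str
    residues: str
    softmask: Optional[Tuple[bool, ...]] = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("empty record identifier")
        if not self.residues:
            raise ValueError(f"record {self.identifier!r} has no residues")
        if self.softmask is not None and len(self.softmask) != len(self.residues):
            raise ValueError("softmask length mismatch")


@dataclass
class TranscriptModel:
    """A transcript with CDS and 3'UTR segments in genomic coordinates.

    Segments are 0-based half-open and ordered in *transcript*
    orientation (ascending genomic position on ``+``, descending on
    ``-``), so the first ``utr3_segments`` entry is always the one
    immediately after the stop codon.  Per the Ensembl convention the
    CDS includes the stop codon and the three_prime_UTR starts just
    after it.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    cds_segments: List[Interval] = field(default_factory=list)
    utr3_segments: List[Interval] = field(default_factory=list)
    biotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        for name, segs in (("cds", self.cds_segments), ("utr3", self.utr3_segments)):
            for start, end in segs:
                if start >= end:
                    raise ValueError(f"empty {name} segment ({start}, {end})")
            ordered = sorted(segs)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping {name} segments in {self.transcript_id}")

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def utr3_length(self) -> int:
        return sum(e - s for s, e in self.utr3_segments)

    def utr3_start_transcript_orientation(self) -> Optional[int]:
        """Genomic coordinate of the first 3'UTR base in transcript order."""
        if not self.utr3_segments:
            return None
        s, e = self.utr3_segments[0]
        return s if self.strand == "+" else e - 1


@dataclass
class StructureFileEntry:
    """One record of an RNAfold-style structure file."""

    identifier: str
    sequence: str
    dotbracket: str
    mfe: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError(
                f"entry {self.identifier!r}: sequence length {len(self.sequence)} "
                f"!= structure length {len(self.dotbracket)}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated; T and U are both accepted;
    lowercase (softmasked) letters are uppercased with the mask retained
    per position.  Raises on empty files, duplicate identifiers, and
    illegal characters or internal whitespace (with the offending
    position within the record's residues).
    """
    # SeqIO silently drops whitespace inside sequence lines, so internal
    # whitespace is detected from the raw text first (with the position
    # inside the record's concatenated residues).
    ident: Optional[str] = None
    pos = 0
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            ident = line[1:].split()[0] if line[1:].split() else line[1:]
            pos = 0
            continue
        if ident is None:
            continue
        for ch in line:
            if ch.isspace():
                raise ValueError(
                    f"record {ident!r}: whitespace in sequence at position {pos}"
                )
            pos += 1

    records: List[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            ident = rec.id
            if ident in seen:
                raise ValueError(f"duplicate identifier {ident!r}")
            seen.add(ident)
            raw = str(rec.seq)
            residues: list[str] = []
            mask: list[bool] = []
            for pos, ch in enumerate(raw):
                up = ch.upper()
                if up.isspace():
                    raise ValueError(
                        f"record {ident!r}: whitespace in sequence at position {pos}"
                    )
                if up not in _NUCLEOTIDES:
                    raise ValueError(
                        f"record {ident!r}: illegal character {ch!r} at position {pos}"
                    )
                residues.append(up)
                mask.append(ch.islower())
            records.append(
                SequenceRecord(
                    identifier=ident,
                    residues="".join(residues),
                    softmask=tuple(mask) if any(mask) else None,
                )
            )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, restoring softmasked lowercase letters."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.residues
            if rec.softmask is not None:
                seq = "".join(
                    c.lower() if m else c for c, m in zip(seq, rec.softmask)
                )
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff_transcripts(path: str | Path) -> List[TranscriptModel]:
    """Read Ensembl-dialect GFF3 into :class:`TranscriptModel` objects.

    Returns one model per mRNA having at least one CDS segment;
    transcripts without three_prime_UTR features get empty
    ``utr3_segments``.  Feature score and phase are ignored.  CDS
    features whose Parent cannot be resolved to an mRNA trigger a
    warning and are skipped.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}

    # Parent-resolution check for orphan CDS features.
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            warnings.warn(
                f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no resolvable "
                f"parent mRNA; skipped"
            )

    models: List[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        if mrna.strand not in {"+", "-"}:
            raise ValueError(
                f"unknown strand symbol {mrna.strand!r} on mRNA {mrna.id}"
            )
        cds = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="CDS")
        ]
        if not cds:
            continue
        utr3 = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="three_prime_UTR")
        ]
        reverse = mrna.strand == "-"
        cds.sort(reverse=reverse)
        utr3.sort(reverse=reverse)
        gene_id = (mrna.attributes.get("Parent") or [mrna.id])[0]
        biotype = (
            mrna.attributes.get("biotype")
            or mrna.attributes.get("gene_biotype")
            or [None]
        )[0]
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                cds_segments=cds,
                utr3_segments=utr3,
                biotype=biotype,
            )
        )
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as Ensembl-style GFF3 (gene/mRNA/CDS/
    three_prime_UTR rows with ID/Parent/biotype attributes)."""
    models = list(models)
    lines = ["##gff-version 3"]
    by_gene: dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        chrom = txs[0].chromosome
        strand = txs[0].strand
        all_ivs = [iv for t in txs for iv in t.cds_segments + t.utr3_segments]
        gstart = min(s for s, _ in all_ivs) + 1
        gend = max(e for _, e in all_ivs)
        biotype = txs[0].biotype or "protein_coding"
        lines.append(
            f"{chrom}\tscrscreen\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
            f"ID={gene_id};biotype={biotype}"
        )
        for t in txs:
            ivs = t.cds_segments + t.utr3_segments
            tstart = min(s for s, _ in ivs) + 1
            tend = max(e for _, e in ivs)
            lines.append(
                f"{chrom}\tscrscreen\tmRNA\t{tstart}\t{tend}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id};biotype={biotype}"
            )
            for s, e in sorted(t.cds_segments):
                lines.append(
                    f"{chrom}\tscrscreen\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                    f"ID=cds-{t.transcript_id};Parent={t.transcript_id}"
                )
            for s, e in sorted(t.utr3_segments):
                lines.append(
                    f"{chrom}\tscrscreen\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID=utr3-{t.transcript_id};Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RNAfold text dialect

_MFE_RE = re.compile(r"^\(\s*(-?\d+(?:\.\d+)?)\s*\)$")


def read_rnafold_file(path: str | Path) -> List[StructureFileEntry]:
    """Parse RNAfold text output (header / sequence / "dotbracket (MFE)").

    The MFE is taken from the trailing parenthesized number, tolerating
    RNAfold's internal padding spaces, and may be absent.  Entries whose
    brackets are unbalanced are rejected individually with a warning;
    a sequence/structure length mismatch raises for that entry.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    entries: List[StructureFileEntry] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected header at line {i + 1} of {path}")
        ident = lines[i][1:].split()[0] if lines[i][1:].split() else ""
        if not ident:
            raise ValueError(f"empty header at line {i + 1} of {path}")
        if i + 2 >= len(lines):
            raise ValueError(f"truncated entry {ident!r} in {path}")
        seq = lines[i + 1].strip().upper().replace("T", "U")
        struct_line = lines[i + 2].strip()
        parts = struct_line.split(None, 1)
        db = parts[0]
        mfe: Optional[float] = None
        if len(parts) == 2:
            m = _MFE_RE.match(parts[1].strip())
            if m is None:
                raise ValueError(
                    f"entry {ident!r}: cannot parse energy field {parts[1]!r}"
                )
            mfe = float(m.group(1))
        i += 3
        try:
            pairs_from_dotbracket(db)
        except ValueError as exc:
            warnings.warn(f"entry {ident!r} rejected: {exc}")
            continue
        entries.append(
            StructureFileEntry(identifier=ident, sequence=seq, dotbracket=db, mfe=mfe)
        )
    return entries


def write_rnafold_file(entries: Iterable[StructureFileEntry], path: str | Path) -> None:
    """Write entries in the exact RNAfold text dialect read back by
    :func:`read_rnafold_file`."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.identifier}\n{e.sequence}\n{e.dotbracket}")
            if e.mfe is not None:
                fh.write(f" ({e.mfe:6.2f})")
            fh.write("\n")


# ---------------------------------------------------------------------------
# tabular outputs

SCREEN_TABLE_COLUMNS = [
    "gene_id",
    "window_length",
    "truncated",
    "passed",
    "failure_reasons",
    "element_start",
    "element_end",
    "backend",
]


def write_screen_table(calls: Sequence, path: str | Path) -> None:
    """Write screen results as TSV with a fixed header.

    Element coordinates are reported in the +1-at-stop convention; rows
    are sorted by gene_id so identical inputs give byte-identical files.
    """
    rows = []
    for r in sorted(calls, key=lambda r: r.gene_id):
        span = r.element_stop_span
        rows.append(
            "\t".join(
                [
                    r.gene_id,
                    str(r.window_length),
                    str(r.truncated).lower(),
                    str(r.call.passed).lower(),
                    ",".join(sorted(r.call.failure_reasons)) or "-",
                    str(span[0]) if span else "-",
                    str(span[1]) if span else "-",
                    r.backend_tag,
                ]
            )
        )
    Path(path).write_text("\t".join(SCREEN_TABLE_COLUMNS) + "\n"
                          + "".join(row + "\n" for row in rows))


def write_bed6(
    intervals: Iterable[Tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6
    (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
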