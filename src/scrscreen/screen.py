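"""Genome-wide stem-loop screen and gene-set overlap analysis.

Per protein-coding gene: select the most-upstream 3'UTR, excise the
first W nucleotides after the stop codon, predict (or ingest) the
secondary structure, and classify it against the stem-loop criteria.
The overlap analysis intersects the resulting gene set with external
evidence lists (ribosome-profiling readthrough, conserved downstream
ORFs) and with prior structure predictions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from scrscreen.folding import PairScoring, SecondaryStructure, fold_maxpair
from scrscreen.hairpins import HairpinCall, HairpinCriteria, DEFAULT_CRITERIA, classify_structure
from scrscreen.io import StructureFileEntry, TranscriptModel
from scrscreen.stop_context import (
    GeneSkipped,
    WINDOW_OFFSET,
    extract_stop_context,
    select_primary_utr,
)

__all__ = [
    "ScreenResult",
    "ScreenSummary",
    "GeneSetOverlap",
    "CombinedReport",
    "run_stemloop_screen",
    "overlap_gene_sets",
    "combine_window_runs",
    "normalize_gene_id",
]


@dataclass
class ScreenResult:
    """One gene's verdict from the stem-loop screen.

    ``element_stop_span`` is the best element's (start, end) in the
    +1-at-stop convention, present only for passing genes.
    """

    gene_id: str
    transcript_id: str
    window_length: int
    truncated: bool
    call: HairpinCall
    backend_tag: str
    element_stop_span: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.element_stop_span is not None:
            lo, hi = self.element_stop_span
            if not (WINDOW_OFFSET <= lo <= hi <= 3 + self.window_length):
                raise ValueError(
                    f"element span +{lo}..+{hi} outside +{WINDOW_OFFSET}.."
                    f"+{3 + self.window_length}"
                )


@dataclass
class ScreenSummary:
    """Counts reported alongside the per-gene results."""

    genes_total: int = 0
    windows_extracted: int = 0
    structures_classified: int = 0
    passes: int = 0
    skipped: Dict[str, str] = field(default_factory=dict)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def run_stemloop_screen(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    W: int = 60,
    criteria: HairpinCriteria = DEFAULT_CRITERIA,
    backend: str = "maxpair",
    structures: Optional[Sequence[StructureFileEntry]] = None,
    scoring: Optional[PairScoring] = None,
    strict: bool = True,
) -> Tuple[List[ScreenResult], ScreenSummary]:
    """Run the screen over all genes in *transcripts*.

    With ``structures`` given (ingest mode, e.g. RNAfold output) the
    screen never folds internally: entries are matched to genes by
    identifier equality after whitespace truncation, and genes without
    a matching structure are counted as skipped, not fatal.  Otherwise
    windows are folded with the internal max-pair backend.

    Returns the per-gene results (gene_id order) and a summary; genes
    without a usable 3'UTR or stop codon are logged in
    ``summary.skipped`` with the reason.
    """
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    ingest: Optional[Dict[str, StructureFileEntry]] = None
    if structures is not None:
        ingest = {e.identifier: e for e in structures}

    summary = ScreenSummary(genes_total=len(by_gene))
    results: List[ScreenResult] = []
    for gene_id in sorted(by_gene):
        try:
            tx = select_primary_utr(by_gene[gene_id])
            ctx = extract_stop_context(genome, tx, W=W, strict=strict)
        except GeneSkipped as exc:
            summary.skipped[gene_id] = str(exc)
            continue
        summary.windows_extracted += 1

        if ingest is not None:
            entry = ingest.get(gene_id)
            if entry is None:
                summary.skipped[gene_id] = "no structure for gene in ingest mode"
                continue
            structure = SecondaryStructure.from_dotbracket(
                entry.sequence, entry.dotbracket, mfe=entry.mfe, backend_tag="external"
            )
            backend_tag = "external"
        else:
            if backend != "maxpair":
                raise ValueError(
                    f"unknown backend {backend!r}; supply structures= for "
                    f"externally folded input"
                )
            structure = fold_maxpair(ctx.window, scoring)
            backend_tag = "maxpair"

        call = classify_structure(structure, criteria)
        summary.structures_classified += 1
        span = None
        if call.passed and call.best_element is not None:
            i, j = call.best_element.outer_pair
            span = (i + WINDOW_OFFSET, j + WINDOW_OFFSET)
            summary.passes += 1
        results.append(
            ScreenResult(
                gene_id=gene_id,
                transcript_id=tx.transcript_id,
                window_length=W,
                truncated=ctx.truncated,
                call=call,
                backend_tag=backend_tag,
                element_stop_span=span,
            )
        )
    return results, summary


# ---------------------------------------------------------------------------
# gene-set overlap analysis

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Strip a trailing version suffix (``FBgn0000001.2`` → ``FBgn0000001``)."""
    return _VERSION_SUFFIX.sub("", gene_id.strip())


def _as_set(name: str, ids: Iterable[str]) -> Set[str]:
    items = [normalize_gene_id(g) for g in ids]
    out = set(items)
    if len(out) != len(items):
        warnings.warn(f"duplicate gene ids within set {name!r}; deduplicated")
    return out


@dataclass
class GeneSetOverlap:
    """All Venn regions for three gene sets plus derived evidence sets.

    ``region_counts`` keys are membership masks over (stemloop,
    riboseq, conserved): e.g. ``"110"`` counts genes in the stem-loop
    and ribo-seq sets but not the conserved-ORF set.
    ``evidence_set`` is stemloop ∩ (riboseq ∪ conserved) — the
    stem-loop genes carrying at least one line of readthrough evidence.
    """

    stemloop: Set[str]
    riboseq: Set[str]
    conserved: Set[str]

    @property
    def region_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        union = self.stemloop | self.riboseq | self.conserved
        for g in union:
            mask = (
                f"{int(g in self.stemloop)}"
                f"{int(g in self.riboseq)}"
                f"{int(g in self.conserved)}"
            )
            counts[mask] = counts.get(mask, 0) + 1
        for mask in ("100", "010", "001", "110", "101", "011", "111"):
            counts.setdefault(mask, 0)
        return counts

    @property
    def stemloop_riboseq(self) -> int:
        return len(self.stemloop & self.riboseq)

    @property
    def stemloop_conserved(self) -> int:
        return len(self.stemloop & self.conserved)

    @property
    def riboseq_conserved(self) -> int:
        return len(self.riboseq & self.conserved)

    @property
    def triple(self) -> int:
        return len(self.stemloop & self.riboseq & self.conserved)

    @property
    def evidence_set(self) -> Set[str]:
        return self.stemloop & (self.riboseq | self.conserved)

    @property
    def evidence_intersection(self) -> int:
        return len(self.evidence_set)

    def novelty_set(self, prior_predictions: Iterable[str]) -> Set[str]:
        """Evidence-supported stem-loop genes absent from a prior
        structure-prediction list."""
        prior = {normalize_gene_id(g) for g in prior_predictions}
        return self.evidence_set - prior


def overlap_gene_sets(
    stemloop_set: Iterable[str],
    riboseq_set: Iterable[str],
    conserved_orf_set: Iterable[str],
) -> GeneSetOverlap:
    """Intersect the predicted stem-loop gene set with the two external
    readthrough-evidence lists.

    Identifiers are normalized (version suffixes stripped); duplicates
    within a list are deduplicated with a warning.
    """
    return GeneSetOverlap(
        stemloop=_as_set("stemloop", stemloop_set),
        riboseq=_as_set("riboseq", riboseq_set),
        conserved=_as_set("conserved", conserved_orf_set),
    )


@dataclass
class CombinedReport:
    """Evidence-supported stem-loop genes combined across two window
    lengths."""

    union: Set[str]
    novel: Set[str]
    only_in_60: Set[str]
    only_in_80: Set[str]


def combine_window_runs(
    run60: Iterable[str],
    run80: Iterable[str],
    prior_structure_predictions: Iterable[str] = (),
) -> CombinedReport:
    """Combine the evidence-supported gene sets of the W=60 and W=80 runs.

    Returns the union, the novelty set (union minus prior structure
    predictions), and the genes found at only one window length —
    genes passing at 60 but not 80 arise when the longer window folds
    into an alternative structure that fails the criteria.
    """
    s60 = {normalize_gene_id(g) for g in run60}
    s80 = {normalize_gene_id(g) for g in run80}
    prior = {normalize_gene_id(g) for g in prior_structure_predictions}
    union = s60 | s80
    return CombinedReport(
        union=union,
        novel=union - prior,
        only_in_60=s60 - s80,
        only_in_80=s80 - s60,
    )
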