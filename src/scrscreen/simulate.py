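"""Deterministic synthetic genomes, structures and reporter tables with
known ground truth.

Planted hairpins are built so that the intended structure is the
*provably unique* optimum of the max-pair folder: the 5' stem strand is
all C, the 3' strand all G, and loops, bulges and flanks are all A.
Every C then precedes every G, so the only non-crossing matching using
all stem bases is the rainbow matching — the planted stem — and any
other structure pairs fewer bases and scores lower.  A bases pair with
nothing in these sequences, so negative (unstructured) windows drawn
from {A, C} fold to the empty structure.  Ground-truth labels are
therefore exact, with no thermodynamic computation required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from scrscreen.hairpins import HairpinCriteria, DEFAULT_CRITERIA
from scrscreen.io import (
    SequenceRecord,
    TranscriptModel,
    write_fasta,
    write_gff3,
)
from scrscreen.stop_context import reverse_complement

__all__ = [
    "PlantSpec",
    "plant_hairpin",
    "synth_genome",
    "synth_luminescence",
]

#: DNA stop codons sampled for synthetic CDSs.
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint for one planted hairpin.

    ``bulges`` lists (gap_index, side, length): a run of *length*
    unpaired bases inserted between stem pairs ``gap_index - 1`` and
    ``gap_index`` (counted from the outer pair) on the given side.
    ``flank_lengths`` are the unpaired tails 5' and 3' of the element.
    """

    stem_length: int
    loop_length: int
    bulges: Tuple[Tuple[int, str, int], ...] = ()
    flank_lengths: Tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_length < 3:
            raise ValueError(
                "stem_length < 3: uniqueness of the planted optimum cannot "
                "be guaranteed"
            )
        if self.loop_length < 1:
            raise ValueError("loop_length must be >= 1")
        for gap, side, length in self.bulges:
            if not 1 <= gap <= self.stem_length - 1:
                raise ValueError(f"bulge gap index {gap} outside 1..stem_length-1")
            if side not in {"5prime", "3prime"}:
                raise ValueError(f"unknown bulge side {side!r}")
            if length < 1:
                raise ValueError("bulge length must be >= 1")

    @property
    def total_bulge_length(self) -> int:
        return sum(length for _, _, length in self.bulges)

    @property
    def span(self) -> int:
        """Element span: 2*stem + loop + total bulge lengths."""
        return 2 * self.stem_length + self.loop_length + self.total_bulge_length

    def satisfies(self, criteria: HairpinCriteria = DEFAULT_CRITERIA) -> bool:
        """Ground-truth label, computed arithmetically from the blueprint
        fields (independent of the classifier implementation)."""
        if self.span < criteria.min_span:
            return False
        if not criteria.loop_min <= self.loop_length <= criteria.loop_max:
            return False
        if self.bulges and max(l for _, _, l in self.bulges) > criteria.bulge_max:
            return False
        return True


def plant_hairpin(spec: PlantSpec) -> Tuple[str, str]:
    """Build (sequence, dot-bracket ground truth) for a planted hairpin.

    Deterministic for a fixed spec; the planted structure is the unique
    max-pair optimum (see module docstring).
    """
    n = spec.stem_length
    five_seq: List[str] = []
    five_db: List[str] = []
    three_outer_in_seq: List[str] = []
    three_outer_in_db: List[str] = []
    bul5 = {gap: length for gap, side, length in spec.bulges if side == "5prime"}
    bul3 = {gap: length for gap, side, length in spec.bulges if side == "3prime"}
    for k in range(n):
        if k in bul5:
            five_seq.append("A" * bul5[k])
            five_db.append("." * bul5[k])
        if k in bul3:
            three_outer_in_seq.append("A" * bul3[k])
            three_outer_in_db.append("." * bul3[k])
        five_seq.append("C")
        five_db.append("(")
        three_outer_in_seq.append("G")
        three_outer_in_db.append(")")
    f5, f3 = spec.flank_lengths
    seq = (
        "A" * f5
        + "".join(five_seq)
        + "A" * spec.loop_length
        + "".join(reversed(three_outer_in_seq))
        + "A" * f3
    )
    db = (
        "." * f5
        + "".join(five_db)
        + "." * spec.loop_length
        + "".join(reversed(three_outer_in_db))
        + "." * f3
    )
    assert len(seq) == len(db) == spec.span + f5 + f3
    return seq, db


@dataclass
class SyntheticGene:
    """Truth-table row for one synthetic gene."""

    gene_id: str
    kind: Literal["qualifying", "subspan", "unstructured"]
    expected_pass: bool
    strand: str
    spliced_utr: bool
    window: str
    true_structure: Optional[str]
    plant: Optional[PlantSpec]


def _qualifying_spec(rng: np.random.Generator, W: int) -> PlantSpec:
    stem = int(rng.integers(16, 21))
    loop = int(rng.integers(3, 9))
    span = 2 * stem + loop
    f5 = int(rng.integers(2, min(6, W - span)))
    f3 = W - span - f5
    return PlantSpec(stem_length=stem, loop_length=loop, flank_lengths=(f5, f3))


def _subspan_spec(rng: np.random.Generator, W: int) -> PlantSpec:
    stem = int(rng.integers(8, 13))  # span 19..31 < 35
    loop = int(rng.integers(3, 8))
    span = 2 * stem + loop
    f5 = int(rng.integers(2, 6))
    f3 = W - span - f5
    return PlantSpec(stem_length=stem, loop_length=loop, flank_lengths=(f5, f3))


def synth_genome(
    n_genes: int,
    planted_fraction: float,
    W: int = 60,
    seed: int = 0,
    subspan_fraction: float = 0.4,
    spliced_every: int = 5,
    out_dir: Optional[str | Path] = None,
) -> Tuple[Dict[str, str], List[TranscriptModel], pd.DataFrame]:
    """Generate a toy genome with planted 3'UTR hairpins.

    Each gene has a CDS ending in a random stop triplet and a 3'UTR
    whose first W nt embed a qualifying hairpin, a sub-span hairpin, or
    an unstructured (A/C) window, per the returned truth table.  Genes
    alternate between the two strands and every ``spliced_every``-th
    gene has its 3'UTR split across two exons.  With ``out_dir`` given,
    ``genome.fa``, ``annotation.gff3`` and ``truth.tsv`` are written in
    the formats the rest of the package consumes.

    Returns (genome mapping, transcript models, truth table).  The
    truth table's ``expected_pass`` column is computed arithmetically
    from the plant specs, independent of the classifier.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = round(n_genes * planted_fraction)
    n_neg = n_genes - n_pos
    n_sub = round(n_neg * subspan_fraction)

    kinds = (
        ["qualifying"] * n_pos + ["subspan"] * n_sub + ["unstructured"] * (n_neg - n_sub)
    )
    chrom = "chrS"
    spacer = "A" * 20
    parts: List[str] = [spacer]
    cursor = len(spacer)
    models: List[TranscriptModel] = []
    truth_rows: List[SyntheticGene] = []

    for idx, kind in enumerate(kinds):
        gene_id = f"SG{idx:04d}"
        strand = "+" if idx % 2 == 0 else "-"
        spliced = spliced_every > 0 and idx % spliced_every == spliced_every - 1

        stop = _STOPS[int(rng.integers(3))]
        cds_body = "".join("ACGT"[b] for b in rng.integers(0, 4, size=27))
        cds = cds_body + stop

        plant: Optional[PlantSpec] = None
        true_db: Optional[str] = None
        if kind == "qualifying":
            plant = _qualifying_spec(rng, W)
            win_rna, true_db = plant_hairpin(plant)
            expected = plant.satisfies(DEFAULT_CRITERIA)
        elif kind == "subspan":
            plant = _subspan_spec(rng, W)
            win_rna, true_db = plant_hairpin(plant)
            win_rna = win_rna + "A" * (W - len(win_rna))
            true_db = true_db + "." * (W - len(true_db))
            expected = plant.satisfies(DEFAULT_CRITERIA)
        else:
            win_rna = "".join("AC"[b] for b in rng.integers(0, 2, size=W))
            expected = False
        window_dna = win_rna.replace("U", "T")
        utr = window_dna + "A" * 6  # short tail beyond the window

        # genomic placement, transcript-sense
        if spliced:
            cut = W // 2
            intron = "A" * 7
            utr_genomic = utr[:cut] + intron + utr[cut:]
            utr_splits = [(0, cut), (cut + len(intron), len(utr_genomic))]
        else:
            utr_genomic = utr
            utr_splits = [(0, len(utr_genomic))]

        tx_sense = cds + utr_genomic
        block = tx_sense if strand == "+" else reverse_complement(tx_sense)
        g0 = cursor
        L = len(block)
        if strand == "+":
            cds_iv = [(g0, g0 + len(cds))]
            utr_ivs = [
                (g0 + len(cds) + s, g0 + len(cds) + e) for s, e in utr_splits
            ]
        else:
            # transcript-sense offset o maps to genomic g0 + L - 1 - o
            cds_iv = [(g0 + L - len(cds), g0 + L)]
            utr_ivs = [
                (g0 + L - len(cds) - e, g0 + L - len(cds) - s)
                for s, e in utr_splits
            ]
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chromosome=chrom,
                strand=strand,
                cds_segments=sorted(cds_iv, reverse=strand == "-"),
                utr3_segments=sorted(utr_ivs, reverse=strand == "-"),
                biotype="protein_coding",
            )
        )
        truth_rows.append(
            SyntheticGene(
                gene_id=gene_id,
                kind=kind,  # type: ignore[arg-type]
                expected_pass=expected,
                strand=strand,
                spliced_utr=spliced,
                window=win_rna,
                true_structure=true_db,
                plant=plant,
            )
        )
        parts.append(block + spacer)
        cursor += L + len(spacer)

    genome = {chrom: "".join(parts)}
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in truth_rows],
            "kind": [g.kind for g in truth_rows],
            "expected_pass": [g.expected_pass for g in truth_rows],
            "strand": [g.strand for g in truth_rows],
            "spliced_utr": [g.spliced_utr for g in truth_rows],
            "window": [g.window for g in truth_rows],
            "true_structure": [g.true_structure or "" for g in truth_rows],
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [SequenceRecord(identifier=chrom, residues=genome[chrom])],
            out / "genome.fa",
        )
        write_gff3(models, out / "annotation.gff3")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return genome, models, truth


def synth_luminescence(
    true_efficiencies: Mapping[str, float],
    replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
    sense_control: str = "sense_control",
    control_ratio: float = 22.0,
    rluc_base: float = 50_000.0,
    fluc_bg: float = 100.0,
    rluc_bg: float = 100.0,
) -> pd.DataFrame:
    """Simulate a dual-luciferase plate with known readthrough
    efficiencies.

    Per well, the corrected FLuc/RLuc ratio equals the construct's
    target ratio (efficiency/100 x the sense-control ratio) times
    multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (mean 1); constant backgrounds are added back so the
    table carries raw counts.  The sense control itself is appended at
    100% efficiency when absent.  Zero noise recovers the efficiencies
    exactly through :func:`scrscreen.reporter.efficiency_table`.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    effs = dict(true_efficiencies)
    effs.setdefault(sense_control, 100.0)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        mu = -0.5 * sigma**2
    rows = []
    for construct in sorted(effs):
        target_ratio = effs[construct] / 100.0 * control_ratio
        for _ in range(replicates):
            if noise_cv > 0:
                rl_noise = float(rng.lognormal(mu, sigma))
                ratio_noise = float(rng.lognormal(mu, sigma))
            else:
                rl_noise = ratio_noise = 1.0
            rluc = rluc_base * rl_noise
            fluc = target_ratio * ratio_noise * rluc
            rows.append(
                {
                    "construct_id": construct,
                    "fluc": fluc + fluc_bg,
                    "rluc": rluc + rluc_bg,
                    "fluc_bg": fluc_bg,
                    "rluc_bg": rluc_bg,
                }
            )
    return pd.DataFrame(rows)
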