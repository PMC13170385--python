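import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from scrscreen.folding import SecondaryStructure
from scrscreen.simulate import PlantSpec, plant_hairpin


@pytest.fixture
def perfect_stemloop() -> SecondaryStructure:
    """16-bp stem + 3-nt loop: span 35, the boundary case."""
    seq, db = plant_hairpin(PlantSpec(stem_length=16, loop_length=3))
    return SecondaryStructure.from_dotbracket(seq, db, backend_tag="maxpair")


@pytest.fixture
def toy_gff(tmp_path) -> Path:
    """One + strand gene: CDS 10-100 ends in TAG, 3'UTR 101-220 (1-based)."""
    text = """##gff-version 3
chr1\tsrc\tgene\t10\t220\t.\t+\t.\tID=g1;biotype=protein_coding
chr1\tsrc\tmRNA\t10\t220\t.\t+\t.\tID=t1;Parent=g1;biotype=protein_coding
chr1\tsrc\tCDS\t10\t100\t.\t+\t0\tID=c1;Parent=t1
chr1\tsrc\tthree_prime_UTR\t101\t220\t.\t+\t.\tID=u1;Parent=t1
"""
    p = tmp_path / "toy.gff3"
    p.write_text(text)
    return p
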