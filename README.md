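# scrscreen

Detection of mRNA stem-loops immediately 3' of stop codons, stem-loop
variant design, and quantification of stop-codon readthrough from
dual-reporter assays.

## The problem

Programmed stop-codon readthrough (SCR) — a near-cognate tRNA decoding a
stop codon so translation continues into a downstream extension ORF — is
promoted in some mRNAs by a *cis*-acting hairpin (stem-loop) located just
after the stop codon in the 3'UTR. `scrscreen` is for researchers who
want to (i) screen an annotated genome for genes whose post-stop 3'UTR
window folds into such a stem-loop, (ii) design sequence variants that
destabilize, stabilize or structurally restore a candidate hairpin, and
(iii) quantify readthrough from dual-luciferase or dual-fluorescence
reporter measurements.

## The method

**Window extraction.** For each protein-coding gene, the transcript whose
stop codon lies most 5' in gene orientation (the most upstream annotated
3'UTR) is selected; the first W nucleotides of the spliced 3'UTR after
the stop codon are excised (W = 60 or 80). Coordinates follow the
+1-at-stop convention: +1..+3 is the stop codon, so the window occupies
+4..+(3+W) and +4..+9 is the readthrough motif hexamer.

**Structure prediction.** Two backends: ingestion of thermodynamic MFE
structures (RNAfold text output, or an `RNAfold` subprocess when
ViennaRNA is installed), and a self-contained weighted base-pair
maximization folder (Nussinov-style dynamic program; GC=3, AU=2, GU=1,
hairpin loops ≥ 3 nt) used for dependency-free, provably-unique synthetic
fixtures.

**Classification.** A hairpin *element* is one terminal loop plus the
helix closing it, extended outward through bulges/internal loops until a
multiloop junction or the exterior. A window is called a stem-loop when
some element has span ≥ 35 nt, terminal loop of 3–10 nt, and no bulge run
longer than 2 nt (preset `paper2026`; all thresholds configurable).

**Variant design.** DV breaks chosen stem pairs (i, j) by substituting
the 3' base with the 5' base's identity (identical bases never pair under
WC+G·U rules); DVC restores each broken pair by mutating the untouched
partner to the Watson–Crick complement of the mutated base — the sequence
diverges at both positions while the structure is recreated. SV closes an
internal loop by complement substitution on the 3' side; SVC reopens the
created pairs with a non-pairing 5' substitute chosen so the refolded
structure restores the original topology. Each design carries
`stability_delta` = variant score − base score on the MFE sign convention
(positive = destabilized). The position series inserts 3/6/9 nt
immediately after +9 or deletes the stem-forming segment +12..+57.

**Readthrough quantification.** Relative luminescence =
(FLuc−bg)/(RLuc−bg); readthrough efficiency = 100 × test / sense-codon
control (stop→sense mutant defines 100%); relative readthrough level
rescales efficiencies to a reference construct (= 1). For in vivo
imaging, the GFP/mCD8 ratio of background-subtracted, area-normalized
intensities, optionally adjusted to a reference mCD8 mean.

## Worked example

```bash
scrscreen simulate genome --seed 4 --n-genes 12 --planted-fraction 0.5 --out fixtures
# wrote genome.fa/annotation.gff3/truth.tsv with 6 planted qualifying hairpins
scrscreen screen --gff fixtures/annotation.gff3 --fasta fixtures/genome.fa \
    --window 60 --out calls.tsv
# 12 genes, 12 windows, 6 stem-loop calls, 0 skipped
head -3 calls.tsv
# gene_id  window_length  truncated  passed  failure_reasons  element_start  element_end  backend
# SG0000   60             false      true    -                9              56           maxpair
# SG0001   60             false      true    -                8              44           maxpair
```

The six planted hairpins are recovered and nothing else: each passing row
reports the element's span in stop-anchored coordinates (here the SG0000
hairpin runs from +9 to +56, directly abutting the stop codon's +4..+9
context). For reporter data:

```bash
scrscreen simulate plate --seed 1 --noise-cv 0.0 --out plates
scrscreen readthrough --in plates/plate.tsv --sense-control sense_control \
    --reference dfr288 --out eff.tsv
cat eff.tsv
# construct_id   mean_ratio  efficiency_percent  relative_level
# dfr288         3.96        18                  1
# sense_control  22          100                 5.55556
```

A construct whose FLuc/RLuc mean is 3.96 against a sense-codon control
mean of 22 has 18% readthrough efficiency — i.e. readthrough produces the
extension product at 18% of the level obtained when the stop codon is
replaced by a sense codon.

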