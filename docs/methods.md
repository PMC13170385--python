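# Methods

## Coordinate conventions

GFF3 is 1-based inclusive on disk; everything inside the package is
0-based half-open, with the conversion confined to the `io` module.
Stop-relative coordinates set +1 at the first base of the stop
codon; the Ensembl convention is assumed (the CDS includes the stop
codon, `three_prime_UTR` begins immediately after it), so a W-nt UTR
window occupies +4..+(3+W). Windows are mRNA-level: UTR exon segments
are concatenated in transcript orientation and reverse-complemented for
minus-strand genes before analysis, because the structure forms on the
spliced transcript, not on genomic DNA. DNA is converted to RNA (T→U)
only at the folding boundary; genomic operations keep DNA. Softmasked
(lowercase) bases are treated as ordinary bases for extraction and
folding — masking matters for alignment, not for structure prediction —
but the mask is retained so FASTA round-trips preserve the input.

"Most upstream 3'UTR" is interpreted in gene orientation (the
transcript whose stop codon lies most 5'), not in genomic coordinates;
the genomic reading would select the wrong transcript on the minus
strand. Ties go to the longer annotated UTR, then lexicographic
transcript id, making the choice deterministic. Genes whose UTR is
shorter than W are kept with a `truncated` flag rather than dropped —
the choice is reversible by filtering, whereas dropping would not be.

## Folding backends

The faithful thermodynamic backend is external: MFE structures computed
by ViennaRNA's RNAfold are ingested from its text output (or produced
via a subprocess when the binary is on PATH). Re-implementing the
Turner energy model is out of scope; instead the package ships a
weighted base-pair maximization folder (Nussinov-style interval dynamic
program) so every downstream module is testable with no external
dependency. Default pair weights GC=3, AU=2, GU=1 rank pair stability
in the conventional order; `min_loop=3` forbids hairpin loops shorter
than three nucleotides; N never pairs. The reported "MFE" of this
backend is the negated total pair weight, so lower = more stable holds
for both backends, and the two are never mixed silently
(`backend_tag` records which produced a structure; ingest-mode screens
never fold internally).

Traceback is deterministic: whenever pairing position i attains the
interval optimum, i is paired with the smallest admissible partner.
Pseudoknots are unsupported throughout (single bracket level), matching
the dot-bracket output format of the external folder. One asymmetry is
worth noting: the max-pair score is invariant under
reverse-complementation only for strict Watson–Crick pairing — a G·U
wobble maps to A–C, which cannot pair — so `PairScoring(allow_gu=False)`
exists for contexts where that symmetry matters; wobble stays on by
default. The DP inner loop is JIT-compiled (numba) with a pure-Python
fallback; at W=60–80 a genome-scale screen folds thousands of windows
per minute.

## Stem-loop definition

A hairpin element is one terminal loop plus its closing helix, extended
outward through consecutive pairs; interruptions unpaired on at least
one side (bulges, internal loops) are absorbed and recorded per side as
bulge runs; growth stops at a multiloop junction or the exterior loop.
The classifier passes a structure when at least one element satisfies
span ≥ `min_span` (35), terminal loop within [`loop_min`, `loop_max`]
([3, 10]) and every bulge run ≤ `bulge_max` (2) — the `paper2026`
preset. Design choices where the published criteria are ambiguous:

* The 35-nt minimum is applied to the element span (outer pair to outer
  pair), not to the input length (inputs are fixed 60/80-nt windows, so
  the latter would be vacuous) and not to helix length alone.
* A structure passes if it *contains* a qualifying element; unpaired
  flanking tails are allowed. Whole-structure matching would wrongly
  fail windows whose optimal structure adds a few stray pairs outside
  the hairpin.
* For internal loops, each side is limited to `bulge_max`
  independently; `bulge_mode="joint"` switches to a combined limit.
* `best_element` is the passing element of greatest span, ties going to
  the 5'-most, so calls are independent of discovery order.
* `branched_only` is reported when no element qualifies and the
  structure contains a multiloop junction — the criteria target
  unbranched hairpins, and this flag distinguishes "structured but
  branched" from simple span/loop/bulge failures.

## Variant design rules

The mutagenesis strategy needs one concrete, deterministic realization
of "disrupt pairing" and "recreate pairing":

* **DV**: for each selected pair (i, j), the 3'-side base j is
  substituted with the identity of the 5' base (no base pairs with
  itself under WC+G·U rules, so disruption is guaranteed); a fallback
  to the first non-pairing base in the fixed order C, A, G, U exists
  and is checked, never silently assumed. The mutated side is
  configurable. The stability delta must come out positive.
* **DVC**: each broken pair's untouched partner is mutated to the
  Watson–Crick complement of the DV-mutated base — both strands now
  differ from the original while the pair is recreated as strict WC
  (wobble counts as pairing for disruption checks, but compensation
  targets WC pairs).
* **SV**: an internal loop with unpaired bases on both sides is closed
  by min(k5, k3) new pairs aligned innermost-out, substituting the
  3'-side base with the complement of the opposing 5' base; one-sided
  bulges cannot be closed by substitution and are rejected. The delta
  must come out negative.
* **SVC**: each SV-created pair is reopened by substituting the 5'
  partner with a base that cannot pair the SV-mutated 3' base and
  differs from the original. Candidates are tried in the order C, A,
  G, U, and the first whose *refold* reproduces the original structure
  is kept — the substitute itself could otherwise recruit a new partner
  elsewhere in the stem (this happens on GC-dense stems, where an extra
  C re-pairs with a stem G and shifts the bulge).

Deltas are computed under the active backend; reproducing published
thermodynamic MFE values requires the external backend. The position
series edits a stop-codon context window: 3/6/9-nt insertions
immediately after +9 and deletion of +12..+57 (46 nt), each returning a
remap of surviving stop-relative coordinates.

## Synthetic fixtures

Planted hairpins are constructed, not sampled: the 5' stem strand is
all C, the 3' strand all G, and loops, bulges and flanks all A. Every C
precedes every G, so the only non-crossing matching that pairs all stem
bases is the rainbow matching — the planted stem — and any other nested
structure pairs fewer bases and scores strictly lower. A pairs with
nothing in these sequences. The planted structure is therefore the
provably unique max-pair optimum, verified in tests both by refolding
and by exhaustive enumeration of all nested structures for cores up to
18 nt. Negative windows are random A/C strings (no pairable letter
combinations), so ground-truth labels are exact by construction.

Synthetic genomes place genes on both strands (annotation coordinates
mirrored for the minus strand), give every fifth gene a 3'UTR split
across two exons, and sample stop codons uniformly from UAA/UAG/UGA.
Qualifying plants draw stems of 16–20 bp and loops of 3–8 nt (span
35–48, inside a 60-nt window); sub-span decoys draw 8–12 bp stems
(span 19–31). Truth labels are computed arithmetically from the plant
geometry, independent of the classifier.

What these fixtures deliberately do **not** emulate: thermodynamic
folding (real windows fold under the Turner model, where planted-unique
optima cannot be guaranteed), sequence-composition realism, overlapping
genes, alternative isoform complexity beyond one transcript per gene.
Passing the synthetic screen therefore demonstrates the correctness of
extraction, classification and orchestration — not the biological
accuracy of structure prediction, which belongs to the external folder.

Simulated luciferase plates multiply each well's target FLuc/RLuc ratio
(efficiency/100 × a sense-control ratio of 22) by lognormal noise
parameterized to mean 1 and the requested coefficient of variation, on
both the RLuc level and the ratio, then add constant backgrounds back.
Zero noise recovers the configured efficiencies exactly; at CV 10% with
6 replicates the recovered efficiency is unbiased to within ±1.5
percentage points over 500 seeds (measured in the test suite).

## Reporter quantification choices

Per-construct means of the FLuc/RLuc ratios are taken before the
efficiency ratio (a per-replicate-efficiency mode is available, since
the order of averaging is a genuine free choice; the two agree exactly
at zero noise). Background correction uses the per-well background
columns as given — whether backgrounds are per-well or per-plate is the
caller's decision. The in vivo mCD8 adjustment is implemented as
multiplication of the GFP/mCD8 ratio by (sample corrected
mCD8)/(reference mean), with the direction configurable, because the
printed formula is ambiguous about orientation; the scaling property
(doubling the reference mean halves the multiply-mode ratio) is
asserted in tests. Statistical testing (ANOVA and post-hoc families) is
out of scope; the module emits tidy tables for external stats tools.

## Problem sizes and numerical notes

The default test suite and the acceptance script use a 200-gene
synthetic genome (70 planted positives), 1000 random structures for the
enumeration oracle, 500 random sequences (n ≤ 18) for the exhaustive
folding oracle, and 500 seeded plates for the Monte-Carlo recovery —
sizes chosen so the whole suite completes in well under a minute while
every sampled regime (both strands, spliced UTRs, truncated windows,
all three stop codons, bulged and clean stems) is exercised. All
randomness flows through explicit seeds; identical inputs give
byte-identical output tables (rows sorted by gene id, fixed header).
Scores are small integer-weighted sums held in float64, so equality
comparisons of scores and deltas are exact.

## Known limitations

* The internal folder ranks stability only qualitatively; absolute
  kcal/mol values require the external thermodynamic backend.
* Pseudoknots, suboptimal ensembles and partition-function measures are
  not modelled.
* Isoform biotype filtering is exposed (the GFF reader reports
  `biotype`) but no opinionated filter is applied; annotation builds
  differ in which isoforms they call protein-coding, which shifts
  genome-scale counts.
* Gene-set overlaps assume identifier spaces agree after version-suffix
  stripping; cross-referencing symbol-based with FBgn-based lists is
  the caller's responsibility.
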