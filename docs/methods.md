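# Methods

## Coordinate conventions

Promoter positions are numbered relative to a transcription start site with
no position 0: +1 is the TSS base, −1 the base immediately upstream. Under
this convention the interval −156..+46 spans 202 bp, −124..−75 spans 50 bp
and −91..−84 spans 8 bp — the only convention jointly consistent with the
bundled 202-nt probe sequence, the 16-nt ZTRE at −91..−76, and the 50-bp
competitor oligonucleotide. `interval_length` is symmetric and additive
across a shared endpoint; `promoter_to_offset`/`offset_to_promoter` are
exact inverses. Internally all sequence offsets are 1-based inclusive; BED
input is 0-based half-open and converted on read, TSV anchors are 1-based.

Window extraction around an anchor clips at sequence ends rather than
erroring (an rDNA repeat unit is short relative to ±1 kb flanks) and
records the achieved genomic span, which is the denominator for densities.
The achieved length is `min(pos+flank, len) − max(pos−flank, 1) + 1`. For a
− strand anchor the window is reverse-complemented and numbering follows
the annotated direction.

## ZTRE scanning

The motif model is two ordered half-sites of per-position residue sets
(left: `C [AC] C [TAG] C C [TC]`, right: `[GA] G [ATC] G [TG] G`) and an
integer spacer range, default 0–50. Matching is set membership with no
scoring; `N` in the text matches nothing (masked-sequence safety) and input
is uppercased so matching is case-insensitive. Every (start, gap, strand)
parse is reported; the reverse strand is scanned by reverse-complementing
the *motif* (complement each set, swap and reverse the half-sites — an
involution) so coordinates never need conversion. The scanner enumerates
left half-site hits, then checks each allowed spacer length; an exhaustive
brute-force enumerator serves as the test oracle, and the two agree on
thousands of random sequences.

Copies are counted as **footprints**: distinct (start, end) intervals after
collapsing strand-symmetric parses of the same interval (the element is a
near-palindrome, so most true sites match both strands). A footprint's
canonical parse is the lexicographically smallest (strand, gap) pair, '+'
before '−'. Overlapping footprints at different intervals are all counted —
distinct intervals are distinct elements; no merging rule is imposed.
Spacers are classified short (< 30 nt) or long (30–50 nt).

## Region density

Anchor windows are merged into disjoint mapped regions; a footprint counts
toward a region only if contained entirely within it (a partially mapped
motif was not fully observed; containment vs overlap is switchable in
code). Density is footprints per kilobase of merged mapped length, reported
to two decimals; group-vs-reference ratios are computed between those
two-decimal densities, matching how such legends quote them. The
nearest-neighbor pairing is TSS-to-TSS distance with ties broken toward the
smaller coordinate.

## Zinc-finger annotation

A C2H2 finger is a 21-residue window with the metal-coordinating residues
at window positions 1, 4, 17, 21 (C-X₂-C-X₁₂-H-X₃-H). Spacings are exact by
default; tolerances would be configuration, not defaults. Two relaxations
are available behind `allow_variants` (on by default): H instead of the
first C (His-Cys-His₂ configuration — interpreted as the minimal relaxation
admitting that described configuration) and R instead of the final H
(Cys₂-His-Arg). Overlapping candidates are resolved greedily left to right,
the way tandem finger arrays tile; annotated spans therefore never overlap,
and disabling variants can only reduce the count.

## Peptide-mass fingerprinting

Digestion cleaves C-terminal to K/R except before P (Keil rule;
configurable off). Missed cleavages `m` add every concatenation of up to
m+1 adjacent fully cleaved fragments; the default is complete digestion
(m = 0). Fragment masses are sums of standard monoisotopic residue masses
plus water (18.010565 Da); fixed modifications (e.g. carbamidomethyl-C) are
per-residue offsets, off by default since no alkylation step is assumed.
Peaks are compared as [M+H]⁺ (proton 1.007276 Da) — what MALDI reflector
spectra report — within an inclusive ppm tolerance (default 50) and a
900–4000 Da scan range; each peak takes its smallest-|ppm| match, ties
toward the smaller fragment start. Coverage is the union of matched
fragment spans over the parent length.

## Expression statistics

ΔΔCT assumes 100% amplification efficiency (one cycle = factor 2): ΔCT =
CT_target − CT_reference per sample, ΔΔCT relative to the mean ΔCT of the
calibrator condition, level = 2^(−ΔΔCT), so the calibrator is exactly 1.
The dilution-corrected abundance ratio of two transcripts is
`dilution × 2^(CT_low − CT_high)`.

The rank product of a gene is the geometric mean of its fold-change ranks
across sample comparisons (rank 1 = most changed in the tested direction;
average ranks on ties), computed separately for up- and down-regulation.
Comparisons default to all treatment×control sample pairs (`pairing="all"`);
`pairing="paired"` uses disjoint replicate pairs, the design in which the
permutation null's independence assumption holds exactly — the
null-calibration property test runs in that setting. The pfp of gene *g* is
the expected number of null rank products at or below RP_g (null: an
independent random rank permutation per comparison) divided by the rank of
RP_g among observed values; `method="exact"` enumerates the null completely
for tiny instances and matches an independent integer-arithmetic
enumeration in tests. Filters mirror a bead-array workflow: detection
p < 0.01 first, then fold change strictly > 1.2 (down: < 1/1.2) on the
linear scale (log2 input is declared and inverted), then pfp ≤ 0.05,
yielding up/down lists sorted by magnitude.

## Synthetic data

Generators emulate the statistical structure of the real inputs at desk
scale, with every random draw flowing from one seeded generator:

* **DNA with planted ZTREs** — uniform-GC background (configurable) with
  concrete motif instances (each degenerate position sampled from its set)
  at requested positions/gaps/strands; the background is re-drawn until a
  full scan recovers exactly the valid plants, so recovery assertions are
  exact. Gap-51 plants are emitted flagged invalid as negative controls.
* **Anchor panels** — disjoint 2-kb windows at contrasting Poisson motif
  densities (defaults 0.7/kb targets vs 0.15/kb neighbors, the observed
  contrast between the rRNA precursor region and ribosomal-protein-gene
  flanks), separated by N runs so no motif can span a window boundary;
  plants are spaced so half-sites of different plants cannot combine into
  spurious matches. Calibration at 100 windows/group recovers the rates
  within Poisson sampling error.
* **Proteins with fingers** — backgrounds drawn from residues that cannot
  form the finger pattern, K/R sprinkled at a configurable fraction for
  predictable tryptic sites, rejection-checked like the DNA generator.
* **Peak lists** — a random subset of in-range theoretical [M+H]⁺ values
  with Normal ppm jitter (default sd 10 ppm, well inside the 50-ppm
  tolerance) plus decoys placed ≥ 3 tolerances from every theoretical mass,
  so true peaks must all match and decoys must not.
* **CT tables / expression matrices** — true folds encoded as −log2(fold)
  CT shifts or log2 intensity shifts on gene-specific baselines
  (log2-normal noise, default sd 0.25; 3 replicates per group, matching a
  triplicate siRNA design; planted folds ≥ 1.2).

What the generators do **not** emulate: real genome composition (repeats,
CpG islands, GC heterogeneity), probe-level bead-array noise and
normalization artifacts, correlated gene expression, isotope envelopes or
systematic mass-calibration drift. Passing recovery tests therefore
demonstrates correctness of the arithmetic and the detection logic under
the stated noise models, not performance on raw experimental data.

## Problem sizes and numerical choices

The randomized suites use 300–400 nt sequences (1000 for the
scanner-vs-oracle equivalence), proteins of a few hundred residues, and
expression matrices of 150–500 genes × 3 replicates per group with
hundreds-to-thousands of permutations — sizes chosen so the full suite runs
in seconds while leaving the statistics well resolved. Masses are
deterministic to 1e-4 Da; rank-product tie comparison in the permutation
count uses a 1e-9 relative slack so rank products equal analytically but
computed through log arithmetic count as ties. Degenerate inputs error
early with descriptive messages (empty sequences, position 0, zero mapped
length, undersized groups); a zero-density reference yields a flagged
undefined ratio rather than a crash.

## Known limitations

* The motif scanner is exhaustive, not indexed; it targets promoter-scale
  windows and repeat units, not whole genomes.
* No position-weight-matrix scoring, motif discovery, or enrichment against
  shuffled backgrounds (ratio reporting only).
* No probabilistic PMF scoring (Mowse-type), isotope envelopes or MS/MS.
* Variance-stabilizing normalization of raw arrays is upstream of this
  package; the rank-product stage consumes normalized matrices.
* KRAB-domain detection and cross-species alignment are out of scope.
* Checks against accession-derived sequences (the 1,059-residue zinc-finger
  protein, a complete rDNA repeat unit) require the user to supply those
  public sequences locally; see `tests/test_acceptance.py` for the expected
  file layout.
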