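# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
numerical details a user would otherwise have to read out of the source.

## Reporter screen model

The simulated construct is `upstream_anchor (20 bp) + target (25 nt,
ending GCG) + randomized region (7 bp) + downstream_anchor (20 bp)`. The
randomized regions are uniform over 4⁷ by default; an enumeration mode
cycles all 16,384 7-mers for exhaustive tests, and a pinned list can fix
them exactly. No presort skew is modeled: enrichment in reports is against
the uniform expectation unless a presort count table is supplied.

Editing is a two-stage Bernoulli process per construct:

1. **Cleavage** with probability equal to the activity weight of the
   randomized region's first 4 bases (unlisted 4-mers get a default
   weight). Activity is modeled at 4-mer resolution because the dominant
   PAM signal in this screen design lives in positions 1–4; longer-range
   preferences (e.g. a 5th-position G) can be represented by analyzing
   k up to 7 on the counting side.
2. **Repair outcome**: in-frame with probability `editable_fraction`
   (default 1/3, the fraction of net length changes that are ≡ 0 mod 3
   under a frame-agnostic repair process). The net indel length is drawn
   from a geometric-tailed distribution over ±1..±9 (decay 0.8 per bp,
   deletions twice as likely as insertions — the qualitative shape of NHEJ
   spectra), renormalized over the lengths consistent with the drawn frame
   class. Support excludes 0; substitution-only repair is not modeled as
   an "edit".

Only cleaved, in-frame constructs emit reads (they are the GFP-positive,
sorted population). Indel placement: the cut sits 3 bp 5′ of the
PAM-proximal target end (the blunt type II-A cut), i.e. immediately 5′ of
the GCG fixer. Insertions are placed at the cut point; deletions remove
⌈d/2⌉ bases 5′ and ⌊d/2⌋ bases 3′ of it, so any deletion chews into the
fixer and leaves the randomized region unextractable. This is deliberate:
it exercises the extraction's robustness, and the truth table records a
`pam_extractable` flag so filter tests can be exact. The practical
consequence is that extractable in-frame reads are mostly
insertion-derived; at the depths used here that costs depth, not
correctness.

Sequencing error is substitution-only, uniform per base (default 0.001),
with constant Q40 quality strings and a single (sense) read orientation.
Not modeled: transfection efficiency, MOI, PCR bias, sorter impurity, read
indel errors, quality variation, paired ends. Consequence: recovery tests
demonstrate that the analysis is unbiased for the signal the generator
encodes; they say nothing about robustness to PCR chimeras or quality
artifacts, which real screens must handle upstream.

## PAM discovery

* **Anchor location**: leftmost approximate match of each 20-bp anchor
  with ≤ 1 substitution by default; a read missing either anchor (in
  order) is `unanchored`. The 3-bp fixer is matched exactly — a
  trinucleotide carries no information under mismatches.
* **Classification** is by length only: `net = len(inner) − 32`.
  Wildtype requires net 0 and ≤ 2 substitutions in the target region (so
  sequencing errors do not look like edits); net ≠ 0 and ≡ 0 mod 3 is an
  in-frame edit; everything else is a frameshift. Whether substitution-only
  in-frame reads should count as edits is ambiguous in this screen design;
  here they never enter the tally (the boundary is the
  `substitution_tolerance` parameter). Premature-stop screening of the
  repaired ORF is not performed.
* **Extraction**: the randomized region is the last 7 bases of the inner
  sequence, valid only when immediately preceded by an exact fixer and
  containing only ACGT.
* **Tally**: first k bases (default k = 4, configurable to 7) of the
  extracted region over in-frame-edited reads only.
* **Profiles**: additive smoothing with pseudocount 0.5 for frequency
  matrices feeding log computations; tallies themselves are unsmoothed.
  IC uses the logo convention `2 + Σ f log₂ f` with no small-sample
  correction.
* **Consensus**: per position, a single base at ≥ 0.8 wins; otherwise the
  smallest 2–3-base set reaching the degenerate threshold (default 0.9)
  wins; else N. The degenerate threshold is higher than the single-base
  one because an unconstrained position already places ~0.5 / ~0.75 on its
  best pair / triple — 0.9 keeps sampling noise at realistic depths from
  promoting uniform positions to B/D/H/V calls.
* Coordinates are 0-based half-open internally, 1-based inclusive in
  reports; PAM position 1 is the first base 3′ of the protospacer.

## Amplicon quantification

Alignment is global with affine gaps (match +2, mismatch −4, gap of
length k costs 12 + k), so a 3-bp indel (cost 15) is preferred over
spurious mismatch runs but isolated substitutions are never absorbed into
gaps. Equal-length reads with ≤ 4 mismatches take a gapless fast path that
is provably optimal under these scores (a gap pair costs ≥ 28; re-pairing
a mismatch gains ≤ 6). Reads below 60% identity are dropped and counted.

A read is an indel read iff an I/D run overlaps cut ± `quant_window`
(default 10 bp); substitution-only reads never count. Conversion
percentages use only reads with zero I/D runs anywhere, scanning
protospacer positions 1–10 (PAM-distal numbering, the window convention of
BE4max-class editors; the "E1-C4" label style means C at position 4 of
target E1). Reverse-strand targets are handled by coordinate reflection
and complementation; tests assert strand involution exactly. Whether a
published experiment used the same window and indel-free criterion is
generally unknowable from figures alone, so both are parameters.

## Site scanning and density

Density of an IUPAC pattern under an i.i.d. base model is
∏ⱼ Σ_{b∈allowedⱼ} p(b), doubled for both strands with no palindrome
deduplication — per-strand site counting, the only convention under which
NNGG yields exactly 1 site per 8 positions. An ambiguous genome base N
matches nothing, even pattern-N positions (conservative calling in
gap-rich toy genomes). Off-target search is a brute-force vectorized
window scan (exact IUPAC PAM + Hamming-bounded spacer, both strands,
sorted by mismatches); desk-scale genomes are the contract, so no index
structures.

## Protein arithmetic

Global alignment uses BLOSUM62 with EMBOSS-style affine costs (gap of
length k costs 10 + k; end gaps penalized). Percent identity defaults to
identical columns over alignment length including gap columns, switchable
to the shorter-sequence denominator — the two conventions differ by about
a point on diverged orthologs, which is why identity figures quoted
without parameters carry an intrinsic ±1–2-point ambiguity. Residue
numbering is 1-based throughout; mutation specs are validated against the
actual residue and fail loudly on mismatch. Domain spans (e.g. a PID) are
user-supplied 1-based inclusive intervals; the package does no domain
detection.

### The synthetic ortholog stand-in

`pamprofiler.orthologs` bundles the SaCas9 protein (UniProt J7RUA5,
1053 aa) and *generates* a synthetic S. auricularis-style ortholog; the
published ortholog sequence is not distributed with this package. The
stand-in is a deterministic seeded edit of SaCas9: a 5-residue N-terminal
insertion (placing the RuvC catalytic D at position 15), one internal
insertion and one internal deletion (so SaCas9 E782/N968/R1015 align to
positions 788/973/1020 — a +6 offset at 782 but +5 at 968/1015, the
signature of an indel between them), a 3-residue C-terminal extension
(total 1,061 aa), and 389 substituted columns out of 1,062
(62.43% identity by construction), with the landmarks and small windows
around them protected so the optimal alignment recovers the designed
correspondence. All ortholog tests and reported numbers are therefore
checks of the alignment/mapping/mutagenesis machinery against ground truth
known by construction — they validate the arithmetic, not any published
measurement.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to make statistical assertions
sharp while staying desk-scale: ~22k sorted reads for consensus recovery
(IC thresholds are then >50σ from noise), a fully enumerated 256-construct
mini-library for exact filter checks, 4,000–5,000 reads per quantification
replicate across 20 replicates (3-binomial-SD bands), 10 × 10-kb genomes
for off-target oracle agreement, and 1 Mb for the empirical density check
(variance includes the lag-1 covariance of overlapping windows, which
inflates it ~40% over the naive binomial). Stochastic assertions use fixed
seeds; determinism is itself under test (byte-identical FASTQ and
manifests for equal seeds).

## Known limitations

* The generator's NHEJ length distribution is a stylized geometric; real
  indel spectra are locus-dependent and microhomology-driven.
* No UMI handling, paired-end merging, quality trimming or chimera
  filtering; inputs are assumed to be clean single-orientation amplicons.
* Off-target search is Hamming-only (no DNA/RNA bulges) and unranked —
  candidate enumeration with mismatch annotation, not activity prediction.
* The PAM wheel and logo plots are diagnostic graphics, not typographic
  sequence logos.
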