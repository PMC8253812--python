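# Methods

This note documents the models and procedural choices behind
`breaktag`: what each stage assumes, which parameters matter, what the
simulator does and does not emulate, and where the design was genuinely
open.

## Junction model

A tag-integration experiment reads each double-strand break (DSB) from
both sides. The Tag donor integrates into the break; tag-specific
primers then amplify outward from the Tag into genomic sequence, so the
first genomic base of read 2 is the tag–genome junction. A break with
top-strand nick at coordinate `c` and signed overhang `k` (positive =
5′ overhang) exposes two junctions:

- plus-side junction at `c` — observed as plus-strand alignments whose
  aligned start is `c`;
- minus-side junction at `c + k` — observed as minus-strand alignments
  whose aligned **end** is `c + k`.

The minus-strand convention (aligned end, i.e. rightmost aligned base
+ 1) is a deliberate choice: using the raw alignment start on both
strands would shift minus-side observations by the read length.
Residual Tag bases on the read are represented as soft clips and are
excluded from the aligned span, so they never displace the junction.
The simulator emits alignments to the same convention, which is what
makes junction-level recovery tests meaningful. All coordinates are
0-based, half-open.

The modal difference (minus junction − plus junction) recovers the
overhang. By this sign convention +1 is the 1-nt 5′ overhang Cas9
frequently leaves, and +4/+5 mixtures are Cpf1-style staggered ends.

## PCR-duplicate consolidation

Reads mapping to the same (chromosome, position, strand) with the same
UMI, within the same library, are treated as PCR copies of one pre-PCR
molecule and collapse into a single observation. Every count downstream
is a count of consolidated molecules. Exact UMI equality is the
default; an optional directional one-edit clustering (larger counts
absorb 1-substitution neighbours) is available for UMI sequencing
errors. Consolidation can only reduce counts, and with unique UMIs it
is the identity.

## Site calling

Calling is a fixed-threshold recipe, not a statistical model:

1. **Hotspot grouping** — junction positions pooled over strands and
   libraries are grouped whenever consecutive gaps are < `max_gap`
   (default 10 bp, strictly less). Pooling is necessary so the two
   sides of one break land in the same region and can be co-evaluated.
2. **Sliding windows** — windows of `window` bp (default 10), step
   1 bp, covering the region padded by `window − 1` on each side, so
   every window touching a member position is evaluated. Counts are
   kept per (strand × library) class.
3. **Peak detection** — strict local maxima of the summed window
   counts. Plateaus collapse to their leftmost window; among peaks
   closer than `min_peak_separation` (default = the window size, so one
   break cannot be called twice) only the highest survives, leftmost on
   ties. The detector is deliberately written in-house to pin down
   these plateau/tie semantics exactly; tests verify it against an
   exhaustive oracle.
4. **Support rule** — a peak becomes a site when every class in one of
   two evidence branches reaches `min_support` (default 6, i.e. "more
   than five" molecules): both strands, or one strand amplified by both
   tag-primer libraries. The threshold is applied *per class*, the
   stricter of the two possible readings of a bidirectional rule; the
   parameter makes the total-count reading one flag away. The consensus
   cut is the modal junction inside the peak window, leftmost on ties.
5. **Transposon rule** — the single-library mode replaces the branch
   rule by total support ≥ `min_support_transposon` (default 5) with
   both strands represented.

No prominence filter, background model or FDR is applied: support
thresholds are the only filter, which matches how fixed-threshold
junction assays are analysed in practice.

## Guide matching

Each site's ±25 bp flank (`flank`, must be at least the spacer length)
is scanned with the best ungapped local placement of the spacer on both
strands. With unit match/mismatch scores and effectively infinite gap
penalties, the optimal Smith–Waterman alignment is exactly the
placement minimising substitutions, so the scan is implemented as a
vector Hamming sweep over all offsets; spacer bases hanging off the
window, and N bases, count as mismatches. Ties break to the leftmost
genomic offset, then the + strand. Classification: 0 mismatches =
on-target, 1..`max_mismatches` (default 6) = off-target, otherwise
unmatched. A gapped mode exists for exploration but gapped hits are
never counted as off-targets, because substitution counting is only
defined for ungapped placements.

The PAM is **not** required by default: the matcher reports the
adjacent PAM-side bases and whether they fit the configured IUPAC
pattern (NGG 3′ Cas9-style, TTTV 5′ Cpf1-style), and a strict mode
filters on it. This keeps the decision rule purely spacer-based while
letting a user enforce the nuclease's PAM.

## Cut-geometry profiles

Junctions within ±15 bp of the consensus cut are pooled per strand.
The offset distribution assigns each minus-side junction its distance
from the modal plus-side junction, weighted by molecule support.
Labels: `blunt` iff the modal offset is 0; `1-nt 5'/3' overhang` for
±1; `staggered-multi` when at least two offsets each carry ≥ 20% of the
mass or the modal |offset| ≥ 2; `undetermined` with single-strand
support. The 20% mass threshold is an artifact choice that formalises
what is usually judged visually from overlapping read pileups; it is
not a community standard.

`pam_offset` reports the distance from the cut to the PAM-proximal
protospacer boundary, orientation-normalised so the Cas9 convention
("cut 3–4 bp upstream of the PAM") reads the same on either strand.

## Transposon motif statistics

Flank windows of ±5 bp around the insertion dinucleotide (12-mers) are
summarised as a position frequency matrix, and each of the 16
dinucleotides at the central step is tested with a one-sided exact
binomial test against a background frequency — either the genome's
dinucleotide composition or per-window shuffles. This targeted test
replaces de-novo motif discovery deliberately: the scientific question
(is there a TA preference at insertion steps?) is a point hypothesis,
and an exact test against an explicit background is both stronger and
dependency-free. De-novo discovery is out of scope.

Region annotation assigns each site a class by interval overlap with
precedence exon > intron > intergenic. Cross-run overlap counts merge
sites within a ±5 bp tolerance (artifact choice).

## Amplicon validation

Reads are infix-aligned to the amplicon reference in both orientations
with an edit-distance aligner (edlib). Because minimal edit paths are
not unique and fragment long insertions into interleaved ops, variant
ops separated by match runs shorter than 10 bp are merged into blocks;
a block's net query surplus is an insertion (its segment is the block's
query span), net reference surplus a deletion, and a balanced block a
substitution run. Reads divide into wildtype (no net indel), indel,
donor (an inserted segment matches the Tag) and unaligned (> 35%
errors; excluded from denominators by default, switchable).

Tag discrimination uses a local alignment (match +1, mismatch −1, gap
open −2 / extend −1) of the segment against the Tag on both strands: a
match requires ≥ 16 identical bases at ≥ 50% identity over the aligned
region. This is the assay's printed decision rule; an aligner e-value
is deliberately not used since e-values depend on a specific aligner's
statistics while the length/identity rule is self-contained. The
manner is forward/reverse by strand, or partial when less than 90% of
the Tag span aligns. Ratios (indel frequency, integration rate) are
computed in exact rational arithmetic before conversion to float.

## The simulator

The simulator is first-class, tested code and defines the study
conditions for every recovery claim. It emulates:

- a random genome at configurable GC (default 0.41, a typical
  mammalian-genome value);
- planted protospacers at exact Hamming distances (0–6+) from the
  guide, with a concrete PAM drawn from the IUPAC pattern on either
  strand, and a collision check that re-draws a chromosome if the
  random background happens to contain another ≤6-mismatch guide
  occurrence within 100 bp of a planted site;
- cut geometry per site: blunt, fixed overhang, or a mixture sampled
  per molecule (e.g. (4, 5) for a Cpf1-style cutter);
- read structure: R1 = [UMI][barcode][genomic], R2 = [Tag
  prefix][genomic from junction], all lengths configurable (the layout
  of real kits varies; nothing downstream depends on exact lengths);
- Tag orientation 50/50 per molecule; in nuclease mode each molecule
  yields one read pair per tag-primer library (the two nested PCRs of
  one sample), covering both sides of the break; in transposon mode a
  single arm library with one read pair per molecule on a random side;
- per-molecule UMIs, geometric PCR duplication at `pcr_duplicate_rate`,
  uniform per-base substitution errors at `error_rate`, uniform random
  background integrations, and per-site editing efficiency;
- outputs in plain-text FASTA/FASTQ/SAM/TSV, byte-identical for
  identical (config, seed).

It does **not** emulate: indel formation during repair (junction
positions are exact), chimeric reads or translocations, quality-score
structure (flat Q40 with a flat error rate), fragment-size
distributions, mappability/repeat structure of real genomes, or
chromatin-dependent capture efficiency. Recovery results on simulated
data therefore demonstrate the correctness of the algorithmic chain
under the stated read model — not the sensitivity of the assay on real
genomes, where alignment ambiguity and repair-induced junction jitter
add noise the simulator only approximates via its error and background
knobs.

The default Tag is a synthetic 35-mer designed GC-balanced at 45.7%
(16/35 G+C), matching the design target of tag-integration donors; it
is not a vendor oligo.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so a
full run takes seconds on one CPU while every count in the support
rules is still exercised far from its boundary: a 1-Mb genome with ten
planted sites (mismatch ladder 0–6), 100 molecules per site and 500
background integrations for recovery; 40–100 molecules per site for
geometry and transposon scenarios; 1000 random instances per
brute-force oracle comparison; 100 seeded trials for the motif null.

## Known limitations

- The caller's thresholds are counts, not rates: libraries of very
  different depth should be compared via the cross-run report rather
  than by raw support.
- Multi-mapping reads are handled only through the MAPQ filter
  (default ≥ 20); repeat-region breaks are under-detected by design.
- The spec of the bidirectional rule applies per evidence class; a
  site read out deeply from one side only (asymmetric capture) will
  not be called however deep the coverage, unless both libraries agree.
- Edit-distance alignment at amplicon scale treats all indels equally;
  complex alleles (nested insertions with deletions) collapse into the
  net event of their merged block.
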