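# Methods

## The detection model

A retrocopy is the genomic trace of a reverse-transcribed, spliced mRNA:
an intronless copy of a gene's exonic sequence, often 5'-truncated and
ending in a poly-A tract, inserted far from the source locus by the
LINE-1 machinery.  retroscout detects these traces from block-structured
local alignments of annotated transcripts against an assembled genome
(PSL or PAF with CIGAR), applying four filters in sequence to each
alignment chain:

1. **Match length** — at least `min_matched_nt` (default 120) identical
   aligned bases, roughly half an average exon.  "At least" is
   inclusive: 120 passes, 119 fails.
2. **Parental proximity** — chains overlapping the parental gene's
   annotated extent, or within `parental_exclusion_bp` (default
   200 000 bp) of it on the same chromosome, are discarded.  This guards
   against tandem and proximal segmental duplications, which are
   DNA-level copies near the source.  "Up to" is inclusive: a gap of
   exactly 200 000 bp is still excluded; 200 001 bp is retained.
   The reference extent is the per-gene union over all transcripts of
   the gene, one extent per chromosome, because the duplication artefact
   being excluded is a cis phenomenon; loci of the same gene on other
   chromosomes never exclude anything.
3. **Intron loss** — the parent's exon-exon junction positions (cumulative
   exon lengths in transcript coordinates, with genomic exon order
   reversed for minus-strand genes) are projected onto the chain.  A
   junction is *spanned* when a single aligned block contains it with at
   least `junction_flank_nt` (default 10) aligned bases on each side: the
   intron is demonstrably absent there.  A junction falling on a block
   boundary — the alignment pattern produced by an intron-retaining
   copy or the parental locus itself — is not spanned.  The chain passes
   when the 3'-most junction inside its aligned query range is spanned
   and at least `min_spanned_junctions` (default 1) junctions are spanned
   overall.  The 3'-anchored rule reflects the mechanism: L1-mediated
   retroduplication initiates at the mRNA 3' end and truncates 5', so a
   genuine but truncated retrocopy keeps its 3'-terminal junctions while
   a DNA-level duplicate spans none.  Single-exon parents have no
   junction and can never pass; they are tallied separately rather than
   silently dropped.
4. **Transposable-element fraction** — the fraction of the chain's
   aligned target bases (the union of block intervals, not the footprint
   span, so unaligned gaps do not dilute the ratio) covered by annotated
   LINE/SINE/LTR/DNA/Retroposon repeats.  Chains with more than
   `max_te_fraction` (default 0.40) are removed; exactly 0.40 is
   retained ("more than" is strict).  Simple repeats, low-complexity
   runs and satellites are parsed and stored but never counted.

A chain stops at its first failing stage and every verdict (stage,
pass/fail, measured value) is kept as a trace, so each rejection is
attributable.  Survivors are clustered into loci by single-linkage on
footprint overlap (>= 1 bp, strand-agnostic — two overlapping
opposite-strand calls almost surely describe one insertion event); each
cluster's representative is the member with the most matched bases
(ties: longer footprint, then smaller transcript id), and loci are named
`<parental gene name>P<n>`, numbered per gene in (chromosome, start)
order, the conventional processed-pseudogene naming pattern.

## Coordinate and chain conventions

All internal intervals are 0-based half-open on the forward genomic
strand; GTF/GFF3 I/O converts to and from 1-based closed at the file
boundary, BED and PSL are natively 0-based.  Alignment chains are
normalised at parse time to query-forward block order with the strand as
a flag, so junction projection always works directly in transcript
coordinates.  For a minus-strand chain this means per-block target
intervals (still forward-strand) decrease as query position increases;
both orders cannot increase simultaneously for a genuine reverse-strand
alignment, and query-forward order is the one the junction test needs.
PSL minus-strand `qStarts` (stored by that format in
reverse-complement query coordinates) and PAF CIGAR walks are converted
to this convention on input and back on output; the round-trip is exact.
PAF records without a `cg` tag are rejected rather than approximated by
a single block, because the junction test is meaningless without true
block structure.

## The simulator

The generator builds a study in which every filter's designed behaviour
is observable, on an i.i.d. random background sequence (default 1 Mb,
single chromosome):

* 10 genes with 3–8 exons of 80–300 bp separated by introns of
  500–5000 bp, on random strands;
* 20 retrocopies: a random gene's spliced mRNA, 5'-truncated with
  probability 0.3 by a uniform 10–50% of its length, substituted
  per-base at rate 0.02, with a 10–30 bp poly-A appended, inserted on a
  random strand at least 250 kb from the parent (beyond the 200 kb
  exclusion window, as a real detectable retrocopy must be);
* 5 tandem duplications: a verbatim copy of a gene's full genomic span,
  introns included, placed within 50 kb of the parent;
* 5 TE decoys: full-length mRNA inserts whose footprint is annotated as
  repeat over 60% of its length;
* 5 short fragments: 80 bp 3'-terminal mRNA fragments, below the match
  threshold;
* background repeat annotation covering ~10% of the genome, drawn only
  over regions free of planted elements so it cannot contaminate their
  TE fractions.

Each insert carries a ground-truth record including the cascade stage
its class is designed to fail (retrocopy: none; tandem duplication:
parental distance; TE decoy: TE fraction; short fragment: match
length).

Alignments are emitted by bookkeeping rather than by running an aligner:
the parental self-alignment (one block per exon, introns as target
gaps), and one single-block alignment per mRNA-derived insert with
`matches = aligned length − substitutions` (substitutions always change
the base, so this is exact; the poly-A is not part of the alignment).
This keeps the suite hermetic and every expected verdict derivable.

Two generator details are deliberate guarantees rather than samples.
First, the truncation offset is clamped so that the 3'-most junction
survives with a 20 bp safety flank and at least 150 aligned bases
remain: an insert truncated past its last junction would no longer be a
detectable retrocopy, contradicting its own truth record.  Second,
planted elements are spaced at least 200 bp apart, so distinct
insertions never merge into one locus by accident.

What the simulator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: insertions and deletions
within retrocopies, target-site duplications, 5' inversions, empirical
exon/intron length and nucleotide composition distributions, spurious
alignments from genomic repeat homology, and aligner-specific block
fragmentation.  On real genomes the alignment step (external to this
package) governs sensitivity; the cascade only filters what the aligner
reports.

## Numerical and degenerate-input choices

* Covered-base queries over repeats use per-chromosome merged sorted
  intervals with binary search; results equal a per-base membership
  count exactly (no floating point until the final division).
* Interval gap arithmetic is half-open: adjacent intervals (end == start)
  have gap 0 and overlap 0, so they neither exclude (stage 2 measures
  gap) nor cluster (grouping requires >= 1 shared base).
* A gene annotated on several chromosomes yields one extent per
  chromosome; only same-chromosome extents participate in stage 2, and a
  transcript on a chromosome with no same-gene extent is effectively at
  infinite distance.
* Chains are processed in a canonical sorted order, making cascade
  output and locus naming invariant to input file order.
* Empty intervals are rejected at the 1-based conversion boundary (the
  closed convention cannot represent them).
* With the TE filter disabled (no repeat annotation available), stage 4
  is skipped entirely and catalog TE fractions are reported as `NA`
  rather than fabricated as zero.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `min_matched_nt` | 120 | bases | half an average exon; smaller hits are unreliable |
| `parental_exclusion_bp` | 200 000 | bp | window covering most tandem/segmental duplications |
| `max_te_fraction` | 0.40 | fraction | above this the "retrocopy" is likely a repeat artefact |
| `junction_flank_nt` | 10 | aligned bases | rejects junctions merely touching a block edge while tolerating terminal mismatches |
| `min_spanned_junctions` | 1 | count | one cleanly lost intron is sufficient evidence; stricter settings mimic more conservative catalogs |

All five are exposed on the command line and in config files; the
boundary semantics (inclusive/inclusive/strict) are fixed.

## Known limitations

* Parent assignment is per aligned transcript; no splice-isoform-aware
  parent selection is attempted beyond the transcript that aligned.
* Naming is always de novo (`P1..Pn`); adherence to pre-existing curated
  pseudogene names would require an external name source and is out of
  scope.
* Polymorphic (non-reference) retrocopy discovery from read data, ORF
  integrity, and cross-species conservation calls are out of scope.
* The sweep-based single-linkage clustering is exact for the default
  1 bp overlap threshold; for larger thresholds it links against the
  cluster's running union rather than individual members.
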