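# retroscout

Identification of **retrocopies** (processed gene copies, a.k.a.
processed pseudogenes) in an assembled genome from transcript-to-genome
alignments.

Retrocopies arise when the LINE-1 machinery reverse-transcribes a
spliced mRNA and reintegrates the cDNA elsewhere in the genome.  The
resulting copy lacks introns, is frequently 5'-truncated, carries a
poly-A tract, and lands far from its source gene.  Distinguishing these
insertions from tandem duplications and repeat-driven alignment
artefacts is the core problem this package solves, for genome
annotators and researchers studying gene duplication, pseudogenes and
transposable-element activity.

## Method

Given a genome (FASTA), a gene annotation (GTF/GFF3), repeat annotation
(BED or RepeatMasker `.out`) and block-structured alignments of spliced
transcripts against the genome (PSL, or PAF with a `cg` CIGAR tag),
each alignment chain passes through a four-stage cascade:

1. **match length** — keep chains with ≥ 120 identical aligned bases;
2. **parental distance** — drop chains overlapping or within 200 kb of
   the parental gene locus (tandem-duplication guard);
3. **intron loss** — require the 3'-most reachable exon–exon junction of
   the parent transcript to lie inside a single aligned block with ≥ 10
   aligned bases on each side (the intron is absent there; 5'-truncated
   copies still qualify, intron-retaining duplicates never do);
4. **TE fraction** — drop chains whose aligned bases are > 40% covered
   by LINE/SINE/LTR/DNA/Retroposon annotation.

Survivors are clustered into loci by single-linkage footprint overlap
and named `<parental gene name>P<n>` (e.g. `GAPDHP1`), the conventional
processed-pseudogene pattern.  All thresholds are configurable; every
per-chain verdict is recorded and written alongside the catalog.

A seeded simulator (`retroscout simulate`) generates complete synthetic
studies — genes, planted retrocopies, tandem-duplication / TE / short-
fragment decoys, ideal alignments and ground truth — so the whole
pipeline is testable without downloading anything, and an evaluation
harness (`retroscout evaluate`) scores any catalog against that truth.

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

```sh
retroscout simulate --seed 7 --out scene/
retroscout detect \
    --genome scene/genome.fa --annotation scene/annotation.gtf \
    --repeats scene/repeats.bed --alignments scene/alignments.psl \
    --out calls/
retroscout evaluate --catalog calls/catalog.tsv --truth scene/truth.tsv \
    --rejections calls/rejections.tsv
```

`detect` logs the cascade in order (45 input chains: 10 parental
self-alignments plus 35 planted inserts):

```
INFO retroscout: surviving after input: 45
INFO retroscout: surviving after match_length: 40
INFO retroscout: surviving after parental_distance: 25
INFO retroscout: surviving after junction: 25
INFO retroscout: surviving after te_fraction: 20
INFO retroscout: final loci: 20
```

The 5 short fragments fall at stage 1, the 10 parental self-alignments
and 5 tandem duplicates at stage 2, the 5 TE decoys at stage 4, leaving
exactly the 20 planted retrocopies.  `evaluate` prints:

```
loci detected      20
truth retrocopies  20
true positives     20
false positives    0
false negatives    0
precision          1.0000
recall             1.0000
F1                 1.0000
decoy rejection by stage (expected/other/called/unaligned):
  short_fragment   5/0/0/0
  tandem_dup       5/0/0/0
  te_decoy         5/0/0/0
```

and `calls/catalog.tsv` begins:

```
name     chrom   start  end    strand  parental_gene_name  ...  matched_nt  te_fraction  spanned_junctions
GENE3P1  chrSim  3820   4294   -       GENE3               ...  469         0.0000       1
GENE3P2  chrSim  42436  43306  +       GENE3               ...  846         0.0000       3
```

`GENE3P1` is a 5'-truncated copy of GENE3 on the minus strand (469
matched bases, only the last junction retained); `GENE3P2` is a
near-full-length copy spanning 3 junctions.  `calls/` also contains the
catalog as BED6 and GFF3, the retrocopy sequences as FASTA, the
per-chain rejection table, and a manifest with config and checksums.

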