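"""Domain types and coordinate conventions for retrocopy detection.

Everything downstream of the file readers speaks one dialect: 0-based,
half-open intervals on the forward genomic strand.  GTF/GFF3 I/O converts
to and from 1-based closed coordinates at the file boundary; BED and PSL
are natively 0-based.

Alignment chains are normalised to query-forward block order with the
strand carried as a flag, so that exon-junction projection always works in
plain transcript (query) coordinates.  For a minus-strand chain the
per-block target intervals are still expressed on the forward genomic
strand; as query position increases, target position decreases.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

#: Repeat classes recognised by :class:`RepeatIndex`.
TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Retroposon", "Other")

#: Classes counted as transposable-element sequence by default.  Simple
#: repeats, low-complexity runs and satellites map to "Other" and are
#: stored but never counted.
DEFAULT_COUNTABLE_CLASSES = frozenset({"LINE", "SINE", "LTR", "DNA", "Retroposon"})

STAGE_MATCH_LENGTH = "match_length"
STAGE_PARENTAL_DISTANCE = "parental_distance"
STAGE_JUNCTION = "junction"
STAGE_TE_FRACTION = "te_fraction"
STAGES = (
    STAGE_MATCH_LENGTH,
    STAGE_PARENTAL_DISTANCE,
    STAGE_JUNCTION,
    STAGE_TE_FRACTION,
)


class RetroscoutError(Exception):
    """Base class for all package errors."""


class CoordinateError(RetroscoutError):
    """Invalid interval or coordinate-system violation."""


class ChainError(RetroscoutError):
    """Inconsistent alignment-chain block structure."""


class AnnotationError(RetroscoutError):
    """Invalid gene annotation input."""


# ---------------------------------------------------------------------------
# coordinate conversions (file-boundary helpers)

def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> 1-based closed (GTF/GFF3).

    Empty intervals are rejected: the closed convention cannot represent
    them."""
    if end <= start or start < 0:
        raise CoordinateError(f"invalid interval ({start}, {end})")
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """1-based closed (GTF/GFF3) -> internal 0-based half-open."""
    if end < start or start < 1:
        raise CoordinateError(f"invalid 1-based interval ({start}, {end})")
    return start - 1, end


def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


# ---------------------------------------------------------------------------
# sequences and transcripts

@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence (chromosome, scaffold or contig)."""

    seq_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


def junction_positions(exons: Sequence[tuple[int, int]], strand: str) -> list[int]:
    """Exon-exon junction positions in transcript (query) coordinates.

    Each position is the offset of the first base of the next exon in the
    spliced mRNA, accumulated 5'->3'.  For a minus-strand gene the
    genomically last exon is the transcript's first, so genomic exon order
    is reversed before accumulation.  A single-exon transcript has no
    junction.
    """
    lengths = [e - s for s, e in exons]
    if strand == REVERSE:
        lengths.reverse()
    out: list[int] = []
    total = 0
    for ln in lengths[:-1]:
        total += ln
        out.append(total)
    return out


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of a parental transcript.

    ``exons`` are genomic intervals, 0-based half-open, sorted by genomic
    start regardless of strand.  ``junctions`` (a property) are positions
    in transcript coordinates, strictly increasing and bounded by the
    spliced length.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s or s < 0:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: bad exon ({s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = e

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def junctions(self) -> list[int]:
        return junction_positions(self.exons, self.strand)

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneLocus:
    """Genomic extent of a gene on one chromosome: the union extent over
    all of its transcripts there.  ``single_exon`` flags genes whose
    transcripts on this chromosome are all intronless (such genes cannot
    provide the junction evidence the cascade requires)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    single_exon: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def gene_locus_extent(transcripts: Sequence[TranscriptModel]) -> list[GeneLocus]:
    """Union extent of a gene's transcripts, one locus per chromosome.

    All transcripts must share ``gene_id``.  A gene annotated on several
    chromosomes yields one locus per chromosome; the parental-proximity
    filter is a guard against cis tandem duplication, so only same-
    chromosome loci are ever compared against an alignment.
    """
    if not transcripts:
        raise AnnotationError("gene_locus_extent: empty transcript list")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise AnnotationError(f"mixed gene_ids in one extent call: {sorted(gene_ids)}")
    by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_chrom[t.chrom].append(t)
    loci = []
    for chrom in sorted(by_chrom):
        txs = by_chrom[chrom]
        loci.append(
            GeneLocus(
                gene_id=txs[0].gene_id,
                gene_name=txs[0].gene_name,
                chrom=chrom,
                start=min(t.span[0] for t in txs),
                end=max(t.span[1] for t in txs),
                single_exon=all(t.is_single_exon for t in txs),
            )
        )
    return loci


def build_gene_loci(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[GeneLocus]]:
    """Map gene_id -> loci (one per chromosome) for a whole annotation."""
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    return {gid: gene_locus_extent(txs) for gid, txs in by_gene.items()}


# ---------------------------------------------------------------------------
# alignment chains

class Block(NamedTuple):
    """One gapless aligned block; query and target intervals have equal
    length, both 0-based half-open, target on the forward genome strand."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int


@dataclass(frozen=True)
class AlignmentChain:
    """Block-structured local alignment of one transcript to one locus.

    Blocks are stored in query-forward order (strictly increasing, non-
    overlapping query intervals).  For ``target_strand == '-'`` the target
    intervals decrease block-to-block; the footprint is always the forward-
    strand interval from the first to the last aligned target base.
    """

    query_id: str
    query_length: int
    target_chrom: str
    target_length: int
    target_strand: str
    blocks: tuple[Block, ...]
    matches: int

    @property
    def footprint(self) -> tuple[int, int]:
        return (
            min(b.t_start for b in self.blocks),
            max(b.t_end for b in self.blocks),
        )

    @property
    def query_span(self) -> tuple[int, int]:
        return self.blocks[0].q_start, self.blocks[-1].q_end

    @property
    def aligned_bases(self) -> int:
        """Total aligned length (identical to the block-union target size,
        since blocks never overlap in target)."""
        return sum(b.q_end - b.q_start for b in self.blocks)

    def sort_key(self) -> tuple:
        fp = self.footprint
        return (self.target_chrom, fp[0], fp[1], self.query_id,
                self.target_strand, self.matches, self.blocks)


def normalize_chain(
    query_id: str,
    query_length: int,
    target_chrom: str,
    target_length: int,
    target_strand: str,
    blocks: Iterable[tuple[int, int, int, int]],
    matches: int,
) -> AlignmentChain:
    """Build a validated chain with blocks in query-forward order.

    Raises :class:`ChainError` on inconsistent block arithmetic: unequal
    query/target block lengths, overlaps, out-of-bounds coordinates,
    target order inconsistent with the strand flag, or an impossible match
    count.  Normalisation is idempotent.
    """
    if target_strand not in STRANDS:
        raise ChainError(f"{query_id}: unknown strand {target_strand!r}")
    blk = sorted(Block(*b) for b in blocks)
    if not blk:
        raise ChainError(f"{query_id}: chain has no blocks")
    total = 0
    prev: Optional[Block] = None
    for b in blk:
        if b.q_end - b.q_start != b.t_end - b.t_start or b.q_end <= b.q_start:
            raise ChainError(f"{query_id}: bad block {tuple(b)}")
        if b.q_start < 0 or b.q_end > query_length:
            raise ChainError(f"{query_id}: block outside query ({tuple(b)})")
        if b.t_start < 0 or b.t_end > target_length:
            raise ChainError(f"{query_id}: block outside target ({tuple(b)})")
        if prev is not None:
            if b.q_start < prev.q_end:
                raise ChainError(f"{query_id}: blocks overlap in query")
            if target_strand == FORWARD and b.t_start < prev.t_end:
                raise ChainError(f"{query_id}: target order violates + strand")
            if target_strand == REVERSE and b.t_end > prev.t_start:
                raise ChainError(f"{query_id}: target order violates - strand")
        total += b.q_end - b.q_start
        prev = b
    if not 0 <= matches <= total:
        raise ChainError(f"{query_id}: matches={matches} outside [0, {total}]")
    return AlignmentChain(
        query_id=query_id,
        query_length=query_length,
        target_chrom=target_chrom,
        target_length=target_length,
        target_strand=target_strand,
        blocks=tuple(blk),
        matches=matches,
    )


def renormalize(chain: AlignmentChain) -> AlignmentChain:
    """Re-run normalisation on an existing chain (idempotence check hook)."""
    return normalize_chain(
        chain.query_id,
        chain.query_length,
        chain.target_chrom,
        chain.target_length,
        chain.target_strand,
        chain.blocks,
        chain.matches,
    )


# ---------------------------------------------------------------------------
# repeats

class RepeatInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    repeat_class: str  # one of TE_CLASSES
    label: str         # raw class/family string, e.g. "LINE/L1"


class RepeatIndex:
    """Queryable set of repeat intervals with exact covered-base queries.

    Countable intervals (those whose class is in ``countable_classes``)
    are merged per chromosome into disjoint sorted intervals, so a
    covered-base query returns the size of the intersection between the
    query interval and the union of countable repeats.
    """

    def __init__(
        self,
        intervals: Iterable[RepeatInterval],
        countable_classes: frozenset[str] = DEFAULT_COUNTABLE_CLASSES,
    ) -> None:
        self.intervals: tuple[RepeatInterval, ...] = tuple(intervals)
        self.countable_classes = frozenset(countable_classes)
        per: dict[str, list[list[int]]] = defaultdict(list)
        for iv in self.intervals:
            if iv.end <= iv.start or iv.start < 0:
                raise CoordinateError(f"bad repeat interval {iv}")
            if iv.repeat_class in self.countable_classes:
                per[iv.chrom].append([iv.start, iv.end])
        self._merged: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in per.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[chrom] = (
                [s for s, _ in merged],
                [e for _, e in merged],
            )

    def covered_bases(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end) covered by the union of countable repeats."""
        if end <= start:
            return 0
        got = self._merged.get(chrom)
        if got is None:
            return 0
        starts, ends = got
        i = bisect.bisect_right(ends, start)
        total = 0
        while i < len(starts) and starts[i] < end:
            total += min(ends[i], end) - max(starts[i], start)
            i += 1
        return total

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# pipeline configuration and provenance

@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the four-stage filter cascade.

    min_matched_nt
        Minimum identical aligned bases (stage 1); half the average human
        exon size.  "At least" semantics: equality passes.
    parental_exclusion_bp
        Window around the parental gene locus within which alignments are
        discarded as putative tandem duplications (stage 2).  "Up to"
        semantics: a distance equal to the window is still excluded.
    max_te_fraction
        Maximum tolerated fraction of aligned bases covered by countable
        transposable-element annotation (stage 4).  "More than" semantics:
        equality passes, anything above is removed.
    junction_flank_nt
        Aligned bases required on each side of an exon-exon junction, inside
        a single block, for the junction to count as spanned (stage 3).
    min_spanned_junctions
        Minimum number of spanned junctions in addition to the 3'-most rule.
    """

    min_matched_nt: int = 120
    parental_exclusion_bp: int = 200_000
    max_te_fraction: float = 0.40
    junction_flank_nt: int = 10
    min_spanned_junctions: int = 1

    def __post_init__(self) -> None:
        if min(self.min_matched_nt, self.parental_exclusion_bp,
               self.junction_flank_nt, self.min_spanned_junctions) < 0:
            raise RetroscoutError("pipeline thresholds must be non-negative")
        if not 0.0 <= self.max_te_fraction <= 1.0:
            raise RetroscoutError("max_te_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FilterTrace:
    """One stage's verdict on one chain: the stage name, whether the chain
    passed, and the measured quantity (matched nt, distance bp, spanned
    junction count, or TE fraction)."""

    stage: str
    passed: bool
    value: float


@dataclass(frozen=True)
class RetrocopyCandidate:
    """A chain that survived the full cascade, with provenance."""

    chain: AlignmentChain
    parent: TranscriptModel
    trace: tuple[FilterTrace, ...]
    spanned_junctions: int
    three_prime_junction_spanned: bool


@dataclass(frozen=True)
class RetrocopyLocus:
    """A grouped, named retrocopy call.

    The span is the union footprint of the member chains; strand, parental
    gene, matched nt and TE fraction come from the representative (the
    member with the most matched bases)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    parental_gene_id: str
    parental_gene_name: str
    representative_transcript_id: str
    members: tuple[RetrocopyCandidate, ...]
    matched_nt: int
    te_fraction: Optional[float]
    spanned_junctions: int
    name: Optional[str] = None

    def with_name(self, name: str) -> "RetrocopyLocus":
        return replace(self, name=name)


# ---------------------------------------------------------------------------
# simulation ground truth

KIND_RETROCOPY = "retrocopy"
KIND_TANDEM_DUP = "tandem_dup"
KIND_TE_DECOY = "te_decoy"
KIND_SHORT_FRAGMENT = "short_fragment"
TRUTH_KINDS = (KIND_RETROCOPY, KIND_TANDEM_DUP, KIND_TE_DECOY, KIND_SHORT_FRAGMENT)

#: Which cascade stage each planted decoy class is designed to fail.
EXPECTED_REJECTING_STAGE: Mapping[str, str] = {
    KIND_RETROCOPY: "none",
    KIND_TANDEM_DUP: STAGE_PARENTAL_DISTANCE,
    KIND_TE_DECOY: STAGE_TE_FRACTION,
    KIND_SHORT_FRAGMENT: STAGE_MATCH_LENGTH,
}


@dataclass(frozen=True)
class SimTruthRecord:
    """Ground truth for one planted insert in a simulated genome."""

    insert_id: str
    kind: str
    chrom: str
    start: int
    end: int
    parent_gene_id: str
    truncation_fraction: float
    mutation_rate: float
    polya_len: int
    expected_stage: str
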