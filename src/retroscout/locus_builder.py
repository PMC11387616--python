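"""Group surviving alignments into retrocopy loci and name them.

Grouping is single-linkage on genomic footprint overlap (>= 1 bp, same
chromosome, strand-agnostic): for intervals this reduces to one sorted
sweep, which is checked against a brute-force union-find oracle in the
test suite.  Each cluster becomes one locus spanning the union of member
footprints; the representative member is the one with the most matched
bases (ties: longer footprint, then lexicographically smaller transcript
id), and it supplies the locus strand and parental gene.

Naming follows the processed-pseudogene convention "parental gene name" +
"P" + number (e.g. GAPDHP1): loci are partitioned by parental gene name
(falling back to the gene id when the name is empty), sorted by
(chromosome, start), and numbered P1..Pn gap-free in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .datamodel import (
    STAGE_TE_FRACTION,
    RetrocopyCandidate,
    RetrocopyLocus,
)


def _candidate_key(c: RetrocopyCandidate) -> tuple:
    return c.chain.sort_key()


def _representative(members: Sequence[RetrocopyCandidate]) -> RetrocopyCandidate:
    def key(c: RetrocopyCandidate):
        fp = c.chain.footprint
        return (-c.chain.matches, -(fp[1] - fp[0]), c.parent.transcript_id)

    return min(members, key=key)


def _te_fraction_of(c: RetrocopyCandidate) -> Optional[float]:
    for t in c.trace:
        if t.stage == STAGE_TE_FRACTION:
            return t.value
    return None


def group_loci(
    candidates: Sequence[RetrocopyCandidate],
    min_overlap_bp: int = 1,
    per_gene: bool = False,
) -> list[RetrocopyLocus]:
    """Cluster candidates into loci by single-linkage footprint overlap.

    ``min_overlap_bp`` is the minimum shared bases for two footprints to
    be linked (default 1).  With ``per_gene`` set, candidates are
    partitioned by parental gene before clustering, so overlapping calls
    from different genes yield separate loci.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")

    def cluster_key(c: RetrocopyCandidate):
        if per_gene:
            return (c.parent.gene_id, c.chain.target_chrom)
        return (c.chain.target_chrom,)

    ordered = sorted(candidates, key=lambda c: (cluster_key(c),) + _candidate_key(c))
    clusters: list[list[RetrocopyCandidate]] = []
    cur: list[RetrocopyCandidate] = []
    cur_key = None
    cur_end = -1
    for c in ordered:
        fp = c.chain.footprint
        k = cluster_key(c)
        if cur and k == cur_key and fp[0] <= cur_end - min_overlap_bp:
            cur.append(c)
            cur_end = max(cur_end, fp[1])
        else:
            if cur:
                clusters.append(cur)
            cur = [c]
            cur_key = k
            cur_end = fp[1]
    if cur:
        clusters.append(cur)

    loci = []
    for members in clusters:
        rep = _representative(members)
        start = min(c.chain.footprint[0] for c in members)
        end = max(c.chain.footprint[1] for c in members)
        loci.append(
            RetrocopyLocus(
                locus_id="",  # assigned below after global ordering
                chrom=rep.chain.target_chrom,
                start=start,
                end=end,
                strand=rep.chain.target_strand,
                parental_gene_id=rep.parent.gene_id,
                parental_gene_name=rep.parent.gene_name,
                representative_transcript_id=rep.parent.transcript_id,
                members=tuple(members),
                matched_nt=rep.chain.matches,
                te_fraction=_te_fraction_of(rep),
                spanned_junctions=rep.spanned_junctions,
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.parental_gene_id))
    return [
        RetrocopyLocus(
            locus_id=f"locus_{i:06d}",
            chrom=l.chrom, start=l.start, end=l.end, strand=l.strand,
            parental_gene_id=l.parental_gene_id,
            parental_gene_name=l.parental_gene_name,
            representative_transcript_id=l.representative_transcript_id,
            members=l.members, matched_nt=l.matched_nt,
            te_fraction=l.te_fraction, spanned_junctions=l.spanned_junctions,
        )
        for i, l in enumerate(loci, 1)
    ]


def name_loci(loci: Sequence[RetrocopyLocus]) -> list[RetrocopyLocus]:
    """Assign P-numbered names per parental gene.

    Within each gene-name partition loci are sorted by (chromosome,
    start) and numbered P1..Pn; numbering is gap-free and deterministic,
    so re-running on the same catalog reproduces identical names.
    """
    by_name: dict[str, list[RetrocopyLocus]] = {}
    for locus in loci:
        key = locus.parental_gene_name or locus.parental_gene_id
        by_name.setdefault(key, []).append(locus)
    named = []
    for key in sorted(by_name):
        part = sorted(by_name[key], key=lambda l: (l.chrom, l.start, l.end))
        for i, locus in enumerate(part, 1):
            named.append(locus.with_name(f"{key}P{i}"))
    named.sort(key=lambda l: (l.chrom, l.start, l.name))
    return named


@dataclass(frozen=True)
class CatalogComparison:
    """Coordinate-based overlap accounting between two catalogs."""

    shared: int
    a_specific: int
    b_specific: int
    a_flags: tuple[bool, ...]  # per input locus: overlaps >=1 interval in b


def compare_catalogs(
    a: Sequence[RetrocopyLocus],
    b: Sequence[tuple[str, int, int]],
    min_overlap_bp: int = 1,
) -> CatalogComparison:
    """Flag each locus in ``a`` by whether it overlaps (half-open, >=
    ``min_overlap_bp`` shared bases) any interval in ``b``, and count
    shared / a-specific / b-specific entries."""
    flags = []
    b_hit = [False] * len(b)
    for locus in a:
        hit = False
        for i, (chrom, start, end) in enumerate(b):
            if chrom != locus.chrom:
                continue
            ov = min(locus.end, end) - max(locus.start, start)
            if ov >= min_overlap_bp:
                hit = True
                b_hit[i] = True
        flags.append(hit)
    shared = sum(flags)
    return CatalogComparison(
        shared=shared,
        a_specific=len(a) - shared,
        b_specific=b_hit.count(False),
        a_flags=tuple(flags),
    )
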