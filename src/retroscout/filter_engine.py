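"""The four-stage retrocopy filter cascade.

An alignment chain of a spliced transcript against the genome is kept as
a retrocopy candidate only if it

1. carries enough identical aligned bases to be trustworthy
   (``min_matched_nt``, stage ``match_length``);
2. lies outside the parental gene's neighbourhood, guarding against
   tandem duplications (``parental_exclusion_bp``, stage
   ``parental_distance``);
3. shows intron loss: an exon-exon junction of the parent, projected
   into query coordinates, falls inside a single contiguous aligned
   block with flanking aligned sequence on both sides — and specifically
   the 3'-most junction reachable by the alignment does, because
   L1-mediated retroduplication truncates the 5' end but preserves the
   3' end (stage ``junction``);
4. is not dominated by transposable-element sequence
   (``max_te_fraction``, stage ``te_fraction``).

A chain stops at its first failing stage; every verdict is recorded in a
:class:`~retroscout.datamodel.FilterTrace` so the cascade's behaviour is
fully auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .datamodel import (
    STAGE_JUNCTION,
    STAGE_MATCH_LENGTH,
    STAGE_PARENTAL_DISTANCE,
    STAGE_TE_FRACTION,
    AlignmentChain,
    FilterTrace,
    GeneLocus,
    PipelineConfig,
    RepeatIndex,
    RetrocopyCandidate,
    RetroscoutError,
    TranscriptModel,
    interval_gap,
)


def stage1_match_length(chain: AlignmentChain, config: PipelineConfig) -> FilterTrace:
    """Stage (i): keep chains with at least ``min_matched_nt`` identical
    aligned bases (inclusive boundary)."""
    return FilterTrace(
        stage=STAGE_MATCH_LENGTH,
        passed=chain.matches >= config.min_matched_nt,
        value=float(chain.matches),
    )


def parental_distance(chain: AlignmentChain, locus: GeneLocus) -> float:
    """Distance in bp between a chain's footprint and a gene locus.

    0 when they overlap; +inf on different chromosomes (a trans locus can
    never trigger the tandem-duplication exclusion).
    """
    if chain.target_chrom != locus.chrom:
        return math.inf
    return float(interval_gap(chain.footprint, locus.span))


def stage2_parental_exclusion(
    chain: AlignmentChain,
    parent_gene_loci: Sequence[GeneLocus],
    config: PipelineConfig,
) -> FilterTrace:
    """Stage (ii): exclude chains overlapping the parental gene locus or
    within ``parental_exclusion_bp`` of it ("up to" read as inclusive: a
    distance exactly equal to the window is still excluded)."""
    if not parent_gene_loci:
        raise RetroscoutError(
            f"chain {chain.query_id}: parental gene has no annotated locus"
        )
    dist = min(parental_distance(chain, locus) for locus in parent_gene_loci)
    return FilterTrace(
        stage=STAGE_PARENTAL_DISTANCE,
        passed=dist > config.parental_exclusion_bp,
        value=dist,
    )


def project_junctions(
    chain: AlignmentChain,
    parent: TranscriptModel,
    config: PipelineConfig,
) -> tuple[list[int], bool]:
    """Project the parent's exon-exon junctions onto the chain.

    A junction ``j`` (transcript coordinates) is *spanned* when one single
    block contains the query interval ``[j - flank, j + flank)``: the
    junction sits inside contiguous aligned sequence with at least
    ``flank`` aligned bases on each side, i.e. the intron is absent at
    that boundary.  A junction falling on a block boundary — the
    signature of a retained intron — is not spanned.

    ``three_prime_spanned`` is True when the 3'-most junction whose
    flanked interval lies within the chain's aligned query range is
    spanned; False when no junction is in range at all.
    """
    flank = config.junction_flank_nt
    junctions = parent.junctions
    if not junctions:
        return [], False
    spanned = [
        j for j in junctions
        if any(b.q_start <= j - flank and j + flank <= b.q_end for b in chain.blocks)
    ]
    qmin, qmax = chain.query_span
    in_range = [j for j in junctions if j - flank >= qmin and j + flank <= qmax]
    three_prime_spanned = bool(in_range) and in_range[-1] in spanned
    return spanned, three_prime_spanned


def stage3_intronless(
    chain: AlignmentChain,
    parent: TranscriptModel,
    config: PipelineConfig,
) -> tuple[FilterTrace, list[int], bool]:
    """Stage (iii): require the 3'-most reachable junction to be spanned
    and at least ``min_spanned_junctions`` junctions spanned overall.
    Single-exon parents can never pass (no junction to test)."""
    spanned, three_prime = project_junctions(chain, parent, config)
    passed = three_prime and len(spanned) >= config.min_spanned_junctions
    return (
        FilterTrace(stage=STAGE_JUNCTION, passed=passed, value=float(len(spanned))),
        spanned,
        three_prime,
    )


def te_fraction(chain: AlignmentChain, repeats: RepeatIndex) -> float:
    """Fraction of the chain's aligned target bases covered by countable
    transposable-element intervals.  Blocks never overlap in target, so
    the denominator is the summed block length."""
    total = chain.aligned_bases
    if total == 0:
        raise RetroscoutError(f"chain {chain.query_id}: zero aligned length")
    covered = sum(
        repeats.covered_bases(chain.target_chrom, b.t_start, b.t_end)
        for b in chain.blocks
    )
    return covered / total


def stage4_te_filter(
    chain: AlignmentChain,
    repeats: RepeatIndex,
    config: PipelineConfig,
) -> FilterTrace:
    """Stage (iv): remove chains composed of more than ``max_te_fraction``
    transposable elements (strict inequality: exactly at the threshold is
    retained)."""
    frac = te_fraction(chain, repeats)
    return FilterTrace(
        stage=STAGE_TE_FRACTION,
        passed=frac <= config.max_te_fraction,
        value=frac,
    )


@dataclass
class CascadeResult:
    """Outcome of running the cascade over a set of chains.

    ``report`` maps ``"input"`` and each stage name to the number of
    chains still alive after that stage, plus ``"single_exon_parents"``
    for chains whose parent transcript has no junction (rejected at the
    junction stage and tallied separately).
    """

    candidates: list[RetrocopyCandidate]
    rejections: list[tuple[AlignmentChain, tuple[FilterTrace, ...]]]
    report: dict[str, int] = field(default_factory=dict)


def run_cascade(
    chains: Iterable[AlignmentChain],
    transcripts: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
    gene_loci: Mapping[str, Sequence[GeneLocus]],
    repeats: Optional[RepeatIndex],
    config: PipelineConfig,
    te_filter: bool = True,
) -> CascadeResult:
    """Apply stages (i)-(iv) in order to every chain.

    A chain stops at its first failing stage.  The result is independent
    of the input chain order: chains are processed in a canonical sorted
    order.  ``repeats`` may be None only when ``te_filter`` is False, in
    which case stage (iv) is skipped and candidate TE fractions are
    undefined.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}
    if te_filter and repeats is None:
        raise RetroscoutError("TE filtering requested but no repeat annotation given")

    ordered = sorted(chains, key=AlignmentChain.sort_key)
    unresolved = sorted({c.query_id for c in ordered} - set(transcripts))
    if unresolved:
        raise RetroscoutError(
            "alignment query ids absent from the annotation: " + ", ".join(unresolved)
        )

    report = {"input": len(ordered), STAGE_MATCH_LENGTH: 0,
              STAGE_PARENTAL_DISTANCE: 0, STAGE_JUNCTION: 0,
              STAGE_TE_FRACTION: 0, "single_exon_parents": 0}
    candidates: list[RetrocopyCandidate] = []
    rejections: list[tuple[AlignmentChain, tuple[FilterTrace, ...]]] = []

    for chain in ordered:
        parent = transcripts[chain.query_id]
        trace: list[FilterTrace] = []

        t1 = stage1_match_length(chain, config)
        trace.append(t1)
        if not t1.passed:
            rejections.append((chain, tuple(trace)))
            continue
        report[STAGE_MATCH_LENGTH] += 1

        loci = gene_loci.get(parent.gene_id)
        if not loci:
            raise RetroscoutError(
                f"chain {chain.query_id}: no locus for gene {parent.gene_id}"
            )
        t2 = stage2_parental_exclusion(chain, loci, config)
        trace.append(t2)
        if not t2.passed:
            rejections.append((chain, tuple(trace)))
            continue
        report[STAGE_PARENTAL_DISTANCE] += 1

        if parent.is_single_exon:
            report["single_exon_parents"] += 1
        t3, spanned, three_prime = stage3_intronless(chain, parent, config)
        trace.append(t3)
        if not t3.passed:
            rejections.append((chain, tuple(trace)))
            continue
        report[STAGE_JUNCTION] += 1

        te_value: Optional[float] = None
        if te_filter:
            t4 = stage4_te_filter(chain, repeats, config)
            trace.append(t4)
            if not t4.passed:
                rejections.append((chain, tuple(trace)))
                continue
        report[STAGE_TE_FRACTION] += 1

        candidates.append(
            RetrocopyCandidate(
                chain=chain,
                parent=parent,
                trace=tuple(trace),
                spanned_junctions=len(spanned),
                three_prime_junction_spanned=three_prime,
            )
        )

    return CascadeResult(candidates=candidates, rejections=rejections, report=report)
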