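"""Score a detected retrocopy catalog against simulator ground truth.

A detected locus is a true positive when it overlaps (>= 1 bp, same
chromosome) a planted retrocopy; each planted retrocopy is matched at
most once, greedily by descending overlap.  Decoy inserts are
cross-tabulated against the cascade stage that actually rejected their
alignment, which turns the designed behaviour of each filter into an
assertable contract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .datamodel import (
    KIND_RETROCOPY,
    AlignmentChain,
    FilterTrace,
    RetrocopyLocus,
    SimTruthRecord,
)

Rejection = tuple[AlignmentChain, tuple[FilterTrace, ...]]


@dataclass(frozen=True)
class RejectionRecord:
    """File-friendly summary of one rejected chain: its footprint and the
    first cascade stage it failed."""

    query_id: str
    chrom: str
    start: int
    end: int
    failing_stage: str


def _as_rejection_record(r: "Rejection | RejectionRecord") -> RejectionRecord:
    if isinstance(r, RejectionRecord):
        return r
    chain, trace = r
    fp = chain.footprint
    failing = next((t.stage for t in trace if not t.passed), "none")
    return RejectionRecord(chain.query_id, chain.target_chrom, fp[0], fp[1], failing)


@dataclass
class DecoyCounts:
    rejected_expected_stage: int = 0
    rejected_other_stage: int = 0
    called: int = 0
    unaligned: int = 0


@dataclass
class EvalReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    n_truth_retrocopies: int
    n_loci: int
    decoy_table: dict[str, DecoyCounts] = field(default_factory=dict)
    locus_matched: dict[str, bool] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"loci detected      {self.n_loci}",
            f"truth retrocopies  {self.n_truth_retrocopies}",
            f"true positives     {self.true_positives}",
            f"false positives    {self.false_positives}",
            f"false negatives    {self.false_negatives}",
            f"precision          {self.precision:.4f}",
            f"recall             {self.recall:.4f}",
            f"F1                 {self.f1:.4f}",
        ]
        if self.decoy_table:
            lines.append("decoy rejection by stage (expected/other/called/unaligned):")
            for kind in sorted(self.decoy_table):
                c = self.decoy_table[kind]
                lines.append(
                    f"  {kind:<16} {c.rejected_expected_stage}/"
                    f"{c.rejected_other_stage}/{c.called}/{c.unaligned}"
                )
        return "\n".join(lines)


def _ratio(num: int, den: int) -> float:
    """num/den with the 0/0 -> 1 convention (vacuous success)."""
    return 1.0 if den == 0 else num / den


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def match_to_truth(
    loci: Sequence[RetrocopyLocus],
    truth: Sequence[SimTruthRecord],
    rejections: Optional[Sequence["Rejection | RejectionRecord"]] = None,
) -> EvalReport:
    """Compare detected loci with planted truth.

    ``rejections`` — chains eliminated by the cascade together with their
    filter traces — enables the per-decoy stage attribution; without it
    the decoy table only reports erroneously called decoys.
    The report is invariant to the input order of loci and truth records.
    """
    loci_sorted = sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.name or ""))
    truth_sorted = sorted(truth, key=lambda t: t.insert_id)
    retro = [t for t in truth_sorted if t.kind == KIND_RETROCOPY]
    decoys = [t for t in truth_sorted if t.kind != KIND_RETROCOPY]

    # greedy one-to-one matching by descending overlap
    pairs = []
    for li, locus in enumerate(loci_sorted):
        for ti, rec in enumerate(retro):
            if rec.chrom != locus.chrom:
                continue
            ov = _overlap(locus.start, locus.end, rec.start, rec.end)
            if ov > 0:
                pairs.append((-ov, li, ti))
    pairs.sort()
    locus_taken = [False] * len(loci_sorted)
    truth_taken = [False] * len(retro)
    tp = 0
    for _negov, li, ti in pairs:
        if locus_taken[li] or truth_taken[ti]:
            continue
        locus_taken[li] = truth_taken[ti] = True
        tp += 1
    fp = len(loci_sorted) - tp
    fn = len(retro) - tp
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)

    decoy_table: dict[str, DecoyCounts] = {}
    rej_records = sorted(
        (_as_rejection_record(r) for r in (rejections or [])),
        key=lambda r: (r.chrom, r.start, r.end, r.query_id, r.failing_stage),
    )
    for rec in decoys:
        counts = decoy_table.setdefault(rec.kind, DecoyCounts())
        called = any(
            l.chrom == rec.chrom and _overlap(l.start, l.end, rec.start, rec.end) > 0
            for l in loci_sorted
        )
        if called:
            counts.called += 1
            continue
        best: Optional[RejectionRecord] = None
        best_ov = 0
        for rej in rej_records:
            if rej.chrom != rec.chrom:
                continue
            ov = _overlap(rej.start, rej.end, rec.start, rec.end)
            if ov > best_ov:
                best, best_ov = rej, ov
        if best is None:
            counts.unaligned += 1
            continue
        if best.failing_stage == rec.expected_stage:
            counts.rejected_expected_stage += 1
        else:
            counts.rejected_other_stage += 1

    return EvalReport(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        n_truth_retrocopies=len(retro),
        n_loci=len(loci_sorted),
        decoy_table=decoy_table,
        locus_matched={
            (l.name or getattr(l, "locus_id", "") or f"locus#{i}"): locus_taken[i]
            for i, l in enumerate(loci_sorted)
        },
    )


REJECTION_COLUMNS = ["query_id", "chrom", "start", "end", "failing_stage"]


def write_rejections(
    rejections: Sequence["Rejection | RejectionRecord"], path: str | Path
) -> None:
    records = sorted(
        (_as_rejection_record(r) for r in rejections),
        key=lambda r: (r.chrom, r.start, r.end, r.query_id, r.failing_stage),
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REJECTION_COLUMNS)
        for r in records:
            w.writerow([r.query_id, r.chrom, r.start, r.end, r.failing_stage])


def read_rejections(path: str | Path) -> list[RejectionRecord]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            out.append(RejectionRecord(
                query_id=rec["query_id"], chrom=rec["chrom"],
                start=int(rec["start"]), end=int(rec["end"]),
                failing_stage=rec["failing_stage"],
            ))
    return out


def write_eval_report(report: EvalReport, path: str | Path) -> None:
    """Serialise the report as a two-section TSV (metrics, decoy table)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["metric", "value"])
        w.writerow(["n_loci", report.n_loci])
        w.writerow(["n_truth_retrocopies", report.n_truth_retrocopies])
        w.writerow(["true_positives", report.true_positives])
        w.writerow(["false_positives", report.false_positives])
        w.writerow(["false_negatives", report.false_negatives])
        w.writerow(["precision", f"{report.precision:.6f}"])
        w.writerow(["recall", f"{report.recall:.6f}"])
        w.writerow(["f1", f"{report.f1:.6f}"])
        w.writerow([])
        w.writerow(["decoy_kind", "rejected_expected_stage", "rejected_other_stage",
                    "called", "unaligned"])
        for kind in sorted(report.decoy_table):
            c = report.decoy_table[kind]
            w.writerow([kind, c.rejected_expected_stage, c.rejected_other_stage,
                        c.called, c.unaligned])
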