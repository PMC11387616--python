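"""Readers and writers for the standard formats the pipeline touches.

All conversions between file coordinate conventions (1-based closed
GTF/GFF3, 0-based BED/PSL) and the internal 0-based half-open convention
happen here and nowhere else.  Output writers are fully deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import logging
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO

from .datamodel import (
    DEFAULT_COUNTABLE_CLASSES,
    AlignmentChain,
    AnnotationError,
    ChainError,
    CoordinateError,
    GenomeSequence,
    RepeatIndex,
    RepeatInterval,
    RetrocopyLocus,
    RetroscoutError,
    SimTruthRecord,
    TranscriptModel,
    from_one_based,
    normalize_chain,
    to_one_based,
)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(RetroscoutError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into a dict keyed by sequence id.

    The header token before the first whitespace is the id; residues are
    uppercased and U is normalised to T.  Duplicate ids and empty files
    are errors.
    """
    out: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id
        if seq_id in out:
            raise FormatError(f"duplicate sequence id {seq_id!r} in {path}")
        residues = str(rec.seq).upper().replace("U", "T")
        out[seq_id] = GenomeSequence(seq_id=seq_id, residues=residues)
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF3 annotation

def _prevalidate_annotation(path: str | Path) -> None:
    """Cheap line-level checks that produce errors with line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationError(f"{path}:{lineno}: fewer than 8 columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise AnnotationError(f"{path}:{lineno}: end < start")
            if fields[2] == "exon" and fields[6] not in ("+", "-"):
                raise AnnotationError(
                    f"{path}:{lineno}: unknown strand symbol {fields[6]!r}"
                )


def read_annotation(
    path: str | Path,
    stats: Optional[dict] = None,
) -> list[TranscriptModel]:
    """Read transcript models from a GTF or GFF3 file.

    Exon features are grouped by transcript (GTF ``transcript_id``
    attribute, or GFF3 ``Parent``), converted to 0-based half-open
    coordinates.  Transcripts carrying no exon feature (e.g. CDS-only
    records) are dropped; the drop count is logged and, if a ``stats``
    dict is supplied, recorded under ``"dropped_no_exons"``.
    """
    _prevalidate_annotation(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons_by_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gid, gname, chrom, strand)
    tx_refs: set[str] = set()

    def gff3_gene_info(tid: str) -> tuple[str, str]:
        try:
            tx = db[tid]
        except gffutils.FeatureNotFoundError:
            return tid, tid
        parents = tx.attributes.get("Parent", [])
        if not parents:
            return tid, tid
        gid = parents[0]
        try:
            gene = db[gid]
        except gffutils.FeatureNotFoundError:
            return gid, gid
        gname = gene.attributes.get("gene_name", gene.attributes.get("Name", [gid]))[0]
        return gid, gname

    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype in ("transcript", "mRNA"):
            tx_refs.add(feat.id)
            continue
        if ftype == "gene":
            continue
        attrs = feat.attributes
        if "transcript_id" in attrs:
            tid = attrs["transcript_id"][0]
        elif "Parent" in attrs:
            tid = attrs["Parent"][0]
        else:
            continue
        tx_refs.add(tid)
        if ftype != "exon":
            continue
        exons_by_tx.setdefault(tid, []).append(feat)
        if tid not in tx_meta:
            if "gene_id" in attrs:  # GTF dialect
                gid = attrs["gene_id"][0]
                gname = attrs.get("gene_name", [gid])[0]
            else:  # GFF3 dialect: walk Parent links
                gid, gname = gff3_gene_info(tid)
            tx_meta[tid] = (gid, gname, feat.seqid, feat.strand)

    dropped = len(tx_refs - set(exons_by_tx))
    if dropped:
        log.warning("%s: %d transcript(s) without exon features dropped", path, dropped)
    if stats is not None:
        stats["dropped_no_exons"] = dropped

    transcripts = []
    for tid in sorted(exons_by_tx):
        gid, gname, chrom, strand = tx_meta[tid]
        exons = sorted(from_one_based(f.start, f.end) for f in exons_by_tx[tid])
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_name=gname or gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )
    return transcripts


def _gtf_attrs(gid: str, tid: Optional[str], gname: str) -> str:
    parts = [f'gene_id "{gid}";']
    if tid is not None:
        parts.append(f'transcript_id "{tid}";')
    parts.append(f'gene_name "{gname}";')
    return " ".join(parts)


def write_annotation_gtf(transcripts: Sequence[TranscriptModel],
                         path: str | Path, source: str = "retroscout") -> None:
    """Write transcripts as GTF (gene, transcript and exon lines)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.span, t.transcript_id)):
            g1, g2 = to_one_based(*t.span)
            fh.write("\t".join([t.chrom, source, "transcript", str(g1), str(g2),
                                ".", t.strand, ".",
                                _gtf_attrs(t.gene_id, t.transcript_id, t.gene_name)]) + "\n")
            for s, e in t.exons:
                o1, o2 = to_one_based(s, e)
                fh.write("\t".join([t.chrom, source, "exon", str(o1), str(o2),
                                    ".", t.strand, ".",
                                    _gtf_attrs(t.gene_id, t.transcript_id, t.gene_name)]) + "\n")


def write_annotation_gff3(transcripts: Sequence[TranscriptModel],
                          path: str | Path, source: str = "retroscout") -> None:
    """Write transcripts as GFF3 (gene > mRNA > exon hierarchy)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(by_gene):
            txs = sorted(by_gene[gid], key=lambda t: (t.chrom, t.span, t.transcript_id))
            g1, _ = to_one_based(min(t.span[0] for t in txs), max(t.span[1] for t in txs))
            _, g2 = to_one_based(min(t.span[0] for t in txs), max(t.span[1] for t in txs))
            first = txs[0]
            fh.write("\t".join([first.chrom, source, "gene", str(g1), str(g2), ".",
                                first.strand, ".",
                                f"ID={gid};Name={first.gene_name}"]) + "\n")
            for t in txs:
                t1, t2 = to_one_based(*t.span)
                fh.write("\t".join([t.chrom, source, "mRNA", str(t1), str(t2), ".",
                                    t.strand, ".",
                                    f"ID={t.transcript_id};Parent={gid}"]) + "\n")
                for i, (s, e) in enumerate(t.exons, 1):
                    o1, o2 = to_one_based(s, e)
                    fh.write("\t".join([t.chrom, source, "exon", str(o1), str(o2), ".",
                                        t.strand, ".",
                                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]) + "\n")


# ---------------------------------------------------------------------------
# repeats (BED or RepeatMasker .out)

def classify_repeat(label: str) -> str:
    """Map a class/family string ("LINE/L1", "Simple_repeat", ...) to one
    of the coarse repeat classes.  Anything unrecognised — including
    simple repeats, low-complexity runs and satellites — maps to Other,
    which is never counted as TE."""
    prefix = label.split("/", 1)[0].rstrip("?").strip()
    for cls in ("LINE", "SINE", "LTR", "DNA", "Retroposon"):
        if prefix.lower() == cls.lower():
            return cls
    return "Other"


def read_repeats(
    path: str | Path,
    countable_classes: frozenset[str] = DEFAULT_COUNTABLE_CLASSES,
    fmt: str = "auto",
) -> RepeatIndex:
    """Read repeat annotation from BED (chrom,start,end[,class/family]) or
    RepeatMasker .out.  Format is chosen by extension (``.out``) unless
    forced via ``fmt``."""
    path = Path(path)
    if fmt == "auto":
        fmt = "rmout" if path.suffix == ".out" else "bed"
    intervals: list[RepeatInterval] = []
    with open(path) as fh:
        if fmt == "bed":
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: BED line with <3 fields")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer BED coordinate") from exc
                label = fields[3] if len(fields) > 3 else "Other"
                intervals.append(
                    RepeatInterval(fields[0], start, end, classify_repeat(label), label)
                )
        elif fmt == "rmout":
            for lineno, line in enumerate(fh, 1):
                fields = line.split()
                if not fields:
                    continue
                try:
                    int(fields[0])
                except ValueError:
                    if lineno <= 3:  # banner/header lines
                        continue
                    raise FormatError(f"{path}:{lineno}: unparseable RepeatMasker line")
                if len(fields) < 11:
                    raise FormatError(f"{path}:{lineno}: too few RepeatMasker columns")
                try:
                    start, end = from_one_based(int(fields[5]), int(fields[6]))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
                label = fields[10]
                intervals.append(
                    RepeatInterval(fields[4], start, end, classify_repeat(label), label)
                )
        else:
            raise ValueError(f"unknown repeat format {fmt!r}")
    return RepeatIndex(intervals, countable_classes)


def write_repeats_bed(intervals: Sequence[RepeatInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# alignments (PSL / PAF)

_PSL_HEADER_PREFIXES = ("psLayout", "match", "-", " ")


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def _chain_from_psl(fields: list[str], where: str) -> AlignmentChain:
    (matches, _mis, _rep, _nc, _qni, _qbi, _tni, _tbi, strand, qname, qsize,
     qstart, qend, tname, tsize, tstart, tend, blockcount, bsizes, qstarts,
     tstarts) = fields[:21]
    if strand not in ("+", "-"):
        raise FormatError(f"{where}: unsupported PSL strand {strand!r}")
    qsize_i, tsize_i = int(qsize), int(tsize)
    sizes = _parse_int_list(bsizes)
    qss = _parse_int_list(qstarts)
    tss = _parse_int_list(tstarts)
    if not (len(sizes) == len(qss) == len(tss) == int(blockcount)):
        raise ChainError(f"{where} ({qname}): block list lengths disagree")
    blocks = []
    for bs, qs, ts in zip(sizes, qss, tss):
        if strand == "-":
            # PSL stores minus-strand qStarts in reverse-complement query
            # coordinates; unreflect to query-forward.
            q0, q1 = qsize_i - (qs + bs), qsize_i - qs
        else:
            q0, q1 = qs, qs + bs
        blocks.append((q0, q1, ts, ts + bs))
    qmin = min(b[0] for b in blocks)
    qmax = max(b[1] for b in blocks)
    tmin = min(b[2] for b in blocks)
    tmax = max(b[3] for b in blocks)
    if (qmin, qmax) != (int(qstart), int(qend)) or (tmin, tmax) != (int(tstart), int(tend)):
        raise ChainError(f"{where} ({qname}): block extent disagrees with qStart/qEnd/tStart/tEnd")
    try:
        return normalize_chain(qname, qsize_i, tname, tsize_i, strand, blocks, int(matches))
    except ChainError as exc:
        raise ChainError(f"{where}: {exc}") from exc


def _expand_cigar(cg: str) -> list[tuple[int, str]]:
    ops, num = [], ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise FormatError(f"malformed CIGAR {cg!r}")
            ops.append((int(num), ch))
            num = ""
    if num:
        raise FormatError(f"malformed CIGAR {cg!r}")
    return ops


def _chain_from_paf(fields: list[str], where: str) -> AlignmentChain:
    qname, qlen, qstart, qend, strand, tname, tlen, tstart, tend, nmatch = fields[:10]
    cg = None
    for tag in fields[12:]:
        if tag.startswith("cg:Z:"):
            cg = tag[5:]
            break
    if cg is None:
        raise FormatError(
            f"{where} ({qname}): PAF record lacks a cg:Z: CIGAR tag; rerun the "
            "aligner with CIGAR output (e.g. minimap2 -c)"
        )
    qlen_i, tlen_i = int(qlen), int(tlen)
    # CIGAR walks the target forward; query coordinates are walked in the
    # alignment orientation (reverse-complement frame when strand is '-').
    qpos = int(qstart) if strand == "+" else qlen_i - int(qend)
    tpos = int(tstart)
    blocks_aln = []  # in alignment-orientation query coords
    for n, op in _expand_cigar(cg):
        if op in ("M", "=", "X"):
            blocks_aln.append((qpos, qpos + n, tpos, tpos + n))
            qpos += n
            tpos += n
        elif op == "I":
            qpos += n
        elif op in ("D", "N"):
            tpos += n
        else:
            raise FormatError(f"{where} ({qname}): unsupported CIGAR op {op!r}")
    q_expect = int(qend) if strand == "+" else qlen_i - int(qstart)
    if qpos != q_expect or tpos != int(tend):
        raise ChainError(f"{where} ({qname}): CIGAR walk disagrees with coordinates")
    if strand == "-":
        blocks = [(qlen_i - q1, qlen_i - q0, t0, t1) for q0, q1, t0, t1 in blocks_aln]
    else:
        blocks = blocks_aln
    try:
        return normalize_chain(qname, qlen_i, tname, tlen_i, strand, blocks, int(nmatch))
    except ChainError as exc:
        raise ChainError(f"{where}: {exc}") from exc


def read_alignments(path: str | Path) -> list[AlignmentChain]:
    """Read transcript-to-genome alignments from PSL (21-column) or PAF
    (requires the cg:Z: CIGAR tag for block structure)."""
    chains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            where = f"{path}:{lineno}"
            if len(fields) >= 21 and fields[8] in ("+", "-") and fields[0].isdigit():
                chains.append(_chain_from_psl(fields, where))
            elif len(fields) >= 12 and fields[4] in ("+", "-") and fields[1].isdigit():
                chains.append(_chain_from_paf(fields, where))
            elif line.startswith(_PSL_HEADER_PREFIXES):
                continue  # psLayout header block
            else:
                raise FormatError(f"{where}: not a recognisable PSL or PAF record")
    return chains


def psl_record(chain: AlignmentChain) -> str:
    """Serialise one chain as a 21-column PSL line."""
    blocks = list(chain.blocks)
    total = chain.aligned_bases
    qmin, qmax = chain.query_span if chain.target_strand == "+" else (
        min(b.q_start for b in blocks), max(b.q_end for b in blocks))
    fp = chain.footprint
    # gap statistics on PSL-ordered blocks (target-forward order)
    psl_blocks = blocks if chain.target_strand == "+" else list(reversed(blocks))
    qni = qbi = tni = tbi = 0
    for prev, cur in zip(psl_blocks, psl_blocks[1:]):
        if chain.target_strand == "+":
            qgap = cur.q_start - prev.q_end
        else:
            qgap = prev.q_start - cur.q_end  # forward-frame gap, reversed order
        tgap = cur.t_start - prev.t_end
        if qgap > 0:
            qni += 1
            qbi += qgap
        if tgap > 0:
            tni += 1
            tbi += tgap
    sizes = [b.q_end - b.q_start for b in psl_blocks]
    if chain.target_strand == "-":
        qstarts = [chain.query_length - b.q_end for b in psl_blocks]
    else:
        qstarts = [b.q_start for b in psl_blocks]
    tstarts = [b.t_start for b in psl_blocks]
    fields = [
        chain.matches, total - chain.matches, 0, 0, qni, qbi, tni, tbi,
        chain.target_strand, chain.query_id, chain.query_length, qmin, qmax,
        chain.target_chrom, chain.target_length, fp[0], fp[1], len(blocks),
        ",".join(map(str, sizes)) + ",",
        ",".join(map(str, qstarts)) + ",",
        ",".join(map(str, tstarts)) + ",",
    ]
    return "\t".join(map(str, fields))


def write_psl(chains: Sequence[AlignmentChain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(psl_record(chain) + "\n")


# ---------------------------------------------------------------------------
# catalog output

CATALOG_COLUMNS = [
    "name", "chrom", "start", "end", "strand", "parental_gene_name",
    "parental_gene_id", "representative_transcript_id", "matched_nt",
    "te_fraction", "spanned_junctions", "n_members",
]


@dataclass(frozen=True)
class CatalogRow:
    """Flat, lossless summary of one retrocopy locus for tabular output."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    parental_gene_name: str
    parental_gene_id: str
    representative_transcript_id: str
    matched_nt: int
    te_fraction: Optional[float]
    spanned_junctions: int
    n_members: int


def _locus_row(locus: RetrocopyLocus) -> CatalogRow:
    if locus.name is None:
        raise RetroscoutError(f"locus {locus.locus_id} is unnamed; run name_loci first")
    return CatalogRow(
        name=locus.name,
        chrom=locus.chrom,
        start=locus.start,
        end=locus.end,
        strand=locus.strand,
        parental_gene_name=locus.parental_gene_name,
        parental_gene_id=locus.parental_gene_id,
        representative_transcript_id=locus.representative_transcript_id,
        matched_nt=locus.matched_nt,
        te_fraction=locus.te_fraction,
        spanned_junctions=locus.spanned_junctions,
        n_members=len(locus.members),
    )


def _fmt_te(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.4f}"


def write_catalog(loci: Sequence[RetrocopyLocus], out_prefix: str | Path) -> dict[str, Path]:
    """Write the catalog as BED6, GFF3 and TSV with deterministic row
    order (chrom, start, name).  Returns the paths written."""
    rows = sorted((_locus_row(l) for l in loci),
                  key=lambda r: (r.chrom, r.start, r.name))
    out_prefix = Path(out_prefix)
    bed_path = out_prefix.with_suffix(".bed")
    gff_path = out_prefix.with_suffix(".gff3")
    tsv_path = out_prefix.with_suffix(".tsv")
    with open(bed_path, "w") as fh:
        for r in rows:
            score = min(r.matched_nt, 1000)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            s1, e1 = to_one_based(r.start, r.end)
            attrs = (
                f"ID={r.name};Name={r.name};parent_gene={r.parental_gene_name};"
                f"parent_gene_id={r.parental_gene_id};"
                f"representative_transcript={r.representative_transcript_id};"
                f"matched_nt={r.matched_nt};te_fraction={_fmt_te(r.te_fraction)};"
                f"spanned_junctions={r.spanned_junctions};n_members={r.n_members}"
            )
            fh.write("\t".join([r.chrom, "retroscout", "processed_pseudogene",
                                str(s1), str(e1), ".", r.strand, ".", attrs]) + "\n")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_COLUMNS)
        for r in rows:
            writer.writerow([
                r.name, r.chrom, r.start, r.end, r.strand, r.parental_gene_name,
                r.parental_gene_id, r.representative_transcript_id, r.matched_nt,
                _fmt_te(r.te_fraction), r.spanned_junctions, r.n_members,
            ])
    return {"bed": bed_path, "gff3": gff_path, "tsv": tsv_path}


def read_catalog(path: str | Path) -> list[CatalogRow]:
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(CATALOG_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: catalog TSV missing columns {sorted(missing)}")
        for rec in reader:
            rows.append(CatalogRow(
                name=rec["name"],
                chrom=rec["chrom"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                strand=rec["strand"],
                parental_gene_name=rec["parental_gene_name"],
                parental_gene_id=rec["parental_gene_id"],
                representative_transcript_id=rec["representative_transcript_id"],
                matched_nt=int(rec["matched_nt"]),
                te_fraction=None if rec["te_fraction"] == "NA" else float(rec["te_fraction"]),
                spanned_junctions=int(rec["spanned_junctions"]),
                n_members=int(rec["n_members"]),
            ))
    return rows


def extract_sequences(
    loci: Sequence[RetrocopyLocus | CatalogRow],
    genome: dict[str, GenomeSequence],
) -> list[tuple[str, str]]:
    """Genomic footprint sequence of each locus, reverse-complemented for
    minus-strand loci; headers are the retrocopy names."""
    out = []
    for locus in sorted(loci, key=lambda l: (l.chrom, l.start, l.name or "")):
        name = locus.name
        if name is None:
            raise RetroscoutError("cannot extract sequence for an unnamed locus")
        if locus.chrom not in genome:
            raise RetroscoutError(f"locus {name}: chromosome {locus.chrom} not in genome")
        chrom_seq = genome[locus.chrom]
        if locus.end > chrom_seq.length or locus.start < 0:
            raise CoordinateError(
                f"locus {name} ({locus.start}-{locus.end}) exceeds "
                f"{chrom_seq.seq_id} length {chrom_seq.length}"
            )
        seq = chrom_seq.residues[locus.start:locus.end]
        if locus.strand == "-":
            seq = reverse_complement(seq)
        out.append((name, seq))
    return out


# ---------------------------------------------------------------------------
# simulation truth TSV

TRUTH_COLUMNS = [
    "insert_id", "kind", "chrom", "start", "end", "parent_gene_id",
    "truncation_fraction", "mutation_rate", "polya_len", "expected_stage",
]


def write_truth(records: Sequence[SimTruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for r in sorted(records, key=lambda r: r.insert_id):
            writer.writerow([
                r.insert_id, r.kind, r.chrom, r.start, r.end, r.parent_gene_id,
                f"{r.truncation_fraction:.6f}", f"{r.mutation_rate:.6f}",
                r.polya_len, r.expected_stage,
            ])


def read_truth(path: str | Path) -> list[SimTruthRecord]:
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TRUTH_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: truth TSV missing columns {sorted(missing)}")
        for rec in reader:
            records.append(SimTruthRecord(
                insert_id=rec["insert_id"],
                kind=rec["kind"],
                chrom=rec["chrom"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                parent_gene_id=rec["parent_gene_id"],
                truncation_fraction=float(rec["truncation_fraction"]),
                mutation_rate=float(rec["mutation_rate"]),
                polya_len=int(rec["polya_len"]),
                expected_stage=rec["expected_stage"],
            ))
    return records


# ---------------------------------------------------------------------------
# optional external-aligner adapter (untested plumbing)

def align_external(command: str, transcripts_fasta: str | Path,
                   genome_fasta: str | Path, out_path: str | Path) -> None:
    """Shell out to an external aligner producing PSL or PAF.

    ``command`` is a template with ``{query}``, ``{target}`` and ``{out}``
    placeholders, e.g. ``"minimap2 -cx splice {target} {query} > {out}"``.
    This is a convenience hook only: the pipeline itself consumes
    alignment files and never requires an aligner on PATH.
    """
    cmd = command.format(query=str(transcripts_fasta), target=str(genome_fasta),
                         out=str(out_path))
    subprocess.run(cmd, shell=True, check=True)
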