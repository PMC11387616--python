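"""Seeded synthetic genomes with planted retrocopies and decoy classes.

The generator emulates, on a random background genome, the event classes
the filter cascade is designed to separate:

* multi-exon genes with introns (the parental loci);
* retrocopies: a random gene's spliced mRNA, optionally 5'-truncated,
  carrying point substitutions and a 3' poly-A tract, inserted far from
  the parent on a random strand;
* tandem duplications: a full genomic copy of a gene — introns included —
  placed close to the parent (the classic false-positive class);
* TE decoys: spliced-mRNA inserts whose footprint is annotated as
  transposable element over most of its length;
* short fragments: spliced fragments below the match-length threshold.

Alignments are emitted by bookkeeping, not by running an aligner: for
every planted insert the generator knows exactly which transcript bases
map where and how many were substituted, so the "ideal" PSL it writes is
exact and the whole test suite stays hermetic.  Substitutions always
change the base, so ``matches = aligned length - substitutions`` holds
with no approximation.

Every sampled quantity comes from one seeded generator consumed in a
fixed order, making the entire scene byte-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from . import io_formats
from .datamodel import (
    EXPECTED_REJECTING_STAGE,
    KIND_RETROCOPY,
    KIND_SHORT_FRAGMENT,
    KIND_TANDEM_DUP,
    KIND_TE_DECOY,
    AlignmentChain,
    GenomeSequence,
    RepeatIndex,
    RepeatInterval,
    RetroscoutError,
    SimTruthRecord,
    TranscriptModel,
    normalize_chain,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: aligned bases kept on each side of a junction by the truncation clamp,
#: comfortably above the default junction flank of 10
_JUNCTION_SAFETY = 20
#: minimum aligned mRNA length a planted retrocopy retains, comfortably
#: above the default match threshold of 120 even after substitutions
_MIN_ALIGNED = 150
#: spacing kept between planted elements so loci never merge by accident
_PAD = 200


class SimulationError(RetroscoutError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters; ranges are inclusive (low, high) bounds."""

    seed: int = 0
    genome_length: int = 1_000_000
    chrom_name: str = "chrSim"
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (500, 5000)
    n_retrocopies: int = 20
    truncation_prob: float = 0.3
    truncation_fraction: tuple[float, float] = (0.1, 0.5)
    mutation_rate: float = 0.02
    polya_len: tuple[int, int] = (10, 30)
    n_tandem_dups: int = 5
    tandem_offset: int = 50_000
    n_te_decoys: int = 5
    te_decoy_coverage: float = 0.6
    n_short_fragments: int = 5
    short_fragment_len: int = 80
    min_insert_distance_from_parent: int = 250_000
    background_te_density: float = 0.10

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_retrocopies, self.n_tandem_dups,
                  self.n_te_decoys, self.n_short_fragments)
        if min(counts) < 0:
            raise SimulationError("element counts must be non-negative")
        if self.n_genes == 0 and sum(counts[1:]) > 0:
            raise SimulationError("inserts need at least one gene to copy from")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise SimulationError("mutation_rate must lie in [0, 1)")


@dataclass
class Scene:
    """An in-memory simulated study: genome, annotation, repeats, ideal
    alignments and ground truth."""

    config: SimConfig
    genome: dict[str, GenomeSequence]
    transcripts: list[TranscriptModel]
    transcript_seqs: dict[str, str]
    repeat_intervals: list[RepeatInterval]
    chains: list[AlignmentChain]
    truth: list[SimTruthRecord]

    @property
    def repeats(self) -> RepeatIndex:
        return RepeatIndex(self.repeat_intervals)


def splice(transcript: TranscriptModel, genome: dict[str, GenomeSequence]) -> str:
    """Spliced mRNA sequence of a transcript: exon sequences concatenated
    in transcript order (reverse-complemented for minus-strand genes)."""
    chrom = genome[transcript.chrom]
    seq = "".join(chrom.residues[s:e] for s, e in transcript.exons)
    if transcript.strand == "-":
        seq = io_formats.reverse_complement(seq)
    return seq


def _splice_idx(exons, strand, base_idx: np.ndarray) -> np.ndarray:
    parts = [base_idx[s:e] for s, e in exons]
    mrna = np.concatenate(parts) if parts else np.empty(0, dtype=base_idx.dtype)
    if strand == "-":
        mrna = 3 - mrna[::-1]
    return mrna


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


class _Placer:
    """Rejection-sampling placement of non-overlapping elements."""

    def __init__(self, rng: np.random.Generator, genome_length: int):
        self.rng = rng
        self.L = genome_length
        self.occupied: list[tuple[int, int]] = []

    def is_free(self, start: int, end: int) -> bool:
        if start < 0 or end > self.L:
            return False
        return all(end + _PAD <= s or e + _PAD <= start for s, e in self.occupied)

    def claim(self, start: int, end: int) -> None:
        self.occupied.append((start, end))

    def place(self, length: int, accept, attempts: int = 4000) -> int:
        """Sample a start position for an element of ``length`` bp until
        ``accept(start)`` holds and the slot is free."""
        if length >= self.L:
            raise SimulationError("element longer than genome; increase genome_length")
        for _ in range(attempts):
            start = int(self.rng.integers(0, self.L - length))
            if self.is_free(start, start + length) and accept(start):
                self.claim(start, start + length)
                return start
        raise SimulationError(
            "could not place a simulated element without overlap; "
            "increase genome_length or reduce element counts"
        )


@dataclass
class _GeneSpec:
    index: int
    gene_id: str
    transcript_id: str
    gene_name: str
    strand: str
    start: int = 0
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def simulate_scene(config: SimConfig) -> Scene:
    """Generate a complete scene from a seeded configuration."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    chrom = config.chrom_name
    base_idx = rng.integers(0, 4, size=L, dtype=np.uint8)
    placer = _Placer(rng, L)

    # ---- genes ------------------------------------------------------
    genes: list[_GeneSpec] = []
    transcripts: list[TranscriptModel] = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        in_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1,
                               max(0, n_ex - 1))
        glen = int(ex_lens.sum() + in_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        start = placer.place(glen, accept=lambda s: True)
        exons = []
        pos = start
        for i, el in enumerate(ex_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(in_lens):
                pos += int(in_lens[i])
        spec = _GeneSpec(
            index=gi,
            gene_id=f"G{gi:03d}",
            transcript_id=f"T{gi:03d}.1",
            gene_name=f"GENE{gi + 1}",
            strand=strand,
            start=start,
            exons=tuple(exons),
        )
        genes.append(spec)
        transcripts.append(TranscriptModel(
            transcript_id=spec.transcript_id,
            gene_id=spec.gene_id,
            gene_name=spec.gene_name,
            chrom=chrom,
            strand=strand,
            exons=spec.exons,
        ))

    tx_by_gene = {t.transcript_id: t for t in transcripts}
    mrna_idx = {g.transcript_id: _splice_idx(g.exons, g.strand, base_idx)
                for g in genes}

    chains: list[AlignmentChain] = []
    truth: list[SimTruthRecord] = []
    repeat_intervals: list[RepeatInterval] = []
    overwrite: list[tuple[int, np.ndarray]] = []  # (start, sequence indices)

    def parental_self_chain(g: _GeneSpec) -> AlignmentChain:
        t = tx_by_gene[g.transcript_id]
        ex = list(g.exons) if g.strand == "+" else list(reversed(g.exons))
        blocks, off = [], 0
        for s, e in ex:
            blocks.append((off, off + (e - s), s, e))
            off += e - s
        return normalize_chain(g.transcript_id, t.spliced_length, chrom, L,
                               g.strand, blocks, t.spliced_length)

    for g in genes:
        chains.append(parental_self_chain(g))

    def mutate(seq: np.ndarray) -> tuple[np.ndarray, int]:
        """Substitute bases i.i.d. at the configured rate; substitutions
        always change the base, so the match count is exact."""
        if config.mutation_rate <= 0 or seq.size == 0:
            return seq, 0
        mask = rng.random(seq.size) < config.mutation_rate
        n_sub = int(mask.sum())
        if n_sub:
            seq = seq.copy()
            shift = rng.integers(1, 4, size=n_sub, dtype=np.uint8)
            seq[mask] = (seq[mask] + shift) % 4
        return seq, n_sub

    def far_from(span: tuple[int, int], length: int):
        def accept(start: int) -> bool:
            return (_interval_distance(span, (start, start + length))
                    >= config.min_insert_distance_from_parent)
        return accept

    # ---- tandem duplications ---------------------------------------
    # Sampled directly in the parent's neighbourhood: pick a gap within
    # the offset window and a side, so the duplicate's distance to the
    # parent span equals the gap.  Re-draw the parent gene when its
    # surroundings are too crowded.
    for di in range(config.n_tandem_dups):
        start = None
        for _ in range(2000):
            g = genes[int(rng.integers(len(genes)))]
            dlen = g.end - g.start
            gap = int(rng.integers(_PAD, config.tandem_offset + 1))
            right = rng.random() < 0.5
            cand = g.end + gap if right else g.start - gap - dlen
            if placer.is_free(cand, cand + dlen):
                placer.claim(cand, cand + dlen)
                start = cand
                break
        if start is None:
            raise SimulationError(
                "could not place a tandem duplication near its parent; "
                "increase genome_length or reduce element counts"
            )
        t = tx_by_gene[g.transcript_id]
        overwrite.append((start, base_idx[g.start:g.end].copy()))
        shift = start - g.start
        ex = list(g.exons) if g.strand == "+" else list(reversed(g.exons))
        blocks, off = [], 0
        for s, e in ex:
            blocks.append((off, off + (e - s), s + shift, e + shift))
            off += e - s
        chains.append(normalize_chain(g.transcript_id, t.spliced_length, chrom, L,
                                      g.strand, blocks, t.spliced_length))
        truth.append(SimTruthRecord(
            insert_id=f"tandem_{di:03d}", kind=KIND_TANDEM_DUP, chrom=chrom,
            start=start, end=start + dlen, parent_gene_id=g.gene_id,
            truncation_fraction=0.0, mutation_rate=0.0, polya_len=0,
            expected_stage=EXPECTED_REJECTING_STAGE[KIND_TANDEM_DUP],
        ))

    # ---- retrocopies -------------------------------------------------
    def plant_mrna_insert(parent: _GeneSpec, k: int, polya: int,
                          mutated: bool) -> tuple[int, str, int, int, int]:
        """Insert parent mRNA[k:] (+ poly-A) on a random strand, far from
        the parent.  Returns (start, strand, n_sub, aligned_t_start,
        aligned_t_end)."""
        t = tx_by_gene[parent.transcript_id]
        lt = t.spliced_length
        alen = lt - k
        ins_len = alen + polya
        strand = "+" if rng.random() < 0.5 else "-"
        start = placer.place(ins_len, accept=far_from(parent.span, ins_len))
        seq = mrna_idx[parent.transcript_id][k:]
        n_sub = 0
        if mutated:
            seq, n_sub = mutate(seq)
        if polya:
            seq = np.concatenate([seq, np.zeros(polya, dtype=np.uint8)])  # A == 0
        if strand == "-":
            seq = 3 - seq[::-1]
            al_t = (start + polya, start + ins_len)
        else:
            al_t = (start, start + alen)
        overwrite.append((start, seq))
        return start, strand, n_sub, al_t[0], al_t[1]

    for ri in range(config.n_retrocopies):
        g = genes[int(rng.integers(len(genes)))]
        t = tx_by_gene[g.transcript_id]
        lt = t.spliced_length
        junctions = t.junctions
        truncated = rng.random() < config.truncation_prob
        frac = float(rng.uniform(*config.truncation_fraction)) if truncated else 0.0
        k = int(round(frac * lt))
        # Detectability clamp: a real retrocopy record must remain a
        # retrocopy — keep the 3'-most junction (plus safety flank) and a
        # minimum aligned length, so truncation never silently converts
        # the insert into an undetectable fragment.
        k_max = lt - _MIN_ALIGNED
        if junctions:
            k_max = min(k_max, junctions[-1] - _JUNCTION_SAFETY)
        k = max(0, min(k, k_max))
        polya = int(rng.integers(config.polya_len[0], config.polya_len[1] + 1))
        start, strand, n_sub, al0, al1 = plant_mrna_insert(g, k, polya, mutated=True)
        chains.append(normalize_chain(
            g.transcript_id, lt, chrom, L, strand,
            [(k, lt, al0, al1)], (lt - k) - n_sub,
        ))
        truth.append(SimTruthRecord(
            insert_id=f"retro_{ri:03d}", kind=KIND_RETROCOPY, chrom=chrom,
            start=start, end=start + (lt - k) + polya, parent_gene_id=g.gene_id,
            truncation_fraction=k / lt, mutation_rate=config.mutation_rate,
            polya_len=polya,
            expected_stage=EXPECTED_REJECTING_STAGE[KIND_RETROCOPY],
        ))

    # ---- TE decoys ---------------------------------------------------
    for ti in range(config.n_te_decoys):
        g = genes[int(rng.integers(len(genes)))]
        t = tx_by_gene[g.transcript_id]
        lt = t.spliced_length
        polya = int(rng.integers(config.polya_len[0], config.polya_len[1] + 1))
        start, strand, n_sub, al0, al1 = plant_mrna_insert(g, 0, polya, mutated=True)
        cover = int(np.ceil(config.te_decoy_coverage * (al1 - al0)))
        repeat_intervals.append(
            RepeatInterval(chrom, al0, al0 + cover, "SINE", "SINE/Alu")
        )
        chains.append(normalize_chain(
            g.transcript_id, lt, chrom, L, strand,
            [(0, lt, al0, al1)], lt - n_sub,
        ))
        truth.append(SimTruthRecord(
            insert_id=f"tedecoy_{ti:03d}", kind=KIND_TE_DECOY, chrom=chrom,
            start=start, end=start + lt + polya, parent_gene_id=g.gene_id,
            truncation_fraction=0.0, mutation_rate=config.mutation_rate,
            polya_len=polya,
            expected_stage=EXPECTED_REJECTING_STAGE[KIND_TE_DECOY],
        ))

    # ---- short fragments --------------------------------------------
    for si in range(config.n_short_fragments):
        g = genes[int(rng.integers(len(genes)))]
        t = tx_by_gene[g.transcript_id]
        lt = t.spliced_length
        flen = min(config.short_fragment_len, lt)
        strand = "+" if rng.random() < 0.5 else "-"
        start = placer.place(flen, accept=far_from(g.span, flen))
        seq = mrna_idx[g.transcript_id][lt - flen:]
        if strand == "-":
            seq = 3 - seq[::-1]
        overwrite.append((start, seq))
        chains.append(normalize_chain(
            g.transcript_id, lt, chrom, L, strand,
            [(lt - flen, lt, start, start + flen)], flen,
        ))
        truth.append(SimTruthRecord(
            insert_id=f"short_{si:03d}", kind=KIND_SHORT_FRAGMENT, chrom=chrom,
            start=start, end=start + flen, parent_gene_id=g.gene_id,
            truncation_fraction=1.0 - flen / lt, mutation_rate=0.0, polya_len=0,
            expected_stage=EXPECTED_REJECTING_STAGE[KIND_SHORT_FRAGMENT],
        ))

    # ---- background repeat annotation -------------------------------
    te_labels = ["LINE/L1", "SINE/Alu", "LTR/ERVL", "DNA/hAT-Charlie",
                 "LINE/L2", "Simple_repeat"]
    target = config.background_te_density * L
    total = 0
    placed_te: list[tuple[int, int]] = []
    attempts = 0
    while total < target and attempts < 100_000:
        attempts += 1
        ln = int(rng.integers(300, 6001))
        s = int(rng.integers(0, max(1, L - ln)))
        if not placer.is_free(s, s + ln):
            continue
        if any(s < e and b < s + ln for b, e in placed_te):
            continue
        label = te_labels[int(rng.integers(len(te_labels)))]
        repeat_intervals.append(
            RepeatInterval(chrom, s, s + ln, io_formats.classify_repeat(label), label)
        )
        placed_te.append((s, s + ln))
        total += ln

    # ---- assemble final sequence ------------------------------------
    for start, seq in overwrite:
        base_idx[start:start + len(seq)] = seq
    residues = _BASES[base_idx].tobytes().decode("ascii")
    genome = {chrom: GenomeSequence(seq_id=chrom, residues=residues)}
    tx_seqs = {t.transcript_id: splice(t, genome) for t in transcripts}

    return Scene(
        config=config,
        genome=genome,
        transcripts=transcripts,
        transcript_seqs=tx_seqs,
        repeat_intervals=repeat_intervals,
        chains=chains,
        truth=truth,
    )


SCENE_FILES = {
    "genome": "genome.fa",
    "transcripts": "transcripts.fa",
    "annotation": "annotation.gtf",
    "repeats": "repeats.bed",
    "alignments": "alignments.psl",
    "truth": "truth.tsv",
}


def write_scene(scene: Scene, outdir: str | Path) -> dict[str, Path]:
    """Write every scene artefact (FASTA genome and transcripts, GTF
    annotation, BED repeats, PSL alignments, TSV truth) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in SCENE_FILES.items()}
    io_formats.write_fasta(
        ((sid, gs.residues) for sid, gs in sorted(scene.genome.items())),
        paths["genome"],
    )
    io_formats.write_fasta(
        ((t.transcript_id, scene.transcript_seqs[t.transcript_id])
         for t in sorted(scene.transcripts, key=lambda t: t.transcript_id)),
        paths["transcripts"],
    )
    io_formats.write_annotation_gtf(scene.transcripts, paths["annotation"])
    io_formats.write_repeats_bed(scene.repeat_intervals, paths["repeats"])
    io_formats.write_psl(sorted(scene.chains, key=AlignmentChain.sort_key),
                         paths["alignments"])
    io_formats.write_truth(scene.truth, paths["truth"])
    return paths


def config_from_mapping(values: dict) -> SimConfig:
    """Build a SimConfig from a flat mapping of field name -> value,
    accepting "lo,hi" strings (or 2-sequences) for range fields."""
    kwargs = {}
    for f in fields(SimConfig):
        if f.name not in values or values[f.name] is None:
            continue
        raw = values[f.name]
        if isinstance(f.default, tuple):
            if isinstance(raw, str):
                parts = [p.strip() for p in raw.split(",")]
            else:
                parts = list(raw)
            caster = float if isinstance(f.default[0], float) else int
            kwargs[f.name] = tuple(caster(p) for p in parts)
        elif isinstance(f.default, bool):
            kwargs[f.name] = bool(raw)
        elif isinstance(f.default, int):
            kwargs[f.name] = int(raw)
        elif isinstance(f.default, float):
            kwargs[f.name] = float(raw)
        else:
            kwargs[f.name] = str(raw)
    return SimConfig(**kwargs)
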