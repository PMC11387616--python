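"""Unit and property tests for the four-stage filter cascade."""

import math

import numpy as np
import pytest

from retroscout.datamodel import (
    PipelineConfig,
    RepeatIndex,
    RepeatInterval,
    RetroscoutError,
    TranscriptModel,
    build_gene_loci,
    gene_locus_extent,
)
from retroscout.filter_engine import (
    parental_distance,
    project_junctions,
    run_cascade,
    stage1_match_length,
    stage2_parental_exclusion,
    stage3_intronless,
    stage4_te_filter,
    te_fraction,
)

from .conftest import make_chain, random_chain

CFG = PipelineConfig()


def tx(exon_lengths, strand="+", tid="t1", gid="g1", chrom="chr1", start=0,
       intron=1000):
    exons, pos = [], start
    for ln in exon_lengths:
        exons.append((pos, pos + ln))
        pos += ln + intron
    return TranscriptModel(transcript_id=tid, gene_id=gid, gene_name="GENEX",
                           chrom=chrom, strand=strand, exons=tuple(exons))


class TestStage1MatchLength:
    @pytest.mark.parametrize("matches,passed", [(119, False), (120, True), (0, False)])
    def test_inclusive_boundary(self, matches, passed):
        chain = make_chain([(0, 300, 1000, 1300)], matches=matches)
        trace = stage1_match_length(chain, CFG)
        assert trace.passed is passed and trace.value == matches


class TestParentalDistance:
    def test_containment_is_zero(self):
        (locus,) = gene_locus_extent([tx([100, 100], start=100, intron=300)])
        chain = make_chain([(0, 100, 300, 400)])
        assert locus.span == (100, 600)
        assert parental_distance(chain, locus) == 0

    def test_half_open_gap(self):
        (locus,) = gene_locus_extent([tx([100, 100], start=100, intron=300)])
        chain = make_chain([(0, 100, 800, 900)])
        assert parental_distance(chain, locus) == 200

    def test_other_chromosome_is_infinite(self):
        (locus,) = gene_locus_extent([tx([100], chrom="chr2")])
        chain = make_chain([(0, 100, 0, 100)])
        assert parental_distance(chain, locus) == math.inf


class TestStage2ParentalExclusion:
    @pytest.mark.parametrize("distance,passed", [
        (200_000, False),  # "up to" is inclusive: exactly the window is excluded
        (200_001, True),
        (0, False),
    ])
    def test_window_boundary(self, distance, passed):
        (locus,) = gene_locus_extent([tx([100, 100], start=0, intron=100)])
        start = locus.end + distance
        chain = make_chain([(0, 150, start, start + 150)])
        trace = stage2_parental_exclusion(chain, [locus], CFG)
        assert trace.passed is passed and trace.value == distance

    def test_minimum_over_same_chromosome_loci(self):
        loci = (gene_locus_extent([tx([100], start=0)]) +
                gene_locus_extent([tx([100], start=500_000, tid="t2")]))
        chain = make_chain([(0, 150, 490_000, 490_150)])
        trace = stage2_parental_exclusion(chain, loci, CFG)
        assert trace.value == 9850 and not trace.passed

    def test_no_locus_is_an_error(self):
        chain = make_chain([(0, 150, 0, 150)])
        with pytest.raises(RetroscoutError):
            stage2_parental_exclusion(chain, [], CFG)


class TestProjectJunctions:
    def test_single_block_spans_junction(self):
        parent = tx([100, 100])
        chain = make_chain([(0, 200, 5000, 5200)])
        spanned, three_prime = project_junctions(chain, parent, CFG)
        assert spanned == [100] and three_prime

    def test_block_boundary_at_junction_means_intron_present(self):
        # parental-locus-like alignment: the junction falls exactly between
        # two blocks separated by a 5 kb target gap
        parent = tx([100, 100])
        chain = make_chain([(0, 100, 5000, 5100), (100, 200, 10_100, 10_200)])
        spanned, three_prime = project_junctions(chain, parent, CFG)
        assert spanned == [] and not three_prime

    def test_five_prime_truncation_restricts_range(self):
        # junction 100 lies outside the aligned query range; only junction
        # 250 is judged
        parent = tx([100, 150, 150])
        chain = make_chain([(180, 400, 5000, 5220)])
        spanned, three_prime = project_junctions(chain, parent, CFG)
        assert spanned == [250] and three_prime

    def test_no_junction_in_range_is_not_spanned(self):
        parent = tx([100, 100])
        chain = make_chain([(120, 200, 5000, 5080)])  # inside last exon only
        spanned, three_prime = project_junctions(chain, parent, CFG)
        assert spanned == [] and not three_prime

    def test_flank_requirement_each_side(self):
        parent = tx([100, 100])
        cfg = PipelineConfig(junction_flank_nt=10)
        # block ends at 105: only 5 aligned bases 3' of the junction
        chain = make_chain([(0, 105, 5000, 5105)])
        spanned, _ = project_junctions(chain, parent, cfg)
        assert spanned == []

    def test_verdict_matches_brute_force_scan(self):
        rng = np.random.default_rng(29)
        for _ in range(1000):
            n_ex = int(rng.integers(2, 7))
            parent = tx([int(x) for x in rng.integers(30, 300, n_ex)],
                        strand="+" if rng.random() < 0.5 else "-")
            chain = random_chain(rng, qid="t1")
            flank = int(rng.integers(1, 25))
            cfg = PipelineConfig(junction_flank_nt=flank)
            spanned, three_prime = project_junctions(chain, parent, cfg)
            # oracle: per-block materialised query-position sets
            block_sets = [set(range(b.q_start, b.q_end)) for b in chain.blocks]
            oracle_spanned = [
                j for j in parent.junctions
                if any(set(range(j - flank, j + flank)) <= s for s in block_sets)
            ]
            qmin, qmax = chain.query_span
            in_range = [j for j in parent.junctions
                        if j - flank >= qmin and j + flank <= qmax]
            oracle_3p = bool(in_range) and in_range[-1] in oracle_spanned
            assert spanned == oracle_spanned
            assert three_prime == oracle_3p


class TestStage3Intronless:
    def test_all_junctions_spanned_passes(self):
        parent = tx([100, 100, 100])
        chain = make_chain([(0, 300, 5000, 5300)])
        trace, _, _ = stage3_intronless(chain, parent, CFG)
        assert trace.passed and trace.value == 2

    def test_intron_retaining_duplicate_fails(self):
        parent = tx([100, 100])
        chain = make_chain([(0, 100, 5000, 5100), (100, 200, 10_100, 10_200)])
        trace, _, _ = stage3_intronless(chain, parent, CFG)
        assert not trace.passed

    def test_truncated_retrocopy_spanning_last_junction_passes(self):
        parent = tx([100, 150, 150])
        chain = make_chain([(180, 400, 5000, 5220)])
        trace, _, _ = stage3_intronless(chain, parent, CFG)
        assert trace.passed and trace.value == 1

    def test_single_exon_parent_always_fails(self):
        parent = tx([400])
        chain = make_chain([(0, 400, 5000, 5400)])
        trace, _, _ = stage3_intronless(chain, parent, CFG)
        assert not trace.passed and trace.value == 0


class TestTeFraction:
    def test_half_covered(self):
        idx = RepeatIndex([RepeatInterval("chr1", 1000, 1500, "LINE", "LINE/L1")])
        chain = make_chain([(0, 1000, 1000, 2000)])
        assert te_fraction(chain, idx) == 0.5

    def test_no_repeats_is_zero(self):
        chain = make_chain([(0, 1000, 1000, 2000)])
        assert te_fraction(chain, RepeatIndex([])) == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            n = int(rng.integers(0, 15))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 9000))
                e = s + int(rng.integers(1, 1000))
                cls = ["LINE", "SINE", "Other"][int(rng.integers(3))]
                ivs.append(RepeatInterval("chr1", s, e, cls, cls))
            idx = RepeatIndex(ivs)
            chain = random_chain(rng)
            countable = [(iv.start, iv.end) for iv in ivs if iv.repeat_class != "Other"]
            brute = sum(
                any(s <= x < e for s, e in countable)
                for b in chain.blocks
                for x in range(b.t_start, b.t_end)
            )
            assert te_fraction(chain, idx) == pytest.approx(brute / chain.aligned_bases)

    def test_zero_length_chain_impossible_but_guarded(self):
        # normalize_chain already refuses empty blocks; the guard in
        # te_fraction covers hand-built degenerate objects
        chain = make_chain([(0, 10, 0, 10)])
        object.__setattr__(chain, "blocks", ())
        with pytest.raises(RetroscoutError):
            te_fraction(chain, RepeatIndex([]))


class TestStage4TeFilter:
    @pytest.mark.parametrize("covered,passed", [
        (410, False),  # 41% — "more than 40%" removed
        (400, True),   # exactly 40% retained
        (0, True),
    ])
    def test_strict_boundary(self, covered, passed):
        ivs = [RepeatInterval("chr1", 1000, 1000 + covered, "LINE", "LINE/L1")]
        chain = make_chain([(0, 1000, 1000, 2000)])
        trace = stage4_te_filter(chain, RepeatIndex(ivs) if covered else RepeatIndex([]), CFG)
        assert trace.passed is passed
        assert trace.value == pytest.approx(covered / 1000)


def _mini_setup():
    parent = tx([100, 100, 100], tid="t1", start=0, intron=1000)
    transcripts = {"t1": parent}
    gene_loci = build_gene_loci([parent])
    repeats = RepeatIndex([])
    return transcripts, gene_loci, repeats


class TestRunCascade:
    def test_empty_input(self):
        transcripts, gene_loci, repeats = _mini_setup()
        result = run_cascade([], transcripts, gene_loci, repeats, CFG)
        assert result.candidates == [] and result.report["input"] == 0

    def test_chain_stops_at_first_failing_stage(self):
        transcripts, gene_loci, repeats = _mini_setup()
        short = make_chain([(0, 80, 500_000, 500_080)], qid="t1", matches=80)
        near = make_chain([(0, 300, 5000, 5300)], qid="t1")
        good = make_chain([(0, 300, 500_000, 500_300)], qid="t1")
        result = run_cascade([short, near, good], transcripts, gene_loci,
                             repeats, CFG)
        assert len(result.candidates) == 1
        stages = sorted((r[1][-1].stage, r[1][-1].passed) for r in result.rejections)
        assert stages == [("match_length", False), ("parental_distance", False)]

    def test_order_independent(self):
        transcripts, gene_loci, repeats = _mini_setup()
        rng = np.random.default_rng(7)
        chains = [random_chain(rng, qid="t1") for _ in range(40)]
        a = run_cascade(chains, transcripts, gene_loci, repeats, CFG)
        b = run_cascade(list(reversed(chains)), transcripts, gene_loci, repeats, CFG)
        assert a.candidates == b.candidates and a.report == b.report

    def test_unresolvable_query_id_listed(self):
        transcripts, gene_loci, repeats = _mini_setup()
        chain = make_chain([(0, 300, 0, 300)], qid="mystery")
        with pytest.raises(RetroscoutError, match="mystery"):
            run_cascade([chain], transcripts, gene_loci, repeats, CFG)

    def test_trace_prefix_property(self, default_scene):
        """Every chain reaching stage k passed all earlier stages."""
        from retroscout.cli import detect_loci
        _, result = detect_loci(default_scene.genome, default_scene.transcripts,
                                default_scene.repeats, default_scene.chains, CFG)
        for _, trace in result.rejections:
            assert all(t.passed for t in trace[:-1])
            assert not trace[-1].passed
        for cand in result.candidates:
            assert all(t.passed for t in cand.trace)

    def test_threshold_monotonicity(self, default_scene):
        """Tightening any threshold never increases the survivor count."""
        sc = default_scene
        gene_loci = build_gene_loci(sc.transcripts)
        txs = {t.transcript_id: t for t in sc.transcripts}
        reps = sc.repeats

        def survivors(cfg):
            return len(run_cascade(sc.chains, txs, gene_loci, reps, cfg).candidates)

        base = survivors(CFG)
        assert survivors(PipelineConfig(min_matched_nt=500)) <= base
        assert survivors(PipelineConfig(parental_exclusion_bp=400_000)) <= base
        assert survivors(PipelineConfig(max_te_fraction=0.0)) <= base
        assert survivors(PipelineConfig(min_spanned_junctions=3)) <= base
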