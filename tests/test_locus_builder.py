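"""Grouping of surviving alignments into loci, naming, and catalog
comparison."""

import numpy as np
import pytest

from retroscout.datamodel import (
    FilterTrace,
    RetrocopyCandidate,
    RetrocopyLocus,
    TranscriptModel,
)
from retroscout.locus_builder import compare_catalogs, group_loci, name_loci

from .conftest import make_chain


def _tx(tid="t1", gid="g1", gname="GENEX"):
    return TranscriptModel(transcript_id=tid, gene_id=gid, gene_name=gname,
                           chrom="chr1", strand="+", exons=((0, 100), (500, 600)))


def cand(start, end, matches=None, tid="t1", gid="g1", gname="GENEX",
         chrom="chr1", qid=None):
    length = end - start
    chain = make_chain([(0, length, start, end)], qid=qid or tid, chrom=chrom,
                       matches=matches if matches is not None else length)
    return RetrocopyCandidate(
        chain=chain, parent=_tx(tid=tid, gid=gid, gname=gname),
        trace=(FilterTrace("match_length", True, chain.matches),),
        spanned_junctions=1, three_prime_junction_spanned=True,
    )


class TestGroupLoci:
    def test_overlapping_candidates_merge(self):
        loci = group_loci([cand(1000, 2000, tid="t1"), cand(1500, 2500, tid="t2")])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (1000, 2500)
        assert len(loci[0].members) == 2

    def test_disjoint_candidates_stay_separate(self):
        loci = group_loci([cand(1000, 2000), cand(3000, 4000)])
        assert len(loci) == 2

    def test_touching_intervals_do_not_merge(self):
        loci = group_loci([cand(1000, 2000), cand(2000, 3000)])
        assert len(loci) == 2

    def test_representative_has_maximal_matches(self):
        a = cand(1000, 2000, matches=500, tid="tA", gid="gA", gname="ALPHA")
        b = cand(1500, 2500, matches=300, tid="tB", gid="gB", gname="BETA")
        (locus,) = group_loci([a, b])
        assert locus.parental_gene_id == "gA"
        assert locus.matched_nt == 500

    def test_tie_break_longer_footprint_then_transcript_id(self):
        a = cand(1000, 1400, matches=300, tid="tB")
        b = cand(1000, 1500, matches=300, tid="tA")
        (locus,) = group_loci([a, b])
        assert locus.representative_transcript_id == "tA"  # longer footprint
        c = cand(1000, 1500, matches=300, tid="tC")
        (locus,) = group_loci([b, c])
        assert locus.representative_transcript_id == "tA"  # lexicographic

    def test_per_gene_mode_separates_genes(self):
        a = cand(1000, 2000, tid="tA", gid="gA")
        b = cand(1500, 2500, tid="tB", gid="gB")
        assert len(group_loci([a, b])) == 1
        assert len(group_loci([a, b], per_gene=True)) == 2

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            n = int(rng.integers(1, 200))
            cands = []
            for i in range(n):
                chrom = f"chr{int(rng.integers(1, 4))}"
                s = int(rng.integers(0, 50_000))
                e = s + int(rng.integers(1, 3000))
                cands.append(cand(s, e, tid=f"t{i}", chrom=chrom, qid=f"t{i}"))
            loci = group_loci(cands)
            # brute-force union-find over the pairwise overlap graph
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    ci, cj = cands[i].chain, cands[j].chain
                    if ci.target_chrom != cj.target_chrom:
                        continue
                    fi, fj = ci.footprint, cj.footprint
                    if min(fi[1], fj[1]) - max(fi[0], fj[0]) >= 1:
                        parent[find(i)] = find(j)
            oracle = {}
            for i in range(n):
                oracle.setdefault(find(i), set()).add(cands[i].parent.transcript_id)
            got = {frozenset(m.parent.transcript_id for m in l.members) for l in loci}
            assert got == {frozenset(v) for v in oracle.values()}
            # partition property: every candidate in exactly one locus
            assert sum(len(l.members) for l in loci) == n


class TestNameLoci:
    def test_sorted_by_chrom_then_start(self):
        loci = group_loci([
            cand(100, 600, tid="t1", gid="g1", gname="GAPDH", chrom="chr2"),
            cand(500, 1000, tid="t1", gid="g1", gname="GAPDH", chrom="chr1", qid="t1"),
        ])
        named = name_loci(loci)
        by_name = {l.name: l.chrom for l in named}
        assert by_name == {"GAPDHP1": "chr1", "GAPDHP2": "chr2"}

    def test_single_locus_pattern(self):
        named = name_loci(group_loci([cand(0, 500, gname="FTL")]))
        assert named[0].name == "FTLP1"

    def test_empty_gene_name_falls_back_to_gene_id(self):
        named = name_loci(group_loci([cand(0, 500, gname="", gid="g77")]))
        assert named[0].name == "g77P1"

    def test_gap_free_and_permutation_invariant(self):
        rng = np.random.default_rng(41)
        cands = [cand(i * 5000, i * 5000 + 400, tid=f"t{i % 3}",
                      gid=f"g{i % 3}", gname=f"GN{i % 3}", qid=f"t{i % 3}")
                 for i in range(12)]
        named = name_loci(group_loci(cands))
        perm = [cands[i] for i in rng.permutation(len(cands))]
        named2 = name_loci(group_loci(perm))
        assert [l.name for l in named] == [l.name for l in named2]
        for g in range(3):
            nums = sorted(int(l.name.split("P")[-1]) for l in named
                          if l.parental_gene_name == f"GN{g}")
            assert nums == list(range(1, len(nums) + 1))

    def test_rerun_is_deterministic(self):
        loci = group_loci([cand(0, 500), cand(5000, 5500)])
        assert [l.name for l in name_loci(loci)] == [l.name for l in name_loci(loci)]


class TestCompareCatalogs:
    def _loci(self, coords):
        return [
            RetrocopyLocus(locus_id=f"l{i}", chrom=c, start=s, end=e, strand="+",
                           parental_gene_id="g", parental_gene_name="G",
                           representative_transcript_id="t", members=(None,),
                           matched_nt=200, te_fraction=0.0, spanned_junctions=1,
                           name=f"GP{i}")
            for i, (c, s, e) in enumerate(coords, 1)
        ]

    def test_identical_catalogs_all_shared(self):
        a = self._loci([("c", 0, 100), ("c", 500, 600)])
        b = [("c", 0, 100), ("c", 500, 600)]
        cmpres = compare_catalogs(a, b)
        assert (cmpres.shared, cmpres.a_specific, cmpres.b_specific) == (2, 0, 0)

    def test_disjoint_catalogs_nothing_shared(self):
        a = self._loci([("c", 0, 100)])
        cmpres = compare_catalogs(a, [("c", 200, 300)])
        assert (cmpres.shared, cmpres.a_specific, cmpres.b_specific) == (0, 1, 1)

    def test_single_base_half_open_overlap_counts(self):
        a = self._loci([("c", 0, 100)])
        assert compare_catalogs(a, [("c", 99, 200)]).shared == 1
        assert compare_catalogs(a, [("c", 100, 200)]).shared == 0
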