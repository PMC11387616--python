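import numpy as np
import pytest

from retroscout.datamodel import AlignmentChain, TranscriptModel, normalize_chain
from retroscout.simulator import SimConfig, simulate_scene, write_scene


def make_chain(blocks, strand="+", matches=None, qlen=None, qid="q",
               chrom="chr1", tlen=10_000_000):
    """Shorthand chain constructor for unit tests."""
    total = sum(b[1] - b[0] for b in blocks)
    if matches is None:
        matches = total
    if qlen is None:
        qlen = max(b[1] for b in blocks)
    return normalize_chain(qid, qlen, chrom, tlen, strand, blocks, matches)


def random_chain(rng: np.random.Generator, qid="q", chrom="chr1") -> AlignmentChain:
    """A random but internally consistent multi-block chain on either strand."""
    nb = int(rng.integers(1, 6))
    sizes = [int(x) for x in rng.integers(5, 200, nb)]
    qgaps = [int(x) for x in rng.integers(0, 60, nb)]
    tgaps = [int(x) for x in rng.integers(0, 800, nb)]
    pos = int(rng.integers(0, 50))
    qiv = []
    for s, g in zip(sizes, qgaps):
        pos += g
        qiv.append((pos, pos + s))
        pos += s
    qlen = pos + int(rng.integers(0, 100))
    strand = "+" if rng.random() < 0.5 else "-"
    order = list(range(nb)) if strand == "+" else list(reversed(range(nb)))
    tpos = int(rng.integers(0, 10_000))
    tiv = {}
    for i in order:
        tpos += tgaps[i]
        tiv[i] = (tpos, tpos + sizes[i])
        tpos += sizes[i]
    blocks = [(qiv[i][0], qiv[i][1], tiv[i][0], tiv[i][1]) for i in range(nb)]
    matches = int(rng.integers(0, sum(sizes) + 1))
    return normalize_chain(qid, qlen, chrom, tpos + 1000, strand, blocks, matches)


def random_transcript(rng: np.random.Generator, tid="t1", gid="g1",
                      gname="GENEX", chrom="chr1") -> TranscriptModel:
    n = int(rng.integers(1, 7))
    pos = int(rng.integers(0, 5000))
    exons = []
    for _ in range(n):
        pos += int(rng.integers(0, 2000))
        ln = int(rng.integers(1, 400))
        exons.append((pos, pos + ln))
        pos += ln
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(transcript_id=tid, gene_id=gid, gene_name=gname,
                           chrom=chrom, strand=strand, exons=tuple(exons))


@pytest.fixture(scope="session")
def default_scene():
    """The default simulated study: 20 retrocopies, 5 of each decoy class."""
    return simulate_scene(SimConfig(seed=7))


@pytest.fixture(scope="session")
def scene_dir(default_scene, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("scene")
    write_scene(default_scene, outdir)
    return outdir
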