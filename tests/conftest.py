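import numpy as np
import pytest

from ciceratlas import expression, synthetic
from ciceratlas.models import GenomeAnnotation, TranscriptModel


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic atlas (seed 1), shared by every integration test."""
    return synthetic.generate_atlas(synthetic.AtlasSpec(seed=1))


@pytest.fixture(scope="session")
def profiles(bundle):
    return expression.average_replicates(bundle.atlas)


def make_transcript(tid, exons, strand="+", chrom="chr1", biotype="PCG"):
    return TranscriptModel(
        id=tid, chromosome=chrom, strand=strand, exons=exons, biotype=biotype
    )


def make_annotation(transcripts, chrom_lengths=None):
    chrom_lengths = chrom_lengths or {"chr1": 1_000_000}
    return GenomeAnnotation(transcripts, chrom_lengths)


def random_small_annotation(rng: np.random.Generator, chrom_len=120_000):
    """Randomized small annotation (overlaps allowed) for oracle comparisons."""
    transcripts = []
    for i in range(int(rng.integers(4, 9))):
        n_ex = int(rng.integers(1, 5))
        start = int(rng.integers(0, chrom_len - 20_000))
        exons, pos = [], start
        for j in range(n_ex):
            e = pos + int(rng.integers(100, 800))
            exons.append((pos, e))
            pos = e + int(rng.integers(100, 2_000))
        transcripts.append(
            make_transcript(
                f"PCG{i}", exons, strand="+" if rng.integers(0, 2) else "-"
            )
        )
    lncs = []
    for i in range(int(rng.integers(2, 5))):
        start = int(rng.integers(0, chrom_len - 3_000))
        length = int(rng.integers(200, 1_500))
        lncs.append(
            make_transcript(
                f"LNC{i}",
                [(start, start + length)],
                strand="+" if rng.integers(0, 2) else "-",
                biotype="lncRNA",
            )
        )
    return make_annotation(transcripts + lncs, {"chr1": chrom_len})
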