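import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from talechip.core import GeneModel, Genome, GenomicInterval, Peak, PeakSet
from talechip.simulate import scrub_consensus_sites


@pytest.fixture
def toy_genes():
    """A small hand-built annotation: two + genes, one - gene, two
    chromosomes with room for every location class."""
    return [
        GeneModel("geneA", GenomicInterval("chr1", 10_000, 18_000), "+"),
        GeneModel("geneB", GenomicInterval("chr1", 60_000, 75_000), "-"),
        GeneModel("geneC", GenomicInterval("chr2", 30_000, 45_000), "+"),
    ]


@pytest.fixture(scope="session")
def random_background():
    """300 kb of i.i.d. background scrubbed of consensus motif matches."""
    rng = np.random.default_rng(20240917)
    seq = "".join(rng.choice(list("ACGT"), size=300_000))
    return scrub_consensus_sites(seq, ["OCTA", "DECA", "AP1"], rng)


def make_peak(chrom, start, end, summit=None, score=1.0, name="p"):
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end), summit, score, name)


@pytest.fixture
def make_peakset():
    def _make(intervals, label="test", chrom="chr1"):
        peaks = [make_peak(chrom, s, e, name=f"p{i}") for i, (s, e) in enumerate(intervals)]
        return PeakSet(label, peaks)
    return _make
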