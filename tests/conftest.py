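import numpy as np
import pytest

from panelprof import synth
from panelprof.msi_tract import TractDefinition
from panelprof.core_io import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tract():
    """A fixed 15 bp poly-A tract with deterministic 10 bp seeds."""
    return TractDefinition(
        interval=GenomicInterval("chr1", 1000, 1015, "tractA"),
        base="A",
        ref_length=15,
        seed5="CGTACGGTTC",
        seed3="GTCCTAGGTG",
    )


@pytest.fixture
def exon_catalog():
    return synth.make_exon_catalog(total_mb=5.0)


def make_read(tract, tract_len, mapq=60, softclip=0, left=12, right=12,
              read_id="r0", rng=None):
    """Construct a read spanning `tract` with a repeat segment of tract_len."""
    rng = rng or np.random.default_rng(0)
    others = [b for b in "ACGT" if b != tract.base]
    lflank = "".join(rng.choice(others, size=left))
    rflank = "".join(rng.choice(others, size=right))
    seq = lflank + tract.seed5 + tract.base * tract_len + tract.seed3 + rflank
    from panelprof.core_io import ReadRecord

    pos = tract.interval.start - len(tract.seed5) - left
    return ReadRecord(
        read_id=read_id,
        chrom=tract.interval.chrom,
        pos=pos,
        cigar=f"{len(seq)}M",
        mapq=mapq,
        sequence=seq,
        softclip_total=softclip,
    )
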