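import numpy as np
import pytest

from genodiag.io_formats import GenomeLayout, VariantRecord


@pytest.fixture
def layout_100kb():
    """Two 100-kb autosomes plus a non-autosomal X."""
    return GenomeLayout.from_pairs(
        [("1", 100_000), ("2", 100_000), ("X", 100_000)], autosomes={"1", "2"}
    )


@pytest.fixture
def layout_1mb():
    return GenomeLayout.from_pairs([("1", 1_000_000)])


def make_record(
    chrom="1",
    pos=100,
    ref="A",
    alts=("C",),
    qual=50.0,
    gt=(0, 1),
    dp=30,
    ac=None,
):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        qual=qual,
        genotypes=[gt],
        depths=[dp],
        ac=ac,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
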