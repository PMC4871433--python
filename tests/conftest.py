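import numpy as np
import pytest

from yy2scan.io_genomics import AlignedRead, FeatureCatalog, FeatureRecord, GenomicInterval


def make_read(chrom="chr1", start=0, end=50, mapping_class="unique", dataset="ip"):
    return AlignedRead(GenomicInterval(chrom, start, end), mapping_class, dataset)


def make_feature(feature_id, chrom, start, end, strand="+", biotype="protein_coding", name=None):
    return FeatureRecord(
        feature_id, name or feature_id, biotype, GenomicInterval(chrom, start, end, strand), strand
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog():
    return FeatureCatalog(
        [
            make_feature("g1", "chr1", 1000, 2000, "+"),
            make_feature("g2", "chr1", 50_000, 60_000, "-"),
            make_feature("g3", "chr1", 300_000, 310_000, "+", biotype="lncRNA"),
            make_feature("g4", "chr2", 500, 900, "+"),
            make_feature("g5", "chr2", 10_000, 12_000, "-", biotype="other"),
        ]
    )
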