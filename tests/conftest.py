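import numpy as np
import pytest

from rarekernel import from_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_genotypes(rng):
    """12 samples x 8 variants of raw allele counts, minor-allele oriented."""
    counts = rng.integers(0, 3, size=(12, 8)).astype(float)
    return from_counts(counts, orient=True, validate=True)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""


def make_vcf(path, rows):
    """Write a tiny 4-sample VCF. rows: list of (pos, id, gts) with gts like
    ['0/0','0/1','1/1','0/0']."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for pos, vid, gts in rows:
            fh.write(
                f"1\t{pos}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


@pytest.fixture
def vcf_path(tmp_path):
    return make_vcf(
        tmp_path / "region.vcf",
        [
            (100, "v1", ["0/0", "0/1", "1/1", "0/0"]),   # ALT minor
            (200, "v2", ["1/1", "1/1", "0/1", "1/1"]),   # ALT major -> recoded
            (300, "v3", ["0/0", "0/0", "0/1", "0/0"]),   # rare
        ],
    )
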