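from __future__ import annotations

import pytest

from poolsweep.io import LineStats, SnpCall


def make_call(
    pos: int,
    chrom: str = "chr1",
    snpq: float = 50.0,
    depth: int = 10,
    alt_fwd: int = 2,
    alt_rev: int = 2,
    line_id: str = "L1",
    ref: str = "A",
    alt: str = "C",
) -> SnpCall:
    return SnpCall(
        line_id=line_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        snpq=snpq,
        depth=depth,
        alt_fwd=alt_fwd,
        alt_rev=alt_rev,
    )


@pytest.fixture
def line_stats() -> LineStats:
    """A pool of 12 birds with mean depth 10 +/- 2 (upper bound 16)."""
    return LineStats(
        line_id="L1", group="broiler", n_individuals=12, mean_cov=10.0, sd_cov=2.0
    )


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=DP4,Number=4,Type=Integer,Description="Strand read counts">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@pytest.fixture
def small_vcf(tmp_path):
    """Hand-written VCF: one SNP, one indel, one triallelic SNP record."""
    path = tmp_path / "pool.vcf"
    path.write_text(
        VCF_HEADER
        + "chr1\t100\t.\tA\tC\t45\t.\tDP=12;DP4=4,3,3,2\n"
        + "chr1\t200\t.\tG\tGT\t50\t.\tDP=10;DP4=3,3,2,2\n"
        + "chr1\t300\t.\tT\tA,C\t60\t.\tDP=20;DP4=5,5,6,4\n"
    )
    return path
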