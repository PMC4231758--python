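import pysam
import pytest

from telofuse import ChromosomeSet, build_subtelomere_map, tair10_chromosomes


@pytest.fixture(scope="session")
def tair10():
    return tair10_chromosomes()


@pytest.fixture(scope="session")
def toy_genome():
    """Two 1 Mb chromosomes plus a short 150 kb scaffold."""
    return ChromosomeSet(
        (("chr1", 1_000_000), ("chr2", 1_000_000), ("chr3", 150_000))
    )


@pytest.fixture(scope="session")
def toy_submap(toy_genome):
    return build_subtelomere_map(toy_genome, 100_000)


@pytest.fixture(scope="session")
def toy_header(toy_genome):
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in toy_genome.entries],
        }
    )


def make_pair(
    header,
    qname,
    chrom1,
    pos1,
    chrom2,
    pos2,
    mapq1=60,
    mapq2=60,
    proper=None,
    duplicate=False,
    secondary=False,
    read_length=100,
):
    """Build the two primary records of a mate pair for in-memory scans."""
    if proper is None:
        proper = chrom1 == chrom2
    out = []
    for read1, (ca, pa, cb, pb, mq) in zip(
        (True, False),
        ((chrom1, pos1, chrom2, pos2, mapq1), (chrom2, pos2, chrom1, pos1, mapq2)),
    ):
        rec = pysam.AlignedSegment(header)
        rec.query_name = qname
        rec.flag = 0x1 | (0x40 if read1 else 0x80)
        if proper:
            rec.flag |= 0x2
        if duplicate:
            rec.flag |= 0x400
        if secondary:
            rec.flag |= 0x100
        rec.reference_name = ca
        rec.reference_start = pa
        rec.mapping_quality = mq
        rec.cigarstring = f"{read_length}M"
        rec.next_reference_name = cb
        rec.next_reference_start = pb
        out.append(rec)
    return out
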