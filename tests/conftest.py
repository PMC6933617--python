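import re

import pysam
import pytest

from consread.clustering import fragment_key_from_mates
from consread.core_model import AlignedRead, ReadPair

FLAG_R1 = 0x1 | 0x2 | 0x20 | 0x40   # paired, proper, mate reverse, first
FLAG_R2 = 0x1 | 0x2 | 0x10 | 0x80   # paired, proper, reverse, second


def parse_cigar(cigar: str):
    return tuple((op, int(n)) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar))


def mk_read(
    name="r",
    chrom="chr1",
    start=0,
    cigar="50M",
    seq=None,
    quals=30,
    flag=FLAG_R1,
    mapq=60,
    rnext="=",
    pnext=0,
    tlen=0,
    umi="",
):
    ctuples = parse_cigar(cigar)
    qlen = sum(n for op, n in ctuples if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    if isinstance(quals, int):
        quals = [quals] * len(seq)
    return AlignedRead(
        query_name=name, chrom=chrom, ref_start=start, mapq=mapq,
        cigar=ctuples, seq=seq, quals=list(quals), flag=flag,
        rnext=rnext, pnext=pnext, tlen=tlen, umi=umi,
    )


def mk_pair(
    name="p",
    chrom="chr1",
    start1=0,
    start2=None,
    cigar1="50M",
    cigar2="50M",
    seq1=None,
    seq2=None,
    quals1=30,
    quals2=30,
    umi="",
    mapq=60,
):
    if start2 is None:
        start2 = start1
    r1 = mk_read(name, chrom, start1, cigar1, seq1, quals1, FLAG_R1, mapq=mapq, umi=umi)
    r2 = mk_read(name, chrom, start2, cigar2, seq2, quals2, FLAG_R2, mapq=mapq, umi=umi)
    key = fragment_key_from_mates(r1, r2)
    return ReadPair(read1=r1, read2=r2, key=key, umi=umi)


def write_sam(path, reads, chroms=(("chr1", 10_000),), sort_order="coordinate"):
    """Write AlignedReads (in the given order) to a SAM file."""
    from consread.alignment_io import read_to_pysam

    header = {
        "HD": {"VN": "1.6", "SO": sort_order},
        "SQ": [{"SN": n, "LN": ln} for n, ln in chroms],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as af:
        for read in reads:
            af.write(read_to_pysam(read, af.header))
    return str(path)


@pytest.fixture
def tiny_fasta(tmp_path):
    """10 kb single-chromosome reference, deterministic."""
    from consread.simulate import make_reference, write_reference

    ref = make_reference(1, 10_000, seed=123)
    path = tmp_path / "ref.fasta"
    write_reference(ref, str(path))
    return str(path), ref
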