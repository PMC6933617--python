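"""Streaming BAM/SAM input and coordinate-sorted output.

The engine is single-pass: reads stream in coordinate order, mates are joined
by name, position groups are finalized the moment no further member can
arrive (processing-while-reading), and finished records are buffered in a
position-keyed queue that is drained up to a moving watermark
(writing-while-processing), so the output is coordinate-sorted without a
second sort and memory stays bounded by the open window.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import pysam
from pyfaidx import Fasta

from . import __version__
from .clustering import extract_umi, fragment_key_from_mates
from .core_model import (
    AlignedRead,
    ConsensusRead,
    DuplicatePrimaryError,
    FragmentKey,
    OutputOrderError,
    ReadPair,
    ReferenceMissingError,
    UnsortedInputError,
)

CIGAR_OPS = "MIDNSHP=X"


# ---------------------------------------------------------------------------
# pysam record conversion
# ---------------------------------------------------------------------------

def read_from_pysam(seg: pysam.AlignedSegment) -> AlignedRead:
    cigar = tuple(
        (CIGAR_OPS[op], length) for op, length in (seg.cigartuples or ())
    )
    quals = list(seg.query_qualities) if seg.query_qualities is not None else []
    seq = seg.query_sequence or ""
    if not quals and seq:
        quals = [0] * len(seq)
    return AlignedRead(
        query_name=seg.query_name or "",
        chrom=seg.reference_name,
        ref_start=seg.reference_start if seg.reference_start is not None else -1,
        mapq=seg.mapping_quality,
        cigar=cigar,
        seq=seq,
        quals=quals,
        flag=seg.flag,
        rnext=seg.next_reference_name,
        pnext=seg.next_reference_start if seg.next_reference_start is not None else -1,
        tlen=seg.template_length,
        tags=seg.get_tags(),
    )


def read_to_pysam(read: AlignedRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.query_name
    seg.flag = read.flag
    if read.chrom is not None:
        seg.reference_name = read.chrom
        seg.reference_start = read.ref_start
    else:
        seg.reference_id = -1
        seg.reference_start = -1
    seg.mapping_quality = read.mapq
    if read.cigar:
        seg.cigartuples = [(CIGAR_OPS.index(op), n) for op, n in read.cigar]
    seg.query_sequence = read.seq
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in read.quals)
    ) if read.seq else None
    if read.rnext is not None:
        seg.next_reference_name = read.rnext
    else:
        seg.next_reference_id = -1
    seg.next_reference_start = read.pnext
    seg.template_length = read.tlen
    if read.tags:
        seg.set_tags(list(read.tags))
    return seg


# ---------------------------------------------------------------------------
# input stream
# ---------------------------------------------------------------------------

@dataclass
class AlignmentHeaderInfo:
    """Chromosome names/lengths and the sort-order tag of an alignment file."""

    chromosomes: list[tuple[str, int]]
    sort_order: str
    pysam_header: pysam.AlignmentHeader

    @property
    def chrom_ids(self) -> dict[str, int]:
        return {name: i for i, (name, _) in enumerate(self.chromosomes)}


def open_alignment_stream(
    path: str,
) -> tuple[AlignmentHeaderInfo, Iterator[AlignedRead]]:
    """Open a coordinate-sorted BAM/SAM for streaming.

    Raises ``UnsortedInputError`` when the header's SO tag is not
    "coordinate" or, lazily while iterating, when a record's position runs
    backwards on its chromosome (or a chromosome re-appears).
    """
    af = pysam.AlignmentFile(path, require_index=False)
    hd = af.header.to_dict()
    sort_order = hd.get("HD", {}).get("SO", "unknown")
    if sort_order != "coordinate":
        af.close()
        raise UnsortedInputError(
            f"{path}: input must be coordinate-sorted (header SO tag is "
            f"{sort_order!r}, 'coordinate' required)"
        )
    chroms = [(sq["SN"], sq["LN"]) for sq in hd.get("SQ", [])]
    info = AlignmentHeaderInfo(
        chromosomes=chroms, sort_order=sort_order, pysam_header=af.header
    )

    def _iter() -> Iterator[AlignedRead]:
        last: Optional[tuple[int, int]] = None
        seen_chroms: set[int] = set()
        try:
            for seg in af:
                read = read_from_pysam(seg)
                if read.chrom is not None and not read.is_unmapped:
                    cid = seg.reference_id
                    if last is not None and cid == last[0] and read.ref_start < last[1]:
                        raise UnsortedInputError(
                            f"unsorted input: {read.query_name} at "
                            f"{read.chrom}:{read.ref_start} after position {last[1]}"
                        )
                    if last is None or cid != last[0]:
                        if cid in seen_chroms:
                            raise UnsortedInputError(
                                f"unsorted input: chromosome {read.chrom} appears twice"
                            )
                        seen_chroms.add(cid)
                    last = (cid, read.ref_start)
                yield read
        finally:
            af.close()

    return info, _iter()


# ---------------------------------------------------------------------------
# mate pairing
# ---------------------------------------------------------------------------

@dataclass
class MatePairer:
    """Joins primary mapped mates by query name into ReadPairs.

    First-seen mates are buffered in a by-name map bounded by the current
    chromosome: coordinate sort guarantees both mates of an intra-chromosomal
    pair appear before the chromosome ends. Records that can never pair
    (unmapped, secondary, supplementary, mate unmapped or on another
    chromosome) pass through unchanged.
    """

    chrom_ids: dict[str, int]
    umi_delimiter: str = ":"
    umi_prefix: str = "UMI_"
    pending: dict[str, AlignedRead] = field(default_factory=dict)
    completed: set[str] = field(default_factory=set)
    current_chrom: Optional[str] = None
    orphans: int = 0

    def feed(
        self, read: AlignedRead
    ) -> Iterator[Union[ReadPair, AlignedRead]]:
        if read.chrom != self.current_chrom:
            yield from self.flush()
            self.current_chrom = read.chrom
        if not read.is_primary_mapped or not read.is_paired:
            yield read
            return
        if read.mate_unmapped or read.rnext not in (read.chrom, "="):
            self.orphans += 1
            yield read
            return
        name = read.query_name
        mate = self.pending.pop(name, None)
        if mate is None:
            if name in self.completed:
                raise DuplicatePrimaryError(
                    f"duplicate primary alignment for read {name!r}"
                )
            self.pending[name] = read
            return
        if mate.is_read1 == read.is_read1:
            raise DuplicatePrimaryError(
                f"duplicate primary alignment for read {name!r} "
                f"(two records flagged the same mate)"
            )
        self.completed.add(name)
        r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
        assert r1.chrom is not None
        key = fragment_key_from_mates(r1, r2, self.chrom_ids.get(r1.chrom, 0))
        umi1 = extract_umi(r1.query_name, self.umi_delimiter, self.umi_prefix)
        r1.umi = r2.umi = umi1
        yield ReadPair(read1=r1, read2=r2, key=key, umi=umi1)

    def flush(self) -> Iterator[AlignedRead]:
        """End of chromosome / stream: remaining singletons are orphans."""
        for read in self.pending.values():
            self.orphans += 1
            yield read
        self.pending.clear()
        self.completed.clear()

    def min_pending_start(self) -> Optional[int]:
        if not self.pending:
            return None
        return min(r.ref_start for r in self.pending.values())


def pair_reads(
    stream: Iterable[AlignedRead],
    chrom_ids: Optional[dict[str, int]] = None,
    umi_delimiter: str = ":",
    umi_prefix: str = "UMI_",
) -> Iterator[Union[ReadPair, AlignedRead]]:
    """Convenience generator over MatePairer for whole-stream pairing."""
    pairer = MatePairer(
        chrom_ids=chrom_ids or {},
        umi_delimiter=umi_delimiter,
        umi_prefix=umi_prefix,
    )
    for read in stream:
        yield from pairer.feed(read)
    yield from pairer.flush()


# ---------------------------------------------------------------------------
# position-group state machine (processing-while-reading)
# ---------------------------------------------------------------------------

@dataclass
class GroupState:
    """Open position groups keyed by FragmentKey.

    A group is released as soon as the incoming pair's left position has moved
    past the group's right position (or onto a later chromosome): no further
    pair sharing that key can then arrive from a coordinate-sorted stream.
    """

    open_groups: dict[FragmentKey, list[ReadPair]] = field(default_factory=dict)

    def add(self, pair: ReadPair) -> None:
        self.open_groups.setdefault(pair.key, []).append(pair)

    def emit_completed(self, pair: ReadPair) -> list[tuple[FragmentKey, list[ReadPair]]]:
        done = [
            k
            for k in self.open_groups
            if k.chrom_id < pair.key.chrom_id
            or (k.chrom_id == pair.key.chrom_id and k.right_pos < pair.key.left_pos)
        ]
        done.sort(key=lambda k: k.sort_key())
        return [(k, self.open_groups.pop(k)) for k in done]

    def flush(self) -> list[tuple[FragmentKey, list[ReadPair]]]:
        done = sorted(self.open_groups, key=lambda k: k.sort_key())
        return [(k, self.open_groups.pop(k)) for k in done]

    def min_left(self) -> Optional[tuple[int, int]]:
        """(chrom_id, left_pos) lower bound over open groups, None when empty."""
        if not self.open_groups:
            return None
        return min((k.chrom_id, k.left_pos) for k in self.open_groups)


def emit_completed_groups(
    pair: ReadPair, state: GroupState
) -> list[tuple[FragmentKey, list[ReadPair]]]:
    """Functional wrapper: release every group no longer reachable by ``pair``."""
    return state.emit_completed(pair)


# ---------------------------------------------------------------------------
# sorted output (writing-while-processing)
# ---------------------------------------------------------------------------

class SortedWriter:
    """Position-keyed output queue in front of a BAM/SAM sink.

    Records are pushed with their coordinates and drained up to a watermark —
    the smallest position a still-unfinished group could yet emit — so the
    overall output is coordinate-sorted in a single pass. Unplaced reads sort
    after every chromosome.
    """

    def __init__(self, path: str, header: AlignmentHeaderInfo, program_args: str = ""):
        hd = header.pysam_header.to_dict()
        hd.setdefault("PG", []).append(
            {
                "ID": "consread",
                "PN": "consread",
                "VN": __version__,
                "CL": program_args or "consread",
            }
        )
        mode = "wb" if str(path).endswith(".bam") else "w"
        self._af = pysam.AlignmentFile(path, mode, header=hd)
        self._header = self._af.header
        self._chrom_ids = header.chrom_ids
        self._n_chroms = len(header.chromosomes)
        self._heap: list[tuple[int, int, int, AlignedRead]] = []
        self._seq = 0
        self._last_written: Optional[tuple[int, int]] = None

    def _pos_key(self, read: AlignedRead) -> tuple[int, int]:
        if read.chrom is None:
            return (self._n_chroms, 0)
        return (self._chrom_ids[read.chrom], max(read.ref_start, 0))

    def add(self, read: AlignedRead) -> None:
        cid, pos = self._pos_key(read)
        if self._last_written is not None and (cid, pos) < self._last_written:
            raise OutputOrderError(
                f"record {read.query_name} at ({cid},{pos}) arrived below the "
                f"written watermark {self._last_written}"
            )
        heapq.heappush(self._heap, (cid, pos, self._seq, read))
        self._seq += 1

    def drain(self, watermark: Optional[tuple[int, int]]) -> int:
        """Write every queued record strictly below ``watermark``
        ((chrom_id, pos); None means flush everything). Returns the count."""
        n = 0
        while self._heap and (
            watermark is None or self._heap[0][:2] < watermark
        ):
            cid, pos, _, read = heapq.heappop(self._heap)
            self._af.write(read_to_pysam(read, self._header))
            self._last_written = (cid, pos)
            n += 1
        return n

    def close(self) -> None:
        self.drain(None)
        self._af.close()

    def __enter__(self) -> "SortedWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def consensus_to_reads(
    cons: ConsensusRead,
    support_tag: str = "sp",
    duplex_tags: tuple[str, str] = ("da", "db"),
) -> tuple[AlignedRead, AlignedRead]:
    """Materialize a ConsensusRead as two output records cloned from the
    template, annotated with supporting-pair and duplex-orientation tags."""
    t1, t2 = cons.template.read1, cons.template.read2
    assert t2 is not None
    extra: list[tuple[str, object]] = [(support_tag, cons.supporting_pairs)]
    if cons.strand_counts != (0, 0):
        extra.append((duplex_tags[0], cons.strand_counts[0]))
        extra.append((duplex_tags[1], cons.strand_counts[1]))
    out = []
    for mate, seq, quals, mapq in (
        (t1, cons.seq1, cons.quals1, cons.mapq1),
        (t2, cons.seq2, cons.quals2, cons.mapq2),
    ):
        out.append(
            AlignedRead(
                query_name=mate.query_name,
                chrom=mate.chrom,
                ref_start=mate.ref_start,
                mapq=mapq,
                cigar=mate.cigar,
                seq=seq,
                quals=quals,
                flag=mate.flag,
                umi=mate.umi,
                rnext=mate.rnext,
                pnext=mate.pnext,
                tlen=mate.tlen,
                tags=list(mate.tags) + extra,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# reference and BED input
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """Uppercase random-access view of an indexed FASTA."""

    def __init__(self, path: str):
        self._fasta = Fasta(path, sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def _seq(self, chrom: str):
        if chrom not in self._fasta:
            raise ReferenceMissingError(
                f"chromosome {chrom!r} is absent from the reference FASTA"
            )
        return self._fasta[chrom]

    def get_base(self, chrom: str, pos0: int) -> str:
        seq = self._seq(chrom)
        if not 0 <= pos0 < len(seq):
            raise IndexError(f"{chrom}:{pos0} outside sequence of length {len(seq)}")
        return str(seq[pos0])

    def get_subseq(self, chrom: str, start0: int, end0: int) -> str:
        seq = self._seq(chrom)
        if not 0 <= start0 <= end0 <= len(seq):
            raise IndexError(f"{chrom}:{start0}-{end0} outside sequence")
        return str(seq[start0:end0])

    def lengths(self) -> dict[str, int]:
        return {name: len(self._fasta[name]) for name in self._fasta.keys()}

    def require_chromosomes(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self._fasta]
        if missing:
            raise ReferenceMissingError(
                "chromosomes present in the alignment header but absent from "
                "the reference FASTA: " + ", ".join(missing)
            )


def load_reference(path: str) -> ReferenceGenome:
    """Open an (indexed or indexable) reference FASTA."""
    return ReferenceGenome(path)


def load_bed(path: str) -> list[tuple[str, int, int]]:
    """Parse a 3+ column BED of capture regions (0-based half-open),
    sorted by (chrom, start). track/browser/# lines are skipped."""
    regions: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: region end {end} <= start {start}"
                )
            regions.append((chrom, start, end))
    regions.sort(key=lambda r: (r[0], r[1]))
    return regions
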