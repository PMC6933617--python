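"""Shared domain types and configuration for the consensus-read engine.

Coordinate conventions used throughout the package:

* all internal positions are 0-based; ranges are half-open,
* ``FragmentKey.right_pos`` is the 0-based *inclusive* rightmost aligned
  reference base of a read pair,
* Phred qualities are capped at 93 (the SAM printable range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MAX_PHRED = 93

#: CIGAR ops that consume the query sequence.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR ops that consume the reference.
REF_OPS = frozenset("MDN=X")
#: CIGAR ops aligned to the reference base-per-base.
ALIGNED_OPS = frozenset("M=X")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class ConsreadError(Exception):
    """Base class for all errors raised by this package."""


class UnsortedInputError(ConsreadError):
    """Input alignments are not coordinate-sorted (or the header does not say so)."""


class DuplicatePrimaryError(ConsreadError):
    """More than two primary alignments share one query name."""


class MalformedUmiError(ConsreadError):
    """A UMI string does not follow the single or dual (A_B) convention."""


class MixedUmiModeError(ConsreadError):
    """A position group mixes reads with and without UMIs."""


class DegenerateClusterError(ConsreadError):
    """Every cluster member was excluded from scoring (CIGAR/start mismatch)."""


class ReferenceMissingError(ConsreadError):
    """A chromosome required by the alignments is absent from the reference FASTA."""


class OutputOrderError(ConsreadError):
    """Internal contract violation: a record arrived below the written watermark."""


@dataclass
class AlignedRead:
    """One SAM record.

    ``flag`` is the raw SAM flag integer; the usual booleans are exposed as
    properties. ``tags`` keeps the record's aux tags so passthrough reads
    round-trip unchanged.
    """

    query_name: str
    chrom: Optional[str]
    ref_start: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    quals: list[int]
    flag: int
    umi: str = ""
    rnext: Optional[str] = None
    pnext: int = -1
    tlen: int = 0
    tags: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"{self.query_name}: seq length {len(self.seq)} != "
                f"quals length {len(self.quals)}"
            )
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"{self.query_name}: MAPQ {self.mapq} out of range")
        if any(q < 0 or q > MAX_PHRED for q in self.quals):
            raise ValueError(f"{self.query_name}: Phred quality out of [0, {MAX_PHRED}]")
        if self.cigar:
            for op, length in self.cigar:
                if op not in "MIDNSHP=X" or length < 1:
                    raise ValueError(f"{self.query_name}: bad CIGAR op ({op},{length})")
            qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.query_name}: CIGAR query length {qlen} != seq length "
                    f"{len(self.seq)}"
                )
            if not self.is_unmapped and self.ref_end <= self.ref_start:
                raise ValueError(f"{self.query_name}: empty reference span")

    # -- flag accessors ----------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FLAG_READ2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_primary_mapped(self) -> bool:
        return not (self.is_unmapped or self.is_secondary or self.is_supplementary)

    # -- coordinate helpers ------------------------------------------------
    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_OPS)

    def aligned_pairs(self) -> list[tuple[int, int]]:
        """(query_pos, ref_pos) for every M/=/X-aligned base, in query order."""
        out: list[tuple[int, int]] = []
        q = 0
        r = self.ref_start
        for op, n in self.cigar:
            if op in ALIGNED_OPS:
                out.extend((q + i, r + i) for i in range(n))
                q += n
                r += n
            elif op in ("I", "S"):
                q += n
            elif op in ("D", "N"):
                r += n
            # H and P consume nothing we track
        return out

    def ref_to_query(self) -> dict[int, int]:
        """Map reference position -> query index over aligned ops."""
        return {r: q for q, r in self.aligned_pairs()}


@dataclass(frozen=True)
class FragmentKey:
    """Position-clustering key: (chromosome, leftmost, rightmost-inclusive).

    ``chrom_id`` is the chromosome's index in the BAM header so the ordering
    matches coordinate sort; it does not take part in equality beyond chrom.
    """

    chrom: str
    left_pos: int
    right_pos: int
    chrom_id: int = 0

    def __post_init__(self) -> None:
        if self.left_pos > self.right_pos:
            raise ValueError(
                f"FragmentKey left {self.left_pos} > right {self.right_pos}"
            )

    def sort_key(self) -> tuple[int, int, int]:
        return (self.chrom_id, self.left_pos, self.right_pos)

    def __lt__(self, other: "FragmentKey") -> bool:
        return self.sort_key() < other.sort_key()


@dataclass
class ReadPair:
    """A mate-joined template. ``read2`` is absent only for orphans, which are
    passed through and never enter consensus generation."""

    read1: AlignedRead
    read2: Optional[AlignedRead]
    key: FragmentKey
    umi: str = ""

    def __post_init__(self) -> None:
        if self.read2 is not None:
            if self.read1.query_name != self.read2.query_name:
                raise ValueError("mates must share a query name")
            if self.read1.chrom != self.read2.chrom:
                raise ValueError("mates must share a chromosome")

    @property
    def mates(self) -> tuple[AlignedRead, ...]:
        return (self.read1,) if self.read2 is None else (self.read1, self.read2)

    @property
    def summed_mapq(self) -> int:
        return sum(m.mapq for m in self.mates)

    @property
    def query_name(self) -> str:
        return self.read1.query_name


@dataclass
class UmiCluster:
    """Read pairs sharing a FragmentKey and one canonical UMI (within
    tolerance); the unit of consensus generation. ``strand_counts`` holds the
    (A_B, B_A) dual-UMI orientation counts, (0, 0) for single UMIs."""

    key: FragmentKey
    canonical_umi: str
    members: list[ReadPair]
    strand_counts: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("UmiCluster needs at least one member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ScoringSchema:
    """Tunable scoring parameters.

    The initial per-base score (6), the supporting-reads threshold (1, i.e.
    no filtering) and the one-base UMI tolerance are the published defaults;
    the remaining values are this package's defaults, chosen so that a single
    disagreeing duplicate cannot outvote two agreeing ones, and are all
    configurable from the CLI.
    """

    initial_score: int = 6
    agree_bonus_score: int = 8
    disagree_keep_score: int = 3
    disagree_drop_score: int = 0
    high_qual: int = 30
    moderate_qual: int = 15
    dominant_fraction: float = 0.8
    min_supporting_reads: int = 1
    umi_tolerance: int = 1

    def __post_init__(self) -> None:
        if self.initial_score <= 0:
            raise ValueError("initial_score must be > 0")
        if self.high_qual < self.moderate_qual:
            raise ValueError("high_qual must be >= moderate_qual")
        if not 0.5 < self.dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must be in (0.5, 1]")
        if self.min_supporting_reads < 1:
            raise ValueError("min_supporting_reads must be >= 1")
        if self.umi_tolerance < 0:
            raise ValueError("umi_tolerance must be >= 0")


@dataclass
class MateScores:
    """Per-mate per-position summed base scores for one cluster.

    ``scores[i, b]`` sums the pair scores of members carrying base ``b``
    (A/C/G/T) at query position ``i``; ``coverage[i]`` counts covering
    members (N included); ``max_phred[i, b]`` is the highest observed Phred
    among members carrying ``b`` (−1 when none does).
    """

    scores: np.ndarray      # (L, 4) int64
    coverage: np.ndarray    # (L,) int64
    max_phred: np.ndarray   # (L, 4) int64, -1 = unseen

    @classmethod
    def empty(cls, length: int) -> "MateScores":
        return cls(
            scores=np.zeros((length, 4), dtype=np.int64),
            coverage=np.zeros(length, dtype=np.int64),
            max_phred=np.full((length, 4), -1, dtype=np.int64),
        )


@dataclass
class ScoreMatrix:
    """Summed scores for both mates of a cluster, plus bookkeeping on how many
    members were excluded for not matching the template's CIGAR/start."""

    key: FragmentKey
    read1: MateScores
    read2: MateScores
    included_members: int
    excluded_members: int


@dataclass
class ConsensusRead:
    """The merged output of one cluster."""

    template: ReadPair
    seq1: str
    quals1: list[int]
    seq2: str
    quals2: list[int]
    supporting_pairs: int
    strand_counts: tuple[int, int] = (0, 0)
    ref_corrected_positions1: list[int] = field(default_factory=list)
    ref_corrected_positions2: list[int] = field(default_factory=list)
    mapq1: int = 0
    mapq2: int = 0

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.template.read1.seq):
            raise ValueError("consensus read1 length != template length")
        if self.template.read2 is not None and len(self.seq2) != len(
            self.template.read2.seq
        ):
            raise ValueError("consensus read2 length != template length")
        if self.supporting_pairs < 1:
            raise ValueError("supporting_pairs must be >= 1")


@dataclass
class PhaseCounters:
    """Read/base counters for one phase (pre- or post-processing)."""

    total_reads: int = 0
    mapped_reads: int = 0
    total_bases: int = 0
    aligned_bases: int = 0
    mismatched_bases: int = 0

    @property
    def mapping_rate(self) -> Optional[float]:
        return None if self.total_reads == 0 else self.mapped_reads / self.total_reads

    @property
    def mismatch_rate(self) -> Optional[float]:
        if self.aligned_bases == 0:
            return None
        return self.mismatched_bases / self.aligned_bases


@dataclass
class RunStats:
    """Pre/post counters feeding the JSON/HTML reports."""

    pre: PhaseCounters = field(default_factory=PhaseCounters)
    post: PhaseCounters = field(default_factory=PhaseCounters)
    duplication_histogram: dict[int, int] = field(default_factory=dict)
    clusters_total: int = 0
    clusters_passing: int = 0
    pairs_total: int = 0
    orphan_pairs: int = 0
    passthrough_reads: int = 0
    consensus_written: int = 0
    excluded_members: int = 0
    ref_corrected_bases: int = 0
    # phase -> chrom -> bin index -> aligned-base count
    coverage_bins: dict[str, dict[str, dict[int, int]]] = field(
        default_factory=lambda: {"pre": {}, "post": {}}
    )
    # (chrom, start, end) regions and their aligned-base accumulators per phase
    bed_regions: list[tuple[str, int, int]] = field(default_factory=list)
    bed_bases: dict[str, list[int]] = field(
        default_factory=lambda: {"pre": [], "post": []}
    )

    def phase(self, name: str) -> PhaseCounters:
        if name not in ("pre", "post"):
            raise ValueError(f"unknown phase {name!r}")
        return self.pre if name == "pre" else self.post
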