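"""Position and UMI clustering.

Read pairs are first grouped by their mapping coordinates (chromosome,
leftmost, rightmost position). Within each position group, pairs are then
clustered by UMI with a configurable Hamming tolerance (default one base).
Dual UMIs written ``A_B`` are duplex barcodes: reads from the opposite strand
of the same fragment carry ``B_A``, so both forms are mapped to one canonical
key before clustering. Finally each cluster is compared against the
supporting-reads threshold (default 1, i.e. no filtering; 2 is recommended
for ultra-deep data so that fragments without any PCR duplicate are dropped).
"""

from __future__ import annotations

from collections import OrderedDict

from .core_model import (
    AlignedRead,
    FragmentKey,
    MalformedUmiError,
    MixedUmiModeError,
    ReadPair,
    ScoringSchema,
    UmiCluster,
)

#: Sentinel distance for structurally incomparable UMIs.
INF_DISTANCE = 10**9

UMI_ALPHABET = frozenset("ACGTN_")


def fragment_key_from_mates(
    read1: AlignedRead, read2: AlignedRead, chrom_id: int = 0
) -> FragmentKey:
    """Key = (chrom, min ref_start, max ref_end − 1) over the two mates.

    Soft clips consume no reference, so a leading ``5S45M`` mate starts at its
    POS field like any other.
    """
    if read1.chrom != read2.chrom or read1.chrom is None:
        raise ValueError("fragment key requires both mates mapped to one chromosome")
    left = min(read1.ref_start, read2.ref_start)
    right = max(read1.ref_end, read2.ref_end) - 1
    return FragmentKey(read1.chrom, left, right, chrom_id)


def fragment_key(pair: ReadPair, chrom_id: int = 0) -> FragmentKey:
    """Recompute the FragmentKey of a mate-joined pair."""
    if pair.read2 is None:
        raise ValueError("fragment key requires both mates")
    return fragment_key_from_mates(pair.read1, pair.read2, chrom_id)


def extract_umi(query_name: str, delimiter: str = ":", prefix: str = "UMI_") -> str:
    """Pull the UMI from a read name.

    Preprocessors (e.g. fastp) move UMIs from the read sequence into the read
    identifier, conventionally as the final ``delimiter``-separated field.
    Returns the substring after the last delimiter with ``prefix`` stripped
    when present, or "" when the name carries no recognizable UMI (which
    switches that read to non-UMI mode).
    """
    if delimiter not in query_name:
        return ""
    tail = query_name.rsplit(delimiter, 1)[1]
    if prefix and tail.startswith(prefix):
        tail = tail[len(prefix):]
    if tail and all(c in UMI_ALPHABET for c in tail):
        return tail
    return ""


def canonical_umi(umi: str) -> tuple[str, bool]:
    """Canonicalize a UMI; returns (canonical form, was_swapped).

    Single UMIs are returned unchanged. A dual UMI ``A_B`` and its reciprocal
    ``B_A`` come from the two strands of one fragment and must share a key:
    the lexicographically smaller of the two orderings is canonical.
    ``was_swapped`` is True when the input was the non-canonical orientation,
    which feeds the duplex strand counts.
    """
    n_sep = umi.count("_")
    if n_sep == 0:
        return umi, False
    if n_sep > 1:
        raise MalformedUmiError(f"malformed UMI {umi!r}: more than one '_'")
    a, b = umi.split("_")
    swapped = f"{b}_{a}"
    if swapped < umi:
        return swapped, True
    return umi, False


def umi_distance(u1: str, u2: str) -> int:
    """Distance between two canonical UMIs.

    Single UMIs: Hamming distance (length mismatch -> INF_DISTANCE sentinel).
    Dual UMIs: the minimum over the direct and the swapped part alignment of
    the summed part-wise Hamming distances. N counts as a difference.
    """
    dual1 = "_" in u1
    dual2 = "_" in u2
    if dual1 != dual2:
        return INF_DISTANCE
    if not dual1:
        return _hamming(u1, u2)
    a1, b1 = u1.split("_")
    a2, b2 = u2.split("_")
    direct = _add(_hamming(a1, a2), _hamming(b1, b2))
    crossed = _add(_hamming(a1, b2), _hamming(b1, a2))
    return min(direct, crossed)


def _hamming(s1: str, s2: str) -> int:
    if len(s1) != len(s2):
        return INF_DISTANCE
    return sum(c1 != c2 for c1, c2 in zip(s1, s2))


def _add(d1: int, d2: int) -> int:
    return INF_DISTANCE if INF_DISTANCE in (d1, d2) else d1 + d2


def cluster_by_umi(
    pairs: list[ReadPair], schema: ScoringSchema
) -> list[UmiCluster]:
    """Cluster the read pairs of one position group by UMI.

    Greedy seed-based merging: distinct canonical UMIs are visited in order of
    descending support (ties broken lexicographically); each joins the first
    existing cluster whose *seed* UMI is within ``schema.umi_tolerance``, else
    seeds a new cluster. Distances are measured to the seed only — no
    transitive chaining — so unrelated UMIs cannot link through intermediates.

    In non-UMI mode (all UMIs empty) the whole group is one cluster. Mixing
    reads with and without UMIs in one group is an input error.
    """
    if not pairs:
        return []
    key = pairs[0].key
    n_with = sum(1 for p in pairs if p.umi)
    if n_with == 0:
        return [UmiCluster(key=key, canonical_umi="", members=list(pairs))]
    if n_with != len(pairs):
        raise MixedUmiModeError(
            f"inconsistent UMI presence in group {key.chrom}:{key.left_pos}-"
            f"{key.right_pos}: {n_with}/{len(pairs)} reads carry a UMI"
        )

    # canonical UMI -> (members, n_ab, n_ba)
    by_canon: OrderedDict[str, list] = OrderedDict()
    for p in pairs:
        canon, swapped = canonical_umi(p.umi)
        entry = by_canon.setdefault(canon, [[], 0, 0])
        entry[0].append(p)
        is_dual = "_" in canon
        if is_dual:
            entry[2 if swapped else 1] += 1

    order = sorted(by_canon, key=lambda u: (-len(by_canon[u][0]), u))
    clusters: list[list] = []  # [seed, members, n_ab, n_ba]
    for canon in order:
        members, n_ab, n_ba = by_canon[canon]
        for cl in clusters:
            if umi_distance(cl[0], canon) <= schema.umi_tolerance:
                cl[1].extend(members)
                cl[2] += n_ab
                cl[3] += n_ba
                break
        else:
            clusters.append([canon, list(members), n_ab, n_ba])

    return [
        UmiCluster(
            key=key,
            canonical_umi=seed,
            members=members,
            strand_counts=(n_ab, n_ba),
        )
        for seed, members, n_ab, n_ba in clusters
    ]


def passes_filter(cluster: UmiCluster, schema: ScoringSchema) -> bool:
    """Supporting-reads filter: keep a cluster iff it has at least
    ``schema.min_supporting_reads`` member pairs."""
    return len(cluster.members) >= schema.min_supporting_reads
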