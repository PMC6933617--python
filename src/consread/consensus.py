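"""Pair scoring, cluster scoring and reference-aware consensus calling.

Every base starts with the initial score (default 6). Where the two mates of
a pair overlap on the reference, agreement raises both scores (default 8) and
disagreement keeps a reduced score (default 3) on the higher-quality base
while zeroing the other. Per-cluster, the pair scores are summed per query
position and base; the consensus base is the dominant base when one exists,
otherwise the reference base when reads concordant with the reference are
high-quality (or everything is low-quality) — a base discordant with the
reference is more likely a sequencing error, so read evidence alone does not
override the reference unless it dominates.
"""

from __future__ import annotations

from typing import Optional, Protocol

import numpy as np

from .core_model import (
    BASE_INDEX,
    BASES,
    MAX_PHRED,
    ConsensusRead,
    DegenerateClusterError,
    MateScores,
    ReadPair,
    ScoreMatrix,
    ScoringSchema,
    UmiCluster,
)

#: Phred assigned to unresolved (low-confidence) consensus columns.
LOW_CONFIDENCE_QUAL = 2


class ReferenceAccessor(Protocol):
    def get_base(self, chrom: str, pos0: int) -> str: ...
    def get_subseq(self, chrom: str, start0: int, end0: int) -> str: ...


def score_pair(
    pair: ReadPair, schema: ScoringSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Per-mate integer score arrays for one read pair.

    All bases start at ``initial_score``. For every reference position covered
    by both mates (M/=/X ops only): agreement sets both scores to
    ``agree_bonus_score``; disagreement keeps ``disagree_keep_score`` on the
    strictly higher-quality base and ``disagree_drop_score`` on the other;
    equal qualities drop both.
    """
    if pair.read2 is None:
        raise ValueError("score_pair requires both mates (orphans not allowed)")
    r1, r2 = pair.read1, pair.read2
    s1 = np.full(len(r1.seq), schema.initial_score, dtype=np.int64)
    s2 = np.full(len(r2.seq), schema.initial_score, dtype=np.int64)

    map2 = r2.ref_to_query()
    for q1, rpos in r1.aligned_pairs():
        q2 = map2.get(rpos)
        if q2 is None:
            continue
        if r1.seq[q1] == r2.seq[q2]:
            s1[q1] = schema.agree_bonus_score
            s2[q2] = schema.agree_bonus_score
        elif r1.quals[q1] > r2.quals[q2]:
            s1[q1] = schema.disagree_keep_score
            s2[q2] = schema.disagree_drop_score
        elif r2.quals[q2] > r1.quals[q1]:
            s1[q1] = schema.disagree_drop_score
            s2[q2] = schema.disagree_keep_score
        else:
            s1[q1] = schema.disagree_drop_score
            s2[q2] = schema.disagree_drop_score
    return s1, s2


def select_template(cluster: UmiCluster) -> ReadPair:
    """Cluster representative: highest summed mate MAPQ, ties broken by the
    lexicographically smallest query name (deterministic)."""
    return min(cluster.members, key=lambda p: (-p.summed_mapq, p.query_name))


def _member_matches_template(member: ReadPair, template: ReadPair) -> bool:
    # Same per-mate CIGAR and start; members already share the FragmentKey.
    return (
        member.read1.cigar == template.read1.cigar
        and member.read1.ref_start == template.read1.ref_start
        and member.read2 is not None
        and template.read2 is not None
        and member.read2.cigar == template.read2.cigar
        and member.read2.ref_start == template.read2.ref_start
    )


def score_cluster(
    cluster: UmiCluster,
    schema: ScoringSchema,
    template: Optional[ReadPair] = None,
) -> tuple[ScoreMatrix, ReadPair]:
    """Sum per-pair scores into per-position per-base totals.

    Members whose per-mate CIGAR or start differs from the template cannot be
    laid onto the template's query coordinates and are excluded (counted, not
    realigned). N bases contribute zero score but count as coverage.
    """
    if template is None:
        template = select_template(cluster)
    if template.read2 is None:
        raise ValueError("cluster template must be a full pair")

    m1 = MateScores.empty(len(template.read1.seq))
    m2 = MateScores.empty(len(template.read2.seq))
    included = 0
    for member in cluster.members:
        if not _member_matches_template(member, template):
            continue
        included += 1
        s1, s2 = score_pair(member, schema)
        _accumulate(m1, member.read1.seq, member.read1.quals, s1)
        _accumulate(m2, member.read2.seq, member.read2.quals, s2)
    if included == 0:
        raise DegenerateClusterError(
            f"all {len(cluster.members)} members excluded by CIGAR mismatch"
        )
    matrix = ScoreMatrix(
        key=cluster.key,
        read1=m1,
        read2=m2,
        included_members=included,
        excluded_members=len(cluster.members) - included,
    )
    return matrix, template


def _accumulate(m: MateScores, seq: str, quals: list[int], scores: np.ndarray) -> None:
    for i, base in enumerate(seq):
        m.coverage[i] += 1
        b = BASE_INDEX.get(base)
        if b is None:  # N: covers, scores nothing
            continue
        m.scores[i, b] += scores[i]
        if quals[i] > m.max_phred[i, b]:
            m.max_phred[i, b] = quals[i]


def call_consensus_base(
    scores: np.ndarray,
    max_phred: np.ndarray,
    ref_base: Optional[str],
    schema: ScoringSchema,
) -> tuple[str, int, bool]:
    """Call one consensus column; returns (base, phred, ref_override).

    Rule order:

    a. a unique dominant base (share of total score >= ``dominant_fraction``)
       wins, with quality = the best Phred among reads carrying it;
    b. otherwise the reference base is used when some read carries it at
       >= ``high_qual``, or when every covering read is below
       ``moderate_qual`` (quality = ``moderate_qual``);
    c. otherwise the highest-scoring base, ties resolved to the reference
       base when it is among them and alphabetically else, flagged Phred 2.

    A zero-score column (all N) falls back to the reference at Phred 2.
    ``ref_base=None`` disables the reference fallback entirely (insertion and
    soft-clip columns have no reference base); there, rule (a) then rule (c)
    apply, and an all-N column calls N.
    """
    s_tot = int(scores.sum())
    if s_tot == 0:
        if ref_base is None:
            return "N", LOW_CONFIDENCE_QUAL, False
        return ref_base, LOW_CONFIDENCE_QUAL, True

    s_max = int(scores.max())
    top = [i for i in range(4) if scores[i] == s_max]
    if len(top) == 1 and s_max / s_tot >= schema.dominant_fraction:
        b = top[0]
        qual = int(max_phred[b]) if max_phred[b] >= 0 else LOW_CONFIDENCE_QUAL
        return BASES[b], qual, False

    if ref_base is not None and ref_base in BASE_INDEX:
        ref_i = BASE_INDEX[ref_base]
        ref_high = max_phred[ref_i] >= schema.high_qual
        all_low = int(max_phred.max()) < schema.moderate_qual
        if ref_high or all_low:
            return ref_base, schema.moderate_qual, True
        if ref_i in top:
            return ref_base, LOW_CONFIDENCE_QUAL, False
    return BASES[top[0]], LOW_CONFIDENCE_QUAL, False


def build_consensus_pair(
    cluster: UmiCluster,
    reference: Optional[ReferenceAccessor],
    schema: ScoringSchema,
) -> ConsensusRead:
    """Merge one cluster into a consensus read pair.

    The template contributes name, flags, positions and CIGARs; every query
    position is called column-by-column. M/=/X positions are called against
    the reference base; insertion/soft-clip positions have no reference base
    and use the dominant-or-highest-score rule only. A degenerate cluster
    (every member excluded) emits the template pair unchanged.
    """
    template = select_template(cluster)
    try:
        matrix, template = score_cluster(cluster, schema, template)
    except DegenerateClusterError:
        assert template.read2 is not None
        return ConsensusRead(
            template=template,
            seq1=template.read1.seq,
            quals1=list(template.read1.quals),
            seq2=template.read2.seq,
            quals2=list(template.read2.quals),
            supporting_pairs=1,
            strand_counts=cluster.strand_counts,
            mapq1=template.read1.mapq,
            mapq2=template.read2.mapq,
        )

    assert template.read2 is not None
    seq1, quals1, corrected1 = _call_mate(template.read1, matrix.read1, reference, schema)
    seq2, quals2, corrected2 = _call_mate(template.read2, matrix.read2, reference, schema)
    mapq1 = max(m.read1.mapq for m in cluster.members)
    mapq2 = max(m.read2.mapq for m in cluster.members if m.read2 is not None)
    return ConsensusRead(
        template=template,
        seq1=seq1,
        quals1=quals1,
        seq2=seq2,
        quals2=quals2,
        supporting_pairs=matrix.included_members,
        strand_counts=cluster.strand_counts,
        ref_corrected_positions1=corrected1,
        ref_corrected_positions2=corrected2,
        mapq1=mapq1,
        mapq2=mapq2,
    )


def _call_mate(
    read, mate_scores: MateScores, reference: Optional[ReferenceAccessor], schema
) -> tuple[str, list[int], list[int]]:
    qpos_to_ref = {q: r for q, r in read.aligned_pairs()}
    seq = []
    quals = []
    corrected = []
    for i in range(len(read.seq)):
        ref_base: Optional[str] = None
        rpos = qpos_to_ref.get(i)
        if rpos is not None and reference is not None:
            ref_base = reference.get_base(read.chrom, rpos)
        base, qual, overridden = call_consensus_base(
            mate_scores.scores[i], mate_scores.max_phred[i], ref_base, schema
        )
        if overridden and base != read.seq[i]:
            corrected.append(i)
        seq.append(base)
        quals.append(min(qual, MAX_PHRED))
    return "".join(seq), quals, corrected
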