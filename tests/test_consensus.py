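import numpy as np
import pytest

from consread.consensus import (
    build_consensus_pair,
    call_consensus_base,
    score_cluster,
    score_pair,
    select_template,
)
from consread.core_model import ScoringSchema, UmiCluster

from .conftest import mk_pair

SCHEMA = ScoringSchema()


class FlatReference:
    """Reference stub returning one fixed base everywhere."""

    def __init__(self, base="A"):
        self.base = base

    def get_base(self, chrom, pos0):
        return self.base

    def get_subseq(self, chrom, start0, end0):
        return self.base * (end0 - start0)


class SeqReference:
    def __init__(self, seq, chrom="chr1"):
        self.seq = seq

    def get_base(self, chrom, pos0):
        return self.seq[pos0]

    def get_subseq(self, chrom, start0, end0):
        return self.seq[start0:end0]


def one_cluster(*pairs):
    return UmiCluster(key=pairs[0].key, canonical_umi="", members=list(pairs))


# ---------------------------------------------------------------------------
# score_pair
# ---------------------------------------------------------------------------

class TestScorePair:
    def test_non_overlapping_mates_keep_initial_score(self):
        pair = mk_pair(start1=0, start2=180, cigar1="50M", cigar2="50M")
        s1, s2 = score_pair(pair, SCHEMA)
        assert (s1 == 6).all() and (s2 == 6).all()

    def test_fully_overlapping_identical_mates_get_agree_bonus(self):
        pair = mk_pair(start1=0, start2=0, seq1="ACGT" * 5, seq2="ACGT" * 5,
                       cigar1="20M", cigar2="20M")
        s1, s2 = score_pair(pair, SCHEMA)
        assert (s1 == 8).all() and (s2 == 8).all()

    def test_disagreement_rewards_higher_quality_base(self):
        # mates overlap at exactly one position: read1 pos 49 == read2 pos 0
        seq1 = "C" * 49 + "A"
        seq2 = "C" * 50
        pair = mk_pair(start1=0, start2=49, seq1=seq1, seq2=seq2,
                       quals1=30, quals2=10)
        s1, s2 = score_pair(pair, SCHEMA)
        assert s1[49] == 3 and s2[0] == 0      # A at Q30 beats C at Q10
        assert (s1[:49] == 6).all() and (s2[1:] == 6).all()

    def test_equal_quality_disagreement_drops_both(self):
        pair = mk_pair(start1=0, start2=49, seq1="C" * 49 + "A", seq2="C" * 50,
                       quals1=30, quals2=30)
        s1, s2 = score_pair(pair, SCHEMA)
        assert s1[49] == 0 and s2[0] == 0

    def test_orphan_pair_rejected(self):
        pair = mk_pair()
        pair.read2 = None
        with pytest.raises(ValueError):
            score_pair(pair, SCHEMA)


# ---------------------------------------------------------------------------
# score_cluster
# ---------------------------------------------------------------------------

class TestScoreCluster:
    def test_summation_over_identical_members(self):
        # 3 identical pairs, non-overlapping mates, base A everywhere
        pairs = [mk_pair(name=f"m{i}", start1=0, start2=180) for i in range(3)]
        matrix, _ = score_cluster(one_cluster(*pairs), SCHEMA)
        assert (matrix.read1.scores[:, 0] == 18).all()      # 3 x 6 for A
        assert (matrix.read1.scores[:, 1:] == 0).all()
        assert (matrix.read1.coverage == 3).all()

    def test_disagreeing_member_scores_split_by_base(self):
        base_kw = dict(start1=0, start2=180)
        pairs = [
            mk_pair(name="a1", seq1="A" * 50, **base_kw),
            mk_pair(name="a2", seq1="A" * 50, **base_kw),
            mk_pair(name="c1", seq1="C" + "A" * 49, **base_kw),
        ]
        matrix, _ = score_cluster(one_cluster(*pairs), SCHEMA)
        assert matrix.read1.scores[0, 0] == 12      # A: 2 x 6
        assert matrix.read1.scores[0, 1] == 6       # C: 1 x 6

    def test_singleton_cluster_equals_score_pair(self):
        pair = mk_pair(start1=0, start2=0, seq1="ACGT" * 5, seq2="ACGT" * 5,
                       cigar1="20M", cigar2="20M")
        matrix, _ = score_cluster(one_cluster(pair), SCHEMA)
        s1, _ = score_pair(pair, SCHEMA)
        for i, base in enumerate(pair.read1.seq):
            assert matrix.read1.scores[i, "ACGT".index(base)] == s1[i]

    def test_cigar_mismatch_excluded_not_realigned(self):
        template = mk_pair(name="a", start1=0, start2=10, cigar1="50M", cigar2="50M")
        other = mk_pair(name="b", start1=0, start2=10, cigar1="5S45M5D", cigar2="50M")
        assert other.key == template.key  # same fragment key, different CIGAR
        matrix, tmpl = score_cluster(one_cluster(template, other), SCHEMA)
        assert matrix.included_members == 1
        assert matrix.excluded_members == 1

    def test_score_conservation_per_column(self):
        """Column totals equal the sum of the members' per-base pair scores."""
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(4):
            seq1 = "".join(rng.choice(list("ACGT"), 30))
            seq2 = "".join(rng.choice(list("ACGT"), 30))
            pairs.append(
                mk_pair(name=f"m{i}", start1=0, start2=15,
                        cigar1="30M", cigar2="30M", seq1=seq1, seq2=seq2,
                        quals1=list(rng.integers(5, 40, 30)),
                        quals2=list(rng.integers(5, 40, 30)))
            )
        matrix, _ = score_cluster(one_cluster(*pairs), SCHEMA)
        expected = np.zeros(30, dtype=int)
        for p in pairs:
            s1, _ = score_pair(p, SCHEMA)
            expected += s1
        assert (matrix.read1.scores.sum(axis=1) == expected).all()


# ---------------------------------------------------------------------------
# call_consensus_base
# ---------------------------------------------------------------------------

def _col(scores: dict, phreds: dict):
    s = np.zeros(4, dtype=np.int64)
    q = np.full(4, -1, dtype=np.int64)
    for b, v in scores.items():
        s["ACGT".index(b)] = v
    for b, v in phreds.items():
        q["ACGT".index(b)] = v
    return s, q


class TestCallConsensusBase:
    def test_unanimous_dominant_base_wins_over_reference(self):
        s, q = _col({"A": 18}, {"A": 35})
        assert call_consensus_base(s, q, "C", SCHEMA) == ("A", 35, False)

    def test_no_dominant_high_quality_reference_concordance(self):
        s, q = _col({"A": 6, "C": 6}, {"A": 30, "C": 35})
        base, qual, overridden = call_consensus_base(s, q, "C", SCHEMA)
        assert (base, qual, overridden) == ("C", SCHEMA.moderate_qual, True)

    def test_all_low_quality_falls_back_to_reference(self):
        s, q = _col({"T": 6, "G": 6}, {"T": 5, "G": 5})
        base, qual, overridden = call_consensus_base(s, q, "A", SCHEMA)
        assert (base, qual, overridden) == ("A", SCHEMA.moderate_qual, True)

    def test_low_quality_but_dominant_base_still_wins(self):
        s, q = _col({"T": 12}, {"T": 5})
        assert call_consensus_base(s, q, "A", SCHEMA)[0] == "T"

    def test_unresolved_column_flagged_low_confidence(self):
        # no dominant base, reference not carried at high quality, not all low
        s, q = _col({"A": 6, "C": 6}, {"A": 20, "C": 20})
        base, qual, _ = call_consensus_base(s, q, "G", SCHEMA)
        assert base == "A" and qual == 2

    def test_tie_prefers_reference_base(self):
        s, q = _col({"A": 6, "C": 6}, {"A": 20, "C": 20})
        base, qual, _ = call_consensus_base(s, q, "C", SCHEMA)
        assert base == "C" and qual == 2

    def test_zero_score_column_uses_reference(self):
        s, q = _col({}, {})
        assert call_consensus_base(s, q, "G", SCHEMA) == ("G", 2, True)

    def test_no_reference_column_disables_fallback(self):
        s, q = _col({"A": 6, "C": 6}, {"A": 35, "C": 35})
        base, qual, overridden = call_consensus_base(s, q, None, SCHEMA)
        assert base == "A" and not overridden


# ---------------------------------------------------------------------------
# build_consensus_pair
# ---------------------------------------------------------------------------

class TestBuildConsensusPair:
    def _ref_for(self, pair):
        # a reference agreeing with the template everywhere it aligns
        seq = ["A"] * 400
        for mate in pair.mates:
            for q, r in mate.aligned_pairs():
                seq[r] = mate.seq[q]
        return SeqReference("".join(seq))

    def test_single_error_outvoted_by_duplicates(self):
        """One Q30 error among five duplicates disappears: 4x6=24 of 30 total
        is dominant, so the error-free base is called."""
        good = "G" * 50
        bad = "T" + "G" * 49
        pairs = [mk_pair(name=f"d{i}", start1=0, start2=180, seq1=good, seq2=good)
                 for i in range(4)]
        pairs.append(mk_pair(name="d4", start1=0, start2=180, seq1=bad, seq2=good))
        ref = self._ref_for(pairs[0])
        cons = build_consensus_pair(one_cluster(*pairs), ref, SCHEMA)
        assert cons.seq1 == good
        assert cons.supporting_pairs == 5

    def test_identity_on_clean_singleton(self):
        pair = mk_pair(start1=0, start2=180, seq1="C" * 50, seq2="T" * 50)
        ref = self._ref_for(pair)
        cons = build_consensus_pair(one_cluster(pair), ref, SCHEMA)
        assert cons.seq1 == pair.read1.seq
        assert cons.seq2 == pair.read2.seq

    def test_shared_true_variant_is_retained(self):
        """A variant carried by every duplicate survives even though it
        disagrees with the reference."""
        variant_seq = "T" + "A" * 49
        pairs = [mk_pair(name=f"d{i}", start1=0, start2=180, seq1=variant_seq)
                 for i in range(3)]
        ref = FlatReference("A")  # reference says A at the variant position
        cons = build_consensus_pair(one_cluster(*pairs), ref, SCHEMA)
        assert cons.seq1[0] == "T"

    def test_template_is_best_mapq_then_name(self):
        pairs = [
            mk_pair(name="b", mapq=60),
            mk_pair(name="a", mapq=60),
            mk_pair(name="z", mapq=20),
        ]
        assert select_template(one_cluster(*pairs)).query_name == "a"

    def test_monotonicity_agreeing_member_never_changes_call(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(1, 5))
            seq1 = "".join(rng.choice(list("ACGT"), 20))
            seq2 = "".join(rng.choice(list("ACGT"), 20))
            pairs = [
                mk_pair(name=f"m{i}", start1=0, start2=30,
                        cigar1="20M", cigar2="20M", seq1=seq1, seq2=seq2,
                        quals1=list(rng.integers(5, 40, 20)),
                        quals2=list(rng.integers(5, 40, 20)))
                for i in range(n)
            ]
            ref = FlatReference("A")
            cons = build_consensus_pair(one_cluster(*pairs), ref, SCHEMA)
            extra = mk_pair(name="zz", start1=0, start2=30, cigar1="20M",
                            cigar2="20M", seq1=cons.seq1, seq2=cons.seq2,
                            quals1=35, quals2=35)
            cons2 = build_consensus_pair(one_cluster(*pairs, extra), ref, SCHEMA)
            assert cons2.seq1 == cons.seq1
            assert cons2.seq2 == cons.seq2
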