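# Methods

## Model and assumptions

`consread` treats a coordinate-sorted paired-end BAM as a stream of
*fragment observations*: each properly mapped pair is one observation of an
original DNA fragment, identified by its mapping coordinates
`(chrom, left_pos, right_pos)` and, when present, a molecular barcode (UMI)
embedded in the read name. Observations of one fragment differ only by
amplification and sequencing errors, which are assumed random and
independent per base — this is what lets a consensus over duplicates remove
them while systematic differences (real variants) survive.

Assumptions the engine relies on:

* input is coordinate-sorted and both mates of an intra-chromosomal pair are
  mapped to the same chromosome (verified while streaming; violations are
  fatal or pass through, see below);
* duplicates of one fragment share their mapping coordinates exactly — the
  position key uses no tolerance window;
* UMIs, when used, appear as the last `:`-separated field of the read name
  (fastp's convention; delimiter and the optional `UMI_` prefix are
  configurable), dual UMIs as `A_B` with the opposite strand writing `B_A`;
* substitution errors dominate; indel errors are not modelled (a member
  whose CIGAR differs from its cluster's template is excluded from scoring,
  not realigned).

## Coordinates and conventions

Internally everything is 0-based; ranges are half-open except
`FragmentKey.right_pos`, which is the 0-based *inclusive* rightmost aligned
base (so two 50 bp mates at 100 and 180 give the key `(chr, 100, 229)`).
SAM emission converts back through pysam. Phred qualities are capped at 93.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `initial_score` | 6 | score assigned to every base before mate-overlap adjustment |
| `agree_bonus_score` | 8 | both mates' score where overlapped bases agree |
| `disagree_keep_score` | 3 | kept by the strictly higher-quality base on disagreement |
| `disagree_drop_score` | 0 | the lower-quality (or tied) base on disagreement |
| `high_qual` | Q30 | reference-concordant read at/above this enables reference fallback |
| `moderate_qual` | Q15 | below this on every covering read also enables reference fallback; also the quality of reference-fallback calls |
| `dominant_fraction` | 0.8 | share of a column's total score a base needs to win outright |
| `min_supporting_reads` | 1 | cluster filter; 1 = no filtering, 2 recommended for ultra-deep data |
| `umi_tolerance` | 1 | Hamming tolerance (bases) for UMI clustering |

The initial score, the supporting-reads threshold and the one-base UMI
tolerance are the published defaults of this method family. The remaining
scoring values are this package's own defaults: they are chosen so that two
agreeing duplicates always outvote one disagreeing duplicate
(6+6 = 12 > 6, and 12/18 < 0.8 keeps a 2-vs-1 column from being called
against the reference unless the pair-overlap bonus tips it), and so that a
mate-confirmed base (8) outranks an unconfirmed one (6) outranks a
mate-contradicted one (3 or 0). All are CLI-tunable.

## Consensus calling rules

Per column, with per-base summed scores `S(b)`, total `S_tot`, and the best
observed Phred `Q(b)` per base:

1. a unique base with `S(b)/S_tot ≥ dominant_fraction` is called at `Q(b)`;
2. else the reference base is called at `moderate_qual` when `Q(ref) ≥
   high_qual` or when `max_b Q(b) < moderate_qual`;
3. else the top-scoring base is called at Phred 2 (low-confidence flag),
   ties resolved to the reference base if tied, alphabetically otherwise;
4. a zero-score column (all N) calls the reference base at Phred 2.

Insertion and soft-clip columns have no reference base; rules 2 and 4's
fallback are disabled there (rule 4 calls N). The published description says
bases discordant with the reference get "lower weight"; that is realized
here purely through the rule order — read evidence must *dominate* to beat
the reference — not as a multiplicative weight, which was never quantified.

Design choices where the method description was open:

* **Template selection**: the member with the highest summed mate MAPQ, ties
  broken by smallest query name — deterministic and favors the best mapping.
* **UMI merge topology**: greedy, non-transitive. Distinct canonical UMIs
  are visited by descending support (lexicographic tie-break) and join the
  first cluster whose *seed* is within tolerance. No chaining means two
  unrelated UMIs cannot merge through an intermediate. N counts as a
  mismatch (conservative).
* **Orphans** (mate unmapped, on another chromosome, or never seen) pass
  through unchanged and are counted; merging single-read evidence would
  bypass the pair-overlap scoring. Unmapped, secondary and supplementary
  records also pass through rather than being rejected.
* **Consensus qualities** are not specified by the method family: dominant
  calls inherit the best supporting Phred, reference fallbacks get
  `moderate_qual`, unresolved columns get Phred 2.
* **Duplex clusters** are not required to contain both orientations; the
  `(A_B, B_A)` counts are emitted as aux tags (`da`/`db`, with `sp` for
  supporting pairs) for downstream filtering instead.
* **Mate-overlap scoring happens per pair before clustering** (the step
  order as published); the alternative — recomputing overlap consistency
  after clustering — is not implemented.

## Streaming and memory

Groups are held open only while the stream can still reach them: a group is
finalized when the current pair's left position passes the group's right
position (or the chromosome changes). Output records wait in a heap drained
up to a watermark — the minimum of the open groups' left positions, the
buffered unpaired mates' positions and the current stream position — which
guarantees coordinate-sorted output in one pass with no temporary files.

## Reporting

Pre- and post-processing phases count reads, bases, and mismatches by
direct comparison of M/=/X-aligned bases against the reference (deliberately
not via MD tags, which are stale on consensus output). Coverage is binned at
10 kb by default (presentation only, configurable); BED regions get mean
depth. Rates with zero denominators are reported as `null`, never NaN.
The HTML report embeds every number through the same JSON serializer as the
JSON report, so the two agree character-for-character; charts are inline SVG
with native hover tooltips, keeping the page fully self-contained.

## Synthetic data

The simulator emulates exactly the stated world the engine targets: uniform
random reference; fragment lengths normal around 167 bp (sd 10) — the
cell-free DNA peak — clipped so a 100 bp read pair overlaps by at most
50 bp; uniform fragment placement; per-fragment single or dual 4-base UMIs;
duplicate counts `1 + Poisson(dup_mean − 1)` so every fragment is observed;
i.i.d. substitution errors; and a two-level quality model (Q37 with a 2%
fraction of Q12, roughly modern short-read data). All-M CIGARs only.

What a green test therefore does *not* establish: robustness to indels and
clipped alignments inside clusters (excluded members are counted, not
realigned), quality-by-cycle or strand-specific error structure, chimeric
fragments, or marker-duplicate flags from upstream tools.

## Numerical and degenerate-input choices

Integer scores throughout (exact conservation is asserted per column in the
tests). Ties are always broken deterministically (lexicographic names,
alphabetical bases, canonical UMI order), so output is independent of input
record order within a position. Degenerate inputs: an empty run reports
zeroed counters and `null` rates; a cluster whose members all mismatch the
template CIGAR emits the template pair unchanged with one supporting pair;
a record below the output watermark, three primary alignments sharing a
name, mixed UMI presence within a group, an unsorted record, and a BAM
chromosome missing from the FASTA are all fatal with specific messages.

## Known limitations

Single-end data is not merged (passes through). CRAM is not supported.
Indel-bearing clusters lose the indel members' evidence. Per-strand duplex
consensus with two-stage comparison (Duplex-Seq style) is out of scope —
duplex orientation counts are reported, not enforced. The duplication rate
is defined as `1 − clusters/pairs`, which counts UMI-distinguished
co-located fragments as non-duplicates by construction.
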