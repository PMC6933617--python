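"""Ground-truthed synthetic fixtures.

Emulates the input this engine consumes: a small random reference, cfDNA-like
fragments (normal length distribution peaking at ~167 bp), per-fragment UMIs
(single or dual/duplex), PCR duplicate multiplicities (1 + Poisson, so every
fragment is observed at least once), per-base substitution errors under a
two-level Phred quality model, and a coordinate-sorted indexed BAM plus a
JSON ground-truth sidecar.

The simulator emits proper FR read pairs with all-M CIGARs only; indels,
quality-by-cycle structure and strand-specific error signatures of real data
are out of scope, so green tests establish correctness of the clustering /
scoring / consensus machinery, not robustness to alignment artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pysam
from pyfaidx import Faidx

from .core_model import AlignedRead

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default two-level quality model: mostly high-confidence calls with a small
#: fraction of low-quality ones, roughly what modern short-read data looks like.
DEFAULT_QUAL_MODEL = {"high": 37, "low": 12, "low_fraction": 0.02}

DEFAULT_MEAN_LEN = 167    # cfDNA fragment-length peak
DEFAULT_SD_LEN = 10
DEFAULT_READ_LEN = 100
DEFAULT_MAX_OVERLAP = 50
DEFAULT_UMI_LEN = 4


@dataclasses.dataclass
class Fragment:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def make_reference(n_chroms: int, length: int, seed: int) -> dict[str, str]:
    """i.i.d. uniform A/C/G/T chromosomes named chr1..chrN."""
    if length < 1:
        raise ValueError("chromosome length must be >= 1")
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.integers(0, 4, size=length)])
        for i in range(n_chroms)
    }


def write_reference(reference: dict[str, str], fasta_path: str) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    Faidx(fasta_path, rebuild=True)


def draw_fragments(
    n: int,
    reference: dict[str, str],
    seed: int,
    mean_len: int = DEFAULT_MEAN_LEN,
    sd: int = DEFAULT_SD_LEN,
    read_len: int = DEFAULT_READ_LEN,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[Fragment]:
    """Fragments with normal lengths clipped to
    [2*read_len − max_overlap, chrom length] and uniform start positions."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = list(reference)
    min_len = 2 * read_len - max_overlap
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        chrom_len = len(reference[chrom])
        flen = int(round(rng.normal(mean_len, sd)))
        flen = max(min_len, min(flen, chrom_len))
        start = int(rng.integers(0, chrom_len - flen + 1))
        out.append(Fragment(chrom, start, start + flen))
    return out


def _random_umi(rng: np.random.Generator, k: int = DEFAULT_UMI_LEN) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))


def _draw_quals(rng, n: int, qual_model: dict) -> list[int]:
    low = rng.random(n) < qual_model["low_fraction"]
    return [qual_model["low"] if lo else qual_model["high"] for lo in low]


def _apply_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def amplify_and_sequence(
    fragment: Fragment,
    reference: dict[str, str],
    seed: int,
    umi: Optional[str] = None,
    umi_mode: str = "none",
    dup_mean: float = 1.0,
    error_rate: float = 0.0,
    read_len: int = DEFAULT_READ_LEN,
    qual_model: Optional[dict] = None,
    name_prefix: str = "frag",
    truth_seq: Optional[str] = None,
) -> tuple[list[AlignedRead], dict]:
    """PCR-amplify and sequence one fragment.

    The duplicate count is 1 + Poisson(dup_mean − 1). Each duplicate is a
    proper FR read pair (all-M CIGARs, correct flags) with i.i.d.
    substitution errors at ``error_rate``. In dual-UMI mode the UMI is
    ``A_B`` and every second duplicate carries the reciprocal ``B_A``
    orientation in its read name (the opposite strand of the same molecule).
    ``truth_seq`` overrides the fragment's reference sequence, e.g. to plant
    a true variant carried by every duplicate.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be within [0, 1]")
    if dup_mean < 1.0:
        raise ValueError("dup_mean must be >= 1")
    if umi_mode not in ("none", "single", "dual"):
        raise ValueError(f"unknown umi_mode {umi_mode!r}")
    qual_model = qual_model or DEFAULT_QUAL_MODEL
    rng = np.random.default_rng(seed)

    frag_seq = truth_seq or reference[fragment.chrom][fragment.start : fragment.end]
    if len(frag_seq) != fragment.length:
        raise ValueError("truth_seq length must equal the fragment length")
    if umi is None:
        if umi_mode == "single":
            umi = _random_umi(rng)
        elif umi_mode == "dual":
            umi = f"{_random_umi(rng)}_{_random_umi(rng)}"
    truth_r1 = frag_seq[:read_len]
    truth_r2 = frag_seq[-read_len:]
    r2_start = fragment.end - read_len

    n_dup = 1 + int(rng.poisson(max(dup_mean - 1.0, 0.0)))
    reads: list[AlignedRead] = []
    for d in range(n_dup):
        name_umi = umi or ""
        if umi_mode == "dual" and d % 2 == 1:
            a, b = name_umi.split("_")
            name_umi = f"{b}_{a}"
        name = f"{name_prefix}d{d}"
        if name_umi:
            name = f"{name}:{name_umi}"
        seq1 = _apply_errors(rng, truth_r1, error_rate)
        seq2 = _apply_errors(rng, truth_r2, error_rate)
        quals1 = _draw_quals(rng, read_len, qual_model)
        quals2 = _draw_quals(rng, read_len, qual_model)
        tlen = fragment.length
        common = dict(chrom=fragment.chrom, cigar=(("M", read_len),))
        reads.append(
            AlignedRead(
                query_name=name,
                ref_start=fragment.start,
                mapq=60,
                seq=seq1,
                quals=quals1,
                flag=0x1 | 0x2 | 0x20 | 0x40,
                rnext="=",
                pnext=r2_start,
                tlen=tlen,
                **common,
            )
        )
        reads.append(
            AlignedRead(
                query_name=name,
                ref_start=r2_start,
                mapq=60,
                seq=seq2,
                quals=quals2,
                flag=0x1 | 0x2 | 0x10 | 0x80,
                rnext="=",
                pnext=fragment.start,
                tlen=-tlen,
                **common,
            )
        )
    truth = {
        "chrom": fragment.chrom,
        "start": fragment.start,
        "end": fragment.end,
        "umi": umi or "",
        "n_duplicates": n_dup,
        "truth_read1": truth_r1,
        "truth_read2": truth_r2,
    }
    return reads, truth


def write_fixture(
    reads: list[AlignedRead],
    reference: dict[str, str],
    bam_path: str,
    fasta_path: str,
) -> None:
    """Write the FASTA (+.fai) and a coordinate-sorted, indexed BAM."""
    from .alignment_io import read_to_pysam

    write_reference(reference, fasta_path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    }
    chrom_ids = {name: i for i, name in enumerate(reference)}
    ordered = sorted(
        reads, key=lambda r: (chrom_ids.get(r.chrom, len(chrom_ids)), r.ref_start, r.query_name)
    )
    mode = "wb" if str(bam_path).endswith(".bam") else "wh"
    with pysam.AlignmentFile(bam_path, mode, header=header) as af:
        for read in ordered:
            af.write(read_to_pysam(read, af.header))
    if mode == "wb":
        pysam.index(str(bam_path))


def simulate_dataset(
    out_prefix: str,
    n_fragments: int,
    seed: int,
    dup_mean: float = 1.0,
    error_rate: float = 0.0,
    umi_mode: str = "none",
    mean_len: int = DEFAULT_MEAN_LEN,
    read_len: int = DEFAULT_READ_LEN,
    n_chroms: int = 1,
    chrom_length: int = 100_000,
    qual_model: Optional[dict] = None,
    plant_variant: bool = False,
) -> dict:
    """Full fixture: reference + fragments + reads + ground truth on disk.

    Writes ``<prefix>.fasta``(+.fai), ``<prefix>.bam``(+.bai) and
    ``<prefix>.truth.json``; returns the ground-truth model. With
    ``plant_variant`` the first fragment carries a true variant (one
    substituted base in every duplicate), recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    reference = make_reference(n_chroms, chrom_length, int(rng.integers(2**31)))
    fragments = draw_fragments(
        n_fragments, reference, int(rng.integers(2**31)),
        mean_len=mean_len, read_len=read_len,
    )
    all_reads: list[AlignedRead] = []
    truths = []
    variant = None
    for i, frag in enumerate(fragments):
        truth_seq = None
        if plant_variant and i == 0:
            offset = frag.length // 4  # inside read1's span
            ref_seq = reference[frag.chrom][frag.start : frag.end]
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_seq[offset]]
            truth_seq = ref_seq[:offset] + alt + ref_seq[offset + 1 :]
            variant = {
                "chrom": frag.chrom,
                "pos": frag.start + offset,
                "ref": ref_seq[offset],
                "alt": alt,
            }
        reads, truth = amplify_and_sequence(
            frag,
            reference,
            seed=int(rng.integers(2**31)),
            umi_mode=umi_mode,
            dup_mean=dup_mean,
            error_rate=error_rate,
            read_len=read_len,
            qual_model=qual_model,
            name_prefix=f"frag{i}",
            truth_seq=truth_seq,
        )
        all_reads.extend(reads)
        truths.append(truth)

    fasta_path = f"{out_prefix}.fasta"
    bam_path = f"{out_prefix}.bam"
    write_fixture(all_reads, reference, bam_path, fasta_path)
    model = {
        "seed": seed,
        "n_fragments": n_fragments,
        "dup_mean": dup_mean,
        "error_rate": error_rate,
        "umi_mode": umi_mode,
        "read_len": read_len,
        "planted_variant": variant,
        "fragments": truths,
        "paths": {"fasta": fasta_path, "bam": bam_path},
    }
    with open(f"{out_prefix}.truth.json", "w") as fh:
        json.dump(model, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return model
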