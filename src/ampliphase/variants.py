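"""Per-allele SNP consensus calling from phased long reads.

After phasing, each allele's reads form a (near-)haploid pool, so true
substitutions appear essentially homozygous within the pool while sequencing
errors stay near the per-base error rate.  The caller therefore builds a
per-column pileup against the amplicon reference and emits a call where the
column is deep enough (``min_depth``, default 50) and the modal
non-reference base reaches the homozygous fraction (default 0.7).  Only
substitutions are called: long-read indel errors concentrate in homopolymer
regions and are not reliable at amplicon scale.

Reads are optionally down-sampled to a target coverage (default 200x)
before calling to bound the cost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import edit_distance_semiglobal, revcomp, semiglobal_cigar

__all__ = [
    "AlleleSnpCall",
    "downsample_reads",
    "call_allele_snps",
    "amplicon_length",
    "write_vcf",
]

DEFAULT_MIN_DEPTH = 50
DEFAULT_HOMOZYGOUS_FRACTION = 0.7
DEFAULT_TARGET_COVERAGE = 200

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class AlleleSnpCall:
    """A per-allele homozygous substitution call."""

    position: int  # 1-based on the amplicon reference
    ref_base: str
    alt_base: str
    allele: str  # "normal" | "expanded"
    depth: int
    alt_fraction: float


def downsample_reads(
    reads: list[tuple[str, str]],
    amplicon_length: int,
    target_coverage: float = DEFAULT_TARGET_COVERAGE,
    rng_seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform random subset capped at ``target_coverage`` fold coverage.

    Coverage is total read bases divided by the amplicon length.  Reads are
    shuffled with the seeded generator and taken while the running coverage
    stays at or below the target, so the subset is maximal under the cap;
    a pool already below the target is returned unchanged (original order).
    """
    if amplicon_length <= 0:
        raise ValueError("amplicon_length must be positive")
    total = sum(len(seq) for _, seq in reads)
    budget = target_coverage * amplicon_length
    if total <= budget:
        return list(reads)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(reads))
    kept = []
    acc = 0
    for idx in order:
        length = len(reads[idx][1])
        if acc + length > budget:
            continue
        acc += length
        kept.append(reads[idx])
    return kept


def _orient_to_ref(seq: str, ref: str) -> str:
    rc = revcomp(seq)
    return rc if edit_distance_semiglobal(ref, rc) < edit_distance_semiglobal(ref, seq) else seq


def _pileup_counts(reads: list[tuple[str, str]], ref: str) -> np.ndarray:
    """(L, 4) base counts per reference column from semi-global alignments.

    The reference is the alignment query (consumed end to end); each read
    may be clipped.  Reference columns opposite a read gap contribute
    nothing; read insertions are skipped.
    """
    counts = np.zeros((len(ref), 4), dtype=np.int32)
    for _, seq in reads:
        seq = _orient_to_ref(seq.upper(), ref)
        _, cigar, tspan = semiglobal_cigar(ref, seq)
        rpos = 0  # reference position (cigar query)
        tpos = tspan[0]  # read position (cigar target)
        for num, op in _CIGAR_RE.findall(cigar):
            num = int(num)
            if op in "=X":
                for k in range(num):
                    base = seq[tpos + k]
                    if base in _BASE_INDEX:
                        counts[rpos + k, _BASE_INDEX[base]] += 1
                rpos += num
                tpos += num
            elif op == "I":  # reference base vs gap in read
                rpos += num
            else:  # "D": read base vs gap in reference
                tpos += num
    return counts


def call_allele_snps(
    reads: list[tuple[str, str]],
    amplicon_ref: str,
    allele: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    homozygous_fraction: float = DEFAULT_HOMOZYGOUS_FRACTION,
) -> list[AlleleSnpCall]:
    """Pileup consensus substitution calls for one phased allele.

    A call is emitted where the column depth is at least ``min_depth`` and
    the modal non-reference base accounts for at least
    ``homozygous_fraction`` of the aligned bases (a per-allele homozygous
    substitution).  Insertions and deletions are never called.
    """
    amplicon_ref = amplicon_ref.upper()
    counts = _pileup_counts(reads, amplicon_ref)
    depth = counts.sum(axis=1)
    calls = []
    for pos in range(len(amplicon_ref)):
        if depth[pos] < min_depth:
            continue
        ref_base = amplicon_ref[pos]
        if ref_base not in _BASE_INDEX:
            continue
        col = counts[pos].copy()
        col[_BASE_INDEX[ref_base]] = 0
        alt_idx = int(col.argmax())
        frac = col[alt_idx] / depth[pos]
        if frac >= homozygous_fraction:
            calls.append(
                AlleleSnpCall(
                    position=pos + 1,
                    ref_base=ref_base,
                    alt_base=_BASES[alt_idx],
                    allele=allele,
                    depth=int(depth[pos]),
                    alt_fraction=float(frac),
                )
            )
    return calls


def amplicon_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive genomic interval."""
    if start > end:
        raise ValueError(f"invalid interval: start {start} > end {end}")
    return end - start + 1


def write_vcf(
    calls: list[AlleleSnpCall],
    out_path: str | Path,
    contig: str = "amplicon",
    contig_length: int | None = None,
) -> None:
    """Emit calls as a minimal VCF v4.2 file (substitutions only)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ALLELE,Number=1,Type=String,Description="Phased allele (normal or expanded)">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth at the site">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternative base fraction in the allele pool">',
    ]
    if contig_length is not None:
        lines.insert(1, f"##contig=<ID={contig},length={contig_length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in sorted(calls, key=lambda c: (c.position, c.allele)):
        info = f"ALLELE={call.allele};DP={call.depth};AF={call.alt_fraction:.4f}"
        lines.append(
            f"{contig}\t{call.position}\t.\t{call.ref_base}\t{call.alt_base}\t.\tPASS\t{info}"
        )
    Path(out_path).write_text("\n".join(lines) + "\n")
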