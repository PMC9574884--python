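"""Pairwise alignment primitives shared by every pipeline stage.

All sequence comparison in this package goes through this module so that the
scoring behaviour is defined in exactly one place.  Two alignment modes are
supported:

``local``
    Smith-Waterman: the best positive-scoring subalignment of query and
    target.  Used for decoy-based repeat bound estimation and for screening
    barcodes against a reference.

``semi-global``
    The query is consumed end to end while both ends of the target may be
    clipped for free ("glocal" / infix alignment).  Used for matching
    barcode+anchor probes against read ends and for scoring repeat-count
    templates against reads, where the template must be explained in full
    but the read may carry extra sequence.

Scoring is controlled by an :class:`AlignmentScheme`.  The default is an
affine scheme tolerant of nanopore indels (match +1, mismatch -2, gap of
length L costs 2 + L).  The unit-cost scheme :data:`EDIT_SCHEME` (match 0,
mismatch -1, gap base -1, i.e. score = -Levenshtein distance) has a fast
bit-parallel backend (edlib) for semi-global mode and is used in the
throughput-critical repeat-quantification and demultiplexing loops.

Every alignment is attempted on the query and its reverse complement and the
better orientation is reported; amplicon reads occur on both strands.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentScheme",
    "AlignmentResult",
    "MappingConfidence",
    "DEFAULT_SCHEME",
    "EDIT_SCHEME",
    "MAX_MAPQ",
    "align",
    "mapq_of",
    "revcomp",
    "edit_distance_semiglobal",
    "semiglobal_cigar",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")
_ALPHABET = "ACGTN"

#: Cap of the Phred-scaled mapping quality.
MAX_MAPQ = 60
#: Scale constant of the mapping-quality formula.
_MAPQ_SCALE = 60

_CIGAR_TOKEN = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentScheme:
    """Affine alignment scoring scheme.

    A gap of length ``L`` scores ``gap_open + L * gap_extend`` (both values
    are negative).  ``match`` must be >= 0 and ``mismatch``, ``gap_extend``
    < 0.  N is treated as mismatching every base, including another N.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -2
    gap_extend: int = -1

    def gap_score(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend if length > 0 else 0

    @property
    def is_unit_cost(self) -> bool:
        """True when score maximisation equals edit-distance minimisation."""
        return (self.match, self.mismatch, self.gap_open, self.gap_extend) == (
            0,
            -1,
            0,
            -1,
        )


DEFAULT_SCHEME = AlignmentScheme()
EDIT_SCHEME = AlignmentScheme(match=0, mismatch=-1, gap_open=0, gap_extend=-1)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a pairwise alignment.

    ``query_span`` and ``target_span`` are 0-based half-open intervals of
    the aligned region on the (possibly reverse-complemented) query and on
    the target.  ``orientation`` records which query strand aligned.
    """

    score: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    n_matches: int
    orientation: str  # "forward" | "reverse-complement"


@dataclass(frozen=True)
class MappingConfidence:
    """Phred-scaled confidence that the best candidate is the right one."""

    mapq: int
    best_score: int
    second_score: int


def _validate_sequence(seq: str, name: str) -> str:
    if not isinstance(seq, str) or not seq:
        raise ValueError(f"{name} sequence must be a non-empty string")
    up = seq.upper()
    bad = set(up) - _VALID_BASES
    if bad:
        raise ValueError(f"{name} contains non-ACGTN characters: {sorted(bad)!r}")
    return up


@functools.lru_cache(maxsize=32)
def _substitution_matrix(match: int, mismatch: int):
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            # N mismatches everything, including N.
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


@functools.lru_cache(maxsize=32)
def _aligner(scheme: AlignmentScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _substitution_matrix(scheme.match, scheme.mismatch)
    # Biopython charges open+extend for the first gap base.
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    if mode == "local":
        aligner.mode = "local"
    else:  # semi-global: query consumed, target ends clipped for free
        aligner.mode = "global"
        aligner.end_deletion_score = 0.0
    return aligner


def _mask_ambiguous(query: str) -> str:
    """Replace N in the query with a sentinel so edlib never matches it."""
    return query.replace("N", "!")


def _parse_cigar(cigar: str) -> int:
    """Number of identical aligned bases in an edlib extended CIGAR."""
    return sum(int(n) for n, op in _CIGAR_TOKEN.findall(cigar) if op == "=")


def _align_one(query: str, target: str, mode: str, scheme: AlignmentScheme):
    """Single-orientation alignment; returns (score, qspan, tspan, n_matches)."""
    if mode == "semi-global" and scheme.is_unit_cost:
        res = edlib.align(_mask_ambiguous(query), target, mode="HW", task="path")
        start, end = res["locations"][0]
        return (
            -res["editDistance"],
            (0, len(query)),
            (start, end + 1),
            _parse_cigar(res["cigar"]),
        )
    aligner = _aligner(scheme, mode)
    alignments = aligner.align(target, query)
    try:
        aln = alignments[0]
    except IndexError:
        # no positive-scoring local alignment exists
        return 0, (0, 0), (0, 0), 0
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return int(aln.score), (0, 0), (0, 0), 0
    tspan = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    qspan = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    n_matches = int(aln.counts().identities)
    return int(aln.score), qspan, tspan, n_matches


def align(
    query: str,
    target: str,
    mode: str = "local",
    scheme: AlignmentScheme = DEFAULT_SCHEME,
    orientations: str = "both",
) -> AlignmentResult:
    """Best-scoring pairwise alignment of ``query`` against ``target``.

    Parameters
    ----------
    mode
        ``"local"`` or ``"semi-global"`` (query fully consumed, target ends
        free).
    orientations
        ``"both"`` (default) tries the query and its reverse complement and
        reports the better; ``"forward"`` restricts to the given strand.

    Returns
    -------
    AlignmentResult
        Deterministic for fixed inputs and scheme; orientation ties resolve
        to ``"forward"``.
    """
    query = _validate_sequence(query, "query")
    target = _validate_sequence(target, "target")
    if mode not in ("local", "semi-global"):
        raise ValueError(f"unknown alignment mode: {mode!r}")
    if orientations not in ("both", "forward"):
        raise ValueError(f"unknown orientations: {orientations!r}")

    candidates = [("forward", query)]
    if orientations == "both":
        candidates.append(("reverse-complement", revcomp(query)))

    best = None
    for orientation, q in candidates:
        score, qspan, tspan, n_matches = _align_one(q, target, mode, scheme)
        if best is None or score > best.score:
            best = AlignmentResult(
                score=score,
                query_span=qspan,
                target_span=tspan,
                n_matches=n_matches,
                orientation=orientation,
            )
    return best


def mapq_of(candidates: list[AlignmentResult] | list[int]) -> MappingConfidence:
    """Phred-scaled mapping quality from a set of competing alignments.

    Computed as ``min(60, round(60 * (best - second) / best))``; a score tie
    or a non-positive best score yields MAPQ 0, and a single candidate
    competes against an implicit second score of 0 (so a lone positive
    candidate gets the capped maximum).  Permutation invariant.
    """
    if not candidates:
        raise ValueError("mapq_of requires at least one candidate")
    scores = sorted(
        (c.score if isinstance(c, AlignmentResult) else int(c) for c in candidates),
        reverse=True,
    )
    best = scores[0]
    second = scores[1] if len(scores) > 1 else 0
    if best <= 0 or best == second:
        mapq = 0
    else:
        mapq = min(MAX_MAPQ, int(round(_MAPQ_SCALE * (best - second) / best)))
    return MappingConfidence(mapq=mapq, best_score=best, second_score=second)


def edit_distance_semiglobal(query: str, target: str) -> int:
    """Unit-cost semi-global distance (query consumed, target ends free).

    Fast path equivalent to ``-align(query, target, "semi-global",
    EDIT_SCHEME, orientations="forward").score``; used in grid scoring
    loops where constructing full results would dominate runtime.
    """
    return edlib.align(_mask_ambiguous(query.upper()), target.upper(), mode="HW")[
        "editDistance"
    ]


def semiglobal_cigar(query: str, target: str) -> tuple[int, str, tuple[int, int]]:
    """Unit-cost semi-global alignment path of query against target.

    Returns ``(edit_distance, extended_cigar, target_span)`` where the CIGAR
    uses ``=``, ``X`` (consume both), ``I`` (query only) and ``D`` (target
    only), and ``target_span`` is the 0-based half-open aligned interval on
    the target.
    """
    res = edlib.align(_mask_ambiguous(query.upper()), target.upper(), mode="HW", task="path")
    start, end = res["locations"][0]
    return res["editDistance"], res["cigar"], (start, end + 1)
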