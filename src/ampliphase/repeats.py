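"""Joint quantification of two adjacent tandem repeats per read.

The per-read estimate has two stages:

1. *Fast bound estimation* (per motif, independently).  The read is locally
   aligned to a decoy reference of 1,000 tandem motif copies; the number of
   decoy repeat units covered by the alignment bounds the repeat count from
   above (sequencing errors let flanking sequence bleed into the decoy
   alignment, which only inflates the bound).  The length of the longest
   run of exact, error-free motif copies anywhere in the read bounds the
   count from below.

2. *Grid refinement*.  For every (m, n) with L1 <= m <= U1 and
   L2 <= n <= U2 a full amplicon template ``left_flank + motif1^m +
   interstitial + motif2^n + right_flank`` is scored against the read by
   semi-global alignment (template consumed, read ends free).  The argmax
   (m, n) is the read's repeat genotype; ties break to the smallest m, then
   smallest n.

The grid is scored under the unit-cost scheme (score = -edit distance),
whose bit-parallel backend makes the exhaustive grid affordable; the decoy
step uses the default affine local scheme.  Templates are cached across
reads, and each read's orientation is resolved once from its flanks rather
than per template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import (
    DEFAULT_SCHEME,
    AlignmentScheme,
    align,
    edit_distance_semiglobal,
    revcomp,
)
from .locus import LocusModel

__all__ = [
    "RepeatBounds",
    "RepeatProfile",
    "estimate_bounds",
    "joint_refine",
    "quantify_sample",
    "longest_exact_run",
]

#: Decoy reference length in repeat units.
DEFAULT_DECOY_UNITS = 1000

#: Safety margins applied to the raw bounds before grid refinement:
#: L <- max(0, L - LOWER_MARGIN), U <- U + UPPER_MARGIN.  Basecall errors
#: can deflate the alignment-derived upper bound; a small margin protects
#: argmax coverage at negligible grid cost.
LOWER_MARGIN = 1
UPPER_MARGIN = 3


@dataclass(frozen=True)
class RepeatBounds:
    """Lower/upper bounds of the two repeat counts."""

    L1: int
    U1: int
    L2: int
    U2: int

    def __post_init__(self):
        if self.L1 > self.U1 or self.L2 > self.U2:
            raise ValueError("repeat bounds must satisfy L <= U")
        if min(self.L1, self.L2) < 0:
            raise ValueError("repeat bounds must be non-negative")


@dataclass(frozen=True)
class RepeatProfile:
    """Per-read joint repeat estimate."""

    read_id: str
    m: int
    n: int
    score: int
    grid_evaluations: int


def longest_exact_run(seq: str, motif: str) -> int:
    """Longest run of exact consecutive motif copies anywhere in ``seq``.

    All phase offsets are covered because every possible start position is
    considered.
    """
    k = len(motif)
    n = len(seq)
    best = 0
    i = 0
    while i <= n - k:
        if seq[i : i + k] == motif:
            run = 1
            j = i + k
            while seq[j : j + k] == motif:
                run += 1
                j += k
            best = max(best, run)
            # restart after the first unit of this run: a longer run cannot
            # start inside an already-counted full run at the same phase,
            # but may start at a shifted phase one base later.
            i += 1
        else:
            i += 1
    return best


def estimate_bounds(
    read_seq: str,
    motif: str,
    decoy_units: int = DEFAULT_DECOY_UNITS,
    scheme: AlignmentScheme = DEFAULT_SCHEME,
) -> tuple[int, int]:
    """Fast lower/upper bound of the repeat count of one motif in a read.

    Returns ``(lower, upper)``; an unalignable read yields ``(0, 0)``.
    Both read orientations are considered.  The decoy is truncated to
    twice the read length (in units) when that is shorter than
    ``decoy_units``: a local alignment of the read can never cover more
    decoy sequence than that, so the bound is unchanged.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    read_seq = read_seq.upper()
    motif = motif.upper()
    effective_units = min(decoy_units, math.ceil(2 * len(read_seq) / len(motif)) + 2)
    decoy = motif * effective_units

    lower = max(
        longest_exact_run(read_seq, motif),
        longest_exact_run(revcomp(read_seq), motif),
    )
    result = align(read_seq, decoy, mode="local", scheme=scheme)
    if result.score <= 0:
        upper = 0
    else:
        span = result.target_span[1] - result.target_span[0]
        upper = math.ceil(span / len(motif))
    if upper == 0:
        lower = 0
    return lower, max(lower, upper)


def _orient_read(read_seq: str, locus: LocusModel) -> str:
    """Return the read in amplicon (template) orientation.

    Decided once per read by semi-global alignment of both flanks against
    both read orientations; the orientation with the smaller total edit
    distance wins (ties keep the given orientation).
    """
    rc = revcomp(read_seq)
    d_fwd = edit_distance_semiglobal(locus.left_flank, read_seq) + edit_distance_semiglobal(
        locus.right_flank, read_seq
    )
    d_rev = edit_distance_semiglobal(locus.left_flank, rc) + edit_distance_semiglobal(
        locus.right_flank, rc
    )
    return rc if d_rev < d_fwd else read_seq


class _TemplateCache:
    """Memoised locus templates keyed by (m, n)."""

    def __init__(self, locus: LocusModel):
        self.locus = locus
        self._cache: dict[tuple[int, int], str] = {}

    def get(self, m: int, n: int) -> str:
        key = (m, n)
        if key not in self._cache:
            self._cache[key] = self.locus.build_template(m, n)
        return self._cache[key]


def joint_refine(
    read_id: str,
    read_seq: str,
    locus: LocusModel,
    bounds1: tuple[int, int],
    bounds2: tuple[int, int],
    _cache: _TemplateCache | None = None,
) -> RepeatProfile:
    """Exhaustive (m, n) grid refinement of one read's repeat counts.

    Every template in the grid is scored by unit-cost semi-global alignment
    (template consumed, read clipped free) in the read's resolved
    orientation; the returned profile carries the argmax and the number of
    grid evaluations.  Tie-breaking is deterministic: smallest m, then
    smallest n (row-major scan with strict improvement).
    """
    l1, u1 = bounds1
    l2, u2 = bounds2
    if l1 > u1 or l2 > u2:
        raise ValueError(f"degenerate grid: bounds {bounds1}, {bounds2}")
    if min(l1, l2) < 0:
        raise ValueError("bounds must be non-negative")
    cache = _cache or _TemplateCache(locus)
    seq = _orient_read(read_seq.upper(), locus)

    best_score = None
    best_mn = (l1, l2)
    evaluations = 0
    for m in range(l1, u1 + 1):
        for n in range(l2, u2 + 1):
            score = -edit_distance_semiglobal(cache.get(m, n), seq)
            evaluations += 1
            if best_score is None or score > best_score:
                best_score = score
                best_mn = (m, n)
    return RepeatProfile(
        read_id=read_id,
        m=best_mn[0],
        n=best_mn[1],
        score=best_score,
        grid_evaluations=evaluations,
    )


def quantify_sample(
    reads: list[tuple[str, str]],
    locus: LocusModel,
    decoy_units: int = DEFAULT_DECOY_UNITS,
) -> tuple[list[RepeatProfile], list[str]]:
    """Joint repeat quantification of all reads of one sample.

    ``reads`` is a list of ``(read_id, sequence)``.  Returns the per-read
    profiles and the ids of unquantified reads (no alignment to either
    motif's decoy, i.e. raw bounds (0, 0) for both motifs); unquantified
    reads are excluded from downstream phasing.
    """
    if not reads:
        raise ValueError("quantify_sample requires at least one read")
    cache = _TemplateCache(locus)
    profiles: list[RepeatProfile] = []
    unquantified: list[str] = []
    for read_id, seq in reads:
        b1 = estimate_bounds(seq, locus.motif1, decoy_units)
        b2 = estimate_bounds(seq, locus.motif2, decoy_units)
        if b1 == (0, 0) and b2 == (0, 0):
            unquantified.append(read_id)
            continue
        grid1 = (max(0, b1[0] - LOWER_MARGIN), b1[1] + UPPER_MARGIN)
        grid2 = (max(0, b2[0] - LOWER_MARGIN), b2[1] + UPPER_MARGIN)
        profiles.append(joint_refine(read_id, seq, locus, grid1, grid2, _cache=cache))
    return profiles, unquantified
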