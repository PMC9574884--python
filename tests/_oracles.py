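"""Independent brute-force oracles used to validate the implementation.

Everything here is written for clarity, not speed, and deliberately avoids
the package's own alignment/graph code paths.
"""

from __future__ import annotations

import itertools

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _subst(a: str, b: str, match: int, mismatch: int) -> int:
    # N mismatches everything, including N
    return match if (a == b and a != "N") else mismatch


def dp_align_score(
    query: str,
    target: str,
    mode: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -2,
    gap_extend: int = -1,
) -> int:
    """Quadratic-time Gotoh affine-gap alignment score.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``local`` is
    Smith-Waterman (floor at 0); ``semi-global`` consumes the query fully
    with free clipping of both target ends.
    """
    n, m = len(query), len(target)
    NEG = float("-inf")
    local = mode == "local"

    # M: last pair aligned; P: gap consuming query; Q: gap consuming target
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    P = [[NEG] * (m + 1) for _ in range(n + 1)]
    Q = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for j in range(1, m + 1):
        if local or mode == "semi-global":
            M[0][j] = 0  # free leading target clip / local start
        else:
            Q[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        P[i][0] = gap_open + i * gap_extend
        if local:
            M[i][0] = 0
    best_local = 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            s = _subst(qi, target[j - 1], match, mismatch)
            diag = max(M[i - 1][j - 1], P[i - 1][j - 1], Q[i - 1][j - 1])
            M[i][j] = diag + s
            if local:
                M[i][j] = max(M[i][j], s, 0)
            P[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                P[i - 1][j] + gap_extend,
                Q[i - 1][j] + gap_open + gap_extend,
            )
            Q[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Q[i][j - 1] + gap_extend,
                P[i][j - 1] + gap_open + gap_extend,
            )
            if local:
                best_local = max(best_local, M[i][j])
    if local:
        return int(best_local)
    if mode == "semi-global":
        return int(max(max(M[n][j], P[n][j]) for j in range(m + 1)))
    return int(max(M[n][m], P[n][m], Q[n][m]))


def dp_align_score_both(query: str, target: str, mode: str, **scheme) -> int:
    """Best DP score over the query and its reverse complement."""
    return max(
        dp_align_score(query, target, mode, **scheme),
        dp_align_score(oracle_revcomp(query), target, mode, **scheme),
    )


def shared_kmer(a: str, b: str, k: int) -> bool:
    """True when a and b (or revcomp(b)) share any exact k-mer."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    for other in (b, oracle_revcomp(b)):
        kb = {other[i : i + k] for i in range(len(other) - k + 1)}
        if ka & kb:
            return True
    return False


def brute_force_max_clique(nodes: list, edges: set) -> int:
    """Maximum clique size by exhaustive subset enumeration (n <= 15)."""
    def is_clique(subset):
        return all(
            (u, v) in edges or (v, u) in edges
            for u, v in itertools.combinations(subset, 2)
        )

    for size in range(len(nodes), 0, -1):
        for subset in itertools.combinations(nodes, size):
            if is_clique(subset):
                return size
    return 0


def brute_force_longest_run(seq: str, motif: str) -> int:
    """Longest exact tandem run of motif, scanning every start offset."""
    k = len(motif)
    best = 0
    for start in range(len(seq)):
        run = 0
        pos = start
        while seq[pos : pos + k] == motif:
            run += 1
            pos += k
        best = max(best, run)
    return best


def sliding_window_identity(barcode: str, reference: str) -> float:
    """Best gapless identity of barcode against either reference strand.

    An intentionally crude bound used to sanity-check reference screening:
    for verbatim (sub)strings it reaches 1.0.
    """
    k = len(barcode)
    best = 0
    for strand in (reference, oracle_revcomp(reference)):
        for i in range(len(strand) - k + 1):
            matches = sum(a == b for a, b in zip(barcode, strand[i : i + k]))
            best = max(best, matches)
    return best / k
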