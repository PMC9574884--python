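"""Design of mutually non-aligning PCR barcodes.

Candidate barcodes are rejection-sampled under three sequence-composition
constraints (no homopolymer longer than 2 bp, no tandem repeat, GC content
in 40-60%), screened against a reference genome so they cannot prime
off-target, and finally reduced to a mutually non-aligning set by maximal
clique search on a compatibility graph whose edges join barcode pairs with
no pairwise alignment (seeded by a shared word of a configurable size, as
in blastn with word size 6).

With dual (combinatorial) barcoding, a clique of F forward and B backward
barcodes addresses F x B samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from Bio import SeqIO

from .alignment import DEFAULT_SCHEME, AlignmentScheme, align, revcomp

__all__ = [
    "BarcodeCandidate",
    "BarcodeSetResult",
    "generate_candidates",
    "screen_against_reference",
    "build_compatibility_graph",
    "find_barcode_set",
    "max_homopolymer",
    "has_tandem_repeat",
    "gc_fraction",
]

#: Above this node count, exact clique search is replaced by a greedy
#: heuristic and the result is flagged non-exact.
EXACT_CLIQUE_NODE_LIMIT = 200

#: Minimal span (bp) and minimal unit count for the tandem-repeat filter.
_TR_MIN_SPAN = 9
_TR_MIN_UNITS = 3
_TR_MAX_UNIT = 8


@dataclass(frozen=True)
class BarcodeCandidate:
    sequence: str
    gc_fraction: float
    max_homopolymer: int
    has_tandem_repeat: bool


@dataclass(frozen=True)
class BarcodeSetResult:
    """Outcome of the clique search.

    ``found`` is False when no clique of the requested size exists (for
    exact search) or none was found (heuristic search); ``exact`` records
    whether the search was exhaustive.
    """

    found: bool
    members: tuple[str, ...]
    exact: bool


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run."""
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def has_tandem_repeat(seq: str) -> bool:
    """True when some unit of length 1-8 repeats >= 3 times over >= 9 bp.

    The scan is exhaustive over unit lengths and start positions, so e.g.
    ``ACGACGACGACGACGA`` is caught (unit ACG, five copies, 15 bp).
    """
    n = len(seq)
    for unit_len in range(1, min(_TR_MAX_UNIT, n // _TR_MIN_UNITS) + 1):
        for start in range(n - unit_len * _TR_MIN_UNITS + 1):
            unit = seq[start : start + unit_len]
            reps = 1
            pos = start + unit_len
            while seq[pos : pos + unit_len] == unit:
                reps += 1
                pos += unit_len
            if reps >= _TR_MIN_UNITS and reps * unit_len >= _TR_MIN_SPAN:
                return True
    return False


def _passes_composition(seq: str, gc_range: tuple[float, float]) -> bool:
    return (
        max_homopolymer(seq) <= 2
        and not has_tandem_repeat(seq)
        and gc_range[0] <= gc_fraction(seq) <= gc_range[1]
    )


def generate_candidates(
    n: int,
    length: int,
    rng_seed: int,
    gc_range: tuple[float, float] = (0.40, 0.60),
    max_attempts_per_candidate: int = 10_000,
) -> list[BarcodeCandidate]:
    """Rejection-sample ``n`` distinct barcodes meeting composition rules.

    Raises ``RuntimeError`` when the attempt budget is exhausted, which
    signals infeasible constraints for the requested length.
    """
    if length < 8:
        raise ValueError("barcode length must be >= 8")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[BarcodeCandidate] = []
    attempts = 0
    budget = max_attempts_per_candidate * n
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"candidate space exhausted after {attempts} attempts "
                f"({len(out)}/{n} barcodes of length {length})"
            )
        attempts += 1
        seq = "".join(rng.choice(bases, size=length))
        if seq in seen or not _passes_composition(seq, gc_range):
            continue
        seen.add(seq)
        out.append(
            BarcodeCandidate(
                sequence=seq,
                gc_fraction=gc_fraction(seq),
                max_homopolymer=max_homopolymer(seq),
                has_tandem_repeat=False,
            )
        )
    return out


def screen_against_reference(
    candidates: list[BarcodeCandidate],
    reference: str | Path,
    identity_threshold: float = 0.80,
    scheme: AlignmentScheme = DEFAULT_SCHEME,
) -> list[BarcodeCandidate]:
    """Drop candidates similar to a reference genome.

    A candidate is removed when its best local alignment to either strand
    of any reference record has ``n_matches / barcode_length`` reaching
    ``identity_threshold`` (default 0.80); every retained barcode therefore
    has strictly less than 80% identical bases anywhere in the reference.
    With threshold 1.0 only verbatim (or reverse-complement-verbatim)
    substrings are removed.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ref_seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")]
    if not ref_seqs:
        raise OSError(f"reference {reference} contains no FASTA records")
    kept = []
    for cand in candidates:
        best_identity = 0.0
        for ref in ref_seqs:
            result = align(cand.sequence, ref, mode="local", scheme=scheme)
            best_identity = max(best_identity, result.n_matches / len(cand.sequence))
            if best_identity >= identity_threshold:
                break
        if best_identity < identity_threshold:
            kept.append(cand)
    return kept


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _pair_aligns(
    a: str, b: str, word_size: int, scheme: AlignmentScheme
) -> bool:
    """Seed-then-extend alignment predicate between two barcodes.

    True when ``a`` shares an exact word of ``word_size`` with ``b`` or
    revcomp(``b``) and the seeded local extension scores positively.  With
    a positive match score any shared word guarantees a positive local
    alignment, so the predicate reduces to shared-word existence; the
    extension step is kept so that non-default schemes behave sensibly.
    """
    ka = _kmers(a, word_size)
    for other in (b, revcomp(b)):
        if ka & _kmers(other, word_size):
            result = align(a, other, mode="local", scheme=scheme, orientations="forward")
            if result.score > 0:
                return True
    return False


def build_compatibility_graph(
    candidates: list[BarcodeCandidate] | list[str],
    word_size: int = 6,
    scheme: AlignmentScheme = DEFAULT_SCHEME,
) -> nx.Graph:
    """Graph whose edges join barcode pairs with no pairwise alignment.

    Nodes are barcode indices (``b0``, ``b1``, ...) with the sequence
    stored as a node attribute; an edge is present iff the seed-and-extend
    predicate finds no alignment between the two barcodes on either strand.
    """
    seqs = [c.sequence if isinstance(c, BarcodeCandidate) else c for c in candidates]
    if len(seqs) < 2:
        raise ValueError("need at least 2 candidates to build a graph")
    graph = nx.Graph()
    for i, seq in enumerate(seqs):
        graph.add_node(f"b{i}", sequence=seq)
    for (i, a), (j, b) in itertools.combinations(enumerate(seqs), 2):
        if not _pair_aligns(a, b, word_size, scheme):
            graph.add_edge(f"b{i}", f"b{j}")
    return graph


def _greedy_clique(graph: nx.Graph, k: int) -> tuple[str, ...]:
    """Greedy clique growth from high-degree seeds (heuristic, large graphs)."""
    order = sorted(graph.nodes, key=lambda n: graph.degree(n), reverse=True)
    best: tuple[str, ...] = ()
    for start in order:
        clique = [start]
        candidates = set(graph.adj[start])
        while candidates:
            nxt = max(candidates, key=lambda n: len(candidates & set(graph.adj[n])))
            clique.append(nxt)
            candidates &= set(graph.adj[nxt])
        if len(clique) > len(best):
            best = tuple(clique)
        if len(best) >= k:
            break
    return best


def find_barcode_set(graph: nx.Graph, k: int) -> BarcodeSetResult:
    """Find a clique of size >= k (a set of mutually non-aligning barcodes).

    Exact (exhaustive maximal-clique enumeration) up to
    :data:`EXACT_CLIQUE_NODE_LIMIT` nodes; greedy above.  Membership is
    verified pairwise against the graph before returning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if graph.number_of_nodes() <= EXACT_CLIQUE_NODE_LIMIT:
        best: tuple[str, ...] = ()
        for clique in nx.find_cliques(graph):
            if len(clique) > len(best):
                best = tuple(clique)
            if len(best) >= k:
                break
        exact = True
    else:
        best = _greedy_clique(graph, k)
        exact = False
    members = tuple(sorted(best[:k])) if len(best) >= k else tuple(sorted(best))
    found = len(best) >= k
    if found:
        for u, v in itertools.combinations(members, 2):
            if not graph.has_edge(u, v):  # pragma: no cover - safety check
                raise AssertionError("clique verification failed")
    return BarcodeSetResult(found=found, members=members if found else tuple(), exact=exact)


def max_clique_size(graph: nx.Graph) -> int:
    """Size of the maximum clique (exact; intended for small graphs)."""
    return max((len(c) for c in nx.find_cliques(graph)), default=0)
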