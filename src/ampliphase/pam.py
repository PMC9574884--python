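"""SNP-mediated gain and loss of protospacer adjacent motifs (PAMs).

A substitution SNP can create or destroy the PAM of a CRISPR enzyme and
thereby enable allele-specific cutting.  The classification rule is strict:

* An SNP mediates the **gain** of a PAM for an enzyme (on one strand) when
  the alternative allele's sequence contains a high-efficiency PAM
  overlapping the SNP and the reference allele's sequence contains no
  high- or low-efficiency PAM of the same enzyme overlapping the SNP on
  that strand.
* **Loss** is the symmetric rule with reference and alternative swapped.

Motifs are IUPAC patterns; a negative-strand effect means the motif matches
the reverse-complement strand.  Matched motifs are reported in bracket
notation with the SNP base in square brackets (e.g. ``TG[G]`` -> ``TG[C]``).

The shipped default enzyme table covers wild-type SpCas9 (NGG and NAG are
both treated as high-efficiency), the engineered variants SpCas9_VQR
(NGAN, NGNG), SpCas9_EQR (NGAG, plus the literal TGCG) and SpCas9_VRER
(GGCG), SaCas9 (NNGRRT), and AsCpf1 (TTTN).  Efficiency calls derived from
PAM-depletion screens are measured per literal sequence, so an entry may be
an IUPAC generalisation (where the screen supports the whole family) or a
literal sequence (where it does not); users with their own depletion data
can substitute their own table (TSV: enzyme, motif, efficiency).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .alignment import revcomp

__all__ = [
    "PamRule",
    "PamEffect",
    "SnpCall",
    "classify_pam_effect",
    "load_pam_rules",
    "default_pam_rules",
]

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class PamRule:
    enzyme: str
    motif: str
    efficiency: str  # "high" | "low"

    def __post_init__(self):
        bad = set(self.motif.upper()) - IUPAC.keys()
        if bad:
            raise ValueError(f"motif {self.motif!r} has non-IUPAC characters {sorted(bad)}")
        if self.efficiency not in ("high", "low"):
            raise ValueError("efficiency must be 'high' or 'low'")
        object.__setattr__(self, "motif", self.motif.upper())


@dataclass(frozen=True)
class SnpCall:
    """A substitution at a 1-based position of an amplicon reference."""

    snp_id: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        for base in (self.ref_base, self.alt_base):
            if base not in "ACGT":
                raise ValueError(f"SNP bases must be ACGT, got {base!r}")


@dataclass(frozen=True)
class PamEffect:
    snp_id: str
    enzyme: str
    effect: str  # "gain" | "loss"
    ref_motif: str  # bracket notation, read along the matching strand
    alt_motif: str
    strand: str  # "positive" | "negative"


def load_pam_rules(path: str | Path) -> list[PamRule]:
    """Read an enzyme table (TSV columns: enzyme, motif, efficiency)."""
    rules = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rules.append(PamRule(row["enzyme"], row["motif"], row["efficiency"]))
    seen = set()
    for rule in rules:
        key = (rule.enzyme, rule.motif)
        if key in seen:
            raise ValueError(f"duplicate rule {key}")
        seen.add(key)
    return rules


def default_pam_rules() -> list[PamRule]:
    """The shipped default enzyme/PAM table."""
    with resources.as_file(
        resources.files("ampliphase").joinpath("data/pam_rules.tsv")
    ) as path:
        return load_pam_rules(path)


def _iupac_match(seq: str, motif: str) -> bool:
    return len(seq) == len(motif) and all(
        base in IUPAC[sym] for base, sym in zip(seq, motif)
    )


def _bracket(window: str, span: tuple[int, int], snp_idx: int) -> str:
    start, end = span
    seq = window[start:end]
    rel = snp_idx - start
    return seq[:rel] + "[" + seq[rel] + "]" + seq[rel + 1 :]


def classify_pam_effect(
    snp: SnpCall,
    amplicon_ref: str,
    rules: list[PamRule],
) -> list[PamEffect]:
    """Classify the gain/loss effects of one substitution SNP.

    Every candidate motif placement (strand, start, length) overlapping the
    SNP is evaluated independently for each enzyme: the placement is a gain
    when the alternative sequence there matches a high-efficiency motif of
    the enzyme while the reference sequence matches no motif of that enzyme
    (high or low) at the same placement, and symmetrically a loss.  One
    effect is emitted per qualifying placement, so an SNP inside a run of
    overlapping PAMs reports each affected placement.
    """
    amplicon_ref = amplicon_ref.upper()
    pos0 = snp.position - 1
    if not 0 <= pos0 < len(amplicon_ref):
        raise ValueError(f"SNP position {snp.position} outside amplicon")
    if amplicon_ref[pos0] != snp.ref_base:
        raise ValueError(
            f"reference base mismatch at {snp.position}: "
            f"amplicon has {amplicon_ref[pos0]}, SNP says {snp.ref_base}"
        )

    by_enzyme: dict[str, list[PamRule]] = {}
    for rule in rules:
        by_enzyme.setdefault(rule.enzyme, []).append(rule)

    effects: list[PamEffect] = []
    for enzyme, enzyme_rules in by_enzyme.items():
        half = max(len(r.motif) for r in enzyme_rules) - 1
        lo = max(0, pos0 - half)
        hi = min(len(amplicon_ref), pos0 + half + 1)
        ref_win = amplicon_ref[lo:hi]
        snp_idx = pos0 - lo
        alt_win = ref_win[:snp_idx] + snp.alt_base + ref_win[snp_idx + 1 :]

        high = [r for r in enzyme_rules if r.efficiency == "high"]
        lengths = sorted({len(r.motif) for r in enzyme_rules})

        for strand in ("positive", "negative"):
            if strand == "positive":
                r_win, a_win, idx = ref_win, alt_win, snp_idx
            else:
                r_win, a_win = revcomp(ref_win), revcomp(alt_win)
                idx = len(ref_win) - 1 - snp_idx
            for k in lengths:
                for start in range(max(0, idx - k + 1), min(len(r_win) - k, idx) + 1):
                    span = (start, start + k)
                    ref_sub = r_win[span[0] : span[1]]
                    alt_sub = a_win[span[0] : span[1]]
                    ref_any = any(
                        _iupac_match(ref_sub, r.motif)
                        for r in enzyme_rules
                        if len(r.motif) == k
                    )
                    alt_any = any(
                        _iupac_match(alt_sub, r.motif)
                        for r in enzyme_rules
                        if len(r.motif) == k
                    )
                    ref_high = any(
                        _iupac_match(ref_sub, r.motif) for r in high if len(r.motif) == k
                    )
                    alt_high = any(
                        _iupac_match(alt_sub, r.motif) for r in high if len(r.motif) == k
                    )
                    if alt_high and not ref_any:
                        effect = "gain"
                    elif ref_high and not alt_any:
                        effect = "loss"
                    else:
                        continue
                    effects.append(
                        PamEffect(
                            snp_id=snp.snp_id,
                            enzyme=enzyme,
                            effect=effect,
                            ref_motif=_bracket(r_win, span, idx),
                            alt_motif=_bracket(a_win, span, idx),
                            strand=strand,
                        )
                    )
    return effects
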