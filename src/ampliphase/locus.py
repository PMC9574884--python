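"""Locus model for a two-repeat amplicon.

A :class:`LocusModel` describes an amplicon containing two adjacent tandem
repeat tracts, e.g. the HTT exon-1 structure::

    left_flank  (CAG)^m  interstitial  (CCG)^n  right_flank

The interstitial sequence is the fixed linker between the two tracts (for
HTT the CAACAGCCGCCA-type sequence).  The model is the template factory for
both repeat quantification (candidate templates on the (m, n) grid) and
read simulation.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = ["LocusModel", "load_locus", "demo_locus"]

_ROLES = ("left_flank", "motif1", "interstitial", "motif2", "right_flank")

#: Flanks shorter than this give unreliable anchoring of the repeat region.
MIN_RELIABLE_FLANK = 50


@dataclass(frozen=True)
class LocusModel:
    """Two adjacent tandem repeats with fixed flanks.

    ``coords`` optionally carries the 1-based inclusive genomic interval of
    the amplicon for reporting; internal indices are 0-based half-open.
    """

    left_flank: str
    motif1: str
    interstitial: str
    motif2: str
    right_flank: str
    coords: tuple[str, int, int] | None = field(default=None)

    def __post_init__(self):
        for role in ("left_flank", "motif1", "motif2", "right_flank"):
            seq = getattr(self, role)
            if not seq:
                raise ValueError(f"locus {role} must be non-empty")
        for role in _ROLES:
            seq = getattr(self, role)
            bad = set(seq.upper()) - set("ACGT")
            if bad:
                raise ValueError(f"locus {role} contains invalid bases {sorted(bad)}")
            object.__setattr__(self, role, seq.upper())
        for role in ("left_flank", "right_flank"):
            if len(getattr(self, role)) < MIN_RELIABLE_FLANK:
                warnings.warn(
                    f"{role} is shorter than {MIN_RELIABLE_FLANK} bp; "
                    "repeat anchoring may be unreliable",
                    stacklevel=2,
                )
        if self.coords is not None:
            _, start, end = self.coords
            if start > end:
                raise ValueError("locus coords must satisfy start <= end")

    def build_template(self, m: int, n: int) -> str:
        """Amplicon sequence with ``m`` motif1 units and ``n`` motif2 units."""
        if m < 0 or n < 0:
            raise ValueError("repeat counts must be non-negative")
        return (
            self.left_flank
            + self.motif1 * m
            + self.interstitial
            + self.motif2 * n
            + self.right_flank
        )

    def region_offset(self, region: str, m: int | None = None, n: int | None = None) -> int:
        """0-based start of a non-repeat region within ``build_template(m, n)``."""
        if region == "left_flank":
            return 0
        if region == "interstitial":
            if m is None:
                raise ValueError("interstitial offset requires m")
            return len(self.left_flank) + len(self.motif1) * m
        if region == "right_flank":
            if m is None or n is None:
                raise ValueError("right_flank offset requires m and n")
            return (
                len(self.left_flank)
                + len(self.motif1) * m
                + len(self.interstitial)
                + len(self.motif2) * n
            )
        raise ValueError(f"unknown region {region!r}")


def load_locus(path: str | Path) -> LocusModel:
    """Read a locus definition from TOML or FASTA-with-roles.

    TOML files use keys ``left_flank``, ``motif1``, ``interstitial``,
    ``motif2``, ``right_flank`` (and optional ``chrom``/``start``/``end``).
    FASTA files use one record per role with the role name as identifier.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        coords = None
        if {"chrom", "start", "end"} <= data.keys():
            coords = (data["chrom"], int(data["start"]), int(data["end"]))
        kwargs = {role: data[role] for role in _ROLES if role in data}
        missing = set(_ROLES) - kwargs.keys()
        if missing:
            raise ValueError(f"locus TOML missing keys: {sorted(missing)}")
        return LocusModel(coords=coords, **kwargs)
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    missing = set(_ROLES) - records.keys()
    if missing:
        raise ValueError(f"locus FASTA missing roles: {sorted(missing)}")
    return LocusModel(**{role: records[role] for role in _ROLES})


# Synthetic demonstration locus: HTT-exon-1-like structure (CAG tract,
# CAACAGCCGCCA linker, CCG tract) with synthetic 100-bp flanks.  The flanks
# are fixed random draws, not genomic sequence; they satisfy the anchoring
# requirements (no repeat-motif runs at the tract boundaries).
_DEMO_LEFT = (
    "TCGAGTCCTCAAGTCCTATTGACAGAACGTCTTGGCATAGCTGGACTTCT"
    "GGCACAATGTTCCGATAGGTCAACTTGAGCGTAATCCTGTCGACTTAGCA"
)
_DEMO_RIGHT = (
    "GTCATTCAGGACTAAGCTTCGTGTAACGATCCTGAGTTCAGCAAGGTACT"
    "CCATGATTCGGTTAGCAGATCGAACTCTAGGTGACATCCTTAAGCGGACT"
)


def demo_locus() -> LocusModel:
    """Synthetic two-repeat locus used by simulations and examples."""
    return LocusModel(
        left_flank=_DEMO_LEFT,
        motif1="CAG",
        interstitial="CAACAGCCGCCA",
        motif2="CCG",
        right_flank=_DEMO_RIGHT,
    )
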