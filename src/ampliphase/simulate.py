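"""Synthetic read and cohort simulation with full ground truth.

The simulator emulates the study design of a dual-barcoded diploid amplicon
experiment: each sample is a diploid with two (m, n) repeat alleles and
optional heterozygous substitution SNPs in the non-repeat regions; each
read is

    forward_barcode + anchor_forward + allele sequence + revcomp(backward_barcode + anchor_backward)

passed through a nanopore-like error process of independent per-base
substitution, insertion and deletion events, and emitted on a random strand.
Every read is tracked in a ground-truth manifest so each pipeline stage can
be scored exactly.

The error process is the simplest model that exercises indel tolerance: one
left-to-right pass, substitution to a uniformly chosen different base,
insertion of a uniform base after the position, deletion skipping the base.
Base qualities are constant (no stage consumes them).  The default error
rates (1% substitution, 3% insertion, 3% deletion) approximate the residual
error of super-accuracy basecalled nanopore reads on amplicon data;
defaults for coverage are 100 reads per allele (at least 50 per allele is
required downstream, and real runs usually exceed 200x).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import revcomp
from .demux import BarcodeManifest
from .locus import LocusModel

__all__ = [
    "PlantedSnp",
    "AlleleSpec",
    "SampleSpec",
    "ErrorModel",
    "SimulationConfig",
    "SimulatedRead",
    "GroundTruth",
    "simulate_pool",
    "simulate_allele_reads",
    "simulate_cohort",
    "write_fastq",
]

DEFAULT_COVERAGE_PER_ALLELE = 100


@dataclass(frozen=True)
class PlantedSnp:
    """A substitution in a non-repeat region of the allele sequence.

    ``region`` is one of ``left_flank``, ``interstitial``, ``right_flank``;
    ``offset`` is 0-based within that region.  Repeat-tract positions are
    rejected by construction: substitutions are restricted to the fixed
    regions, mirroring SNP targets that flank the repeats.
    """

    region: str
    offset: int
    alt_base: str

    def __post_init__(self):
        if self.region not in ("left_flank", "interstitial", "right_flank"):
            raise ValueError(
                f"SNPs must lie in a non-repeat region, got {self.region!r}"
            )
        if self.alt_base not in "ACGT":
            raise ValueError("alt_base must be one of ACGT")


@dataclass(frozen=True)
class AlleleSpec:
    m: int
    n: int
    snps: tuple[PlantedSnp, ...] = ()


@dataclass(frozen=True)
class SampleSpec:
    name: str
    allele1: AlleleSpec
    allele2: AlleleSpec
    coverage: int = DEFAULT_COVERAGE_PER_ALLELE


@dataclass(frozen=True)
class ErrorModel:
    substitution: float = 0.01
    insertion: float = 0.03
    deletion: float = 0.03

    def __post_init__(self):
        for name, rate in (
            ("substitution", self.substitution),
            ("insertion", self.insertion),
            ("deletion", self.deletion),
        ):
            if not 0 <= rate <= 0.2:
                raise ValueError(f"{name} rate must be in [0, 0.2]")

    @property
    def total(self) -> float:
        return self.substitution + self.insertion + self.deletion

    def quality_char(self) -> str:
        """Constant Phred+33 quality consistent with the total error rate."""
        q = round(-10 * math.log10(max(self.total, 1e-4)))
        return chr(33 + min(q, 40))


@dataclass(frozen=True)
class SimulationConfig:
    locus: LocusModel
    samples: tuple[SampleSpec, ...]
    manifest: BarcodeManifest | None = None
    error_model: ErrorModel = field(default_factory=ErrorModel)
    orientation_flip_probability: float = 0.5
    rng_seed: int = 0


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    sample: str
    allele: str  # "allele1" | "allele2"
    true_m: int
    true_n: int
    orientation: str  # "forward" | "reverse-complement"


@dataclass(frozen=True)
class GroundTruth:
    reads: tuple[SimulatedRead, ...]
    sample_alleles: dict[str, dict[str, AlleleSpec]]

    def to_json(self) -> str:
        payload = {
            "reads": [
                {
                    "read_id": r.read_id,
                    "sample": r.sample,
                    "allele": r.allele,
                    "m": r.true_m,
                    "n": r.true_n,
                    "orientation": r.orientation,
                }
                for r in self.reads
            ],
            "samples": {
                name: {
                    allele: {
                        "m": spec.m,
                        "n": spec.n,
                        "snps": [
                            {"region": s.region, "offset": s.offset, "alt": s.alt_base}
                            for s in spec.snps
                        ],
                    }
                    for allele, spec in alleles.items()
                }
                for name, alleles in self.sample_alleles.items()
            },
        }
        return json.dumps(payload, indent=2)


def _apply_snps(locus: LocusModel, spec: AlleleSpec) -> str:
    """Allele sequence with planted SNPs applied to the fixed regions."""
    regions = {
        "left_flank": list(locus.left_flank),
        "interstitial": list(locus.interstitial),
        "right_flank": list(locus.right_flank),
    }
    for snp in spec.snps:
        region = regions[snp.region]
        if not 0 <= snp.offset < len(region):
            raise ValueError(
                f"SNP offset {snp.offset} outside {snp.region} "
                f"(length {len(region)})"
            )
        if region[snp.offset] == snp.alt_base:
            raise ValueError(
                f"SNP at {snp.region}:{snp.offset} does not change the base"
            )
        region[snp.offset] = snp.alt_base
    return (
        "".join(regions["left_flank"])
        + locus.motif1 * spec.m
        + "".join(regions["interstitial"])
        + locus.motif2 * spec.n
        + "".join(regions["right_flank"])
    )


_BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """One left-to-right pass of the independent per-base error process."""
    out = []
    n = len(seq)
    # draw all event randoms at once for speed
    dels = rng.random(n) < model.deletion
    subs = rng.random(n) < model.substitution
    ins = rng.random(n) < model.insertion
    sub_choice = rng.integers(0, 3, size=n)
    ins_choice = rng.integers(0, 4, size=n)
    for i, base in enumerate(seq):
        if dels[i]:
            continue
        if subs[i]:
            base = _OTHER[base][sub_choice[i]]
        out.append(base)
        if ins[i]:
            out.append(_BASES[ins_choice[i]])
    return "".join(out)


def simulate_allele_reads(
    locus: LocusModel,
    spec: AlleleSpec,
    coverage: int,
    error_model: ErrorModel,
    rng: np.random.Generator,
    sample: str = "sample",
    allele: str = "allele1",
    flip_probability: float = 0.5,
    manifest_wrap: tuple[str, str] | None = None,
    id_prefix: str = "read",
    start_index: int = 0,
) -> list[SimulatedRead]:
    """Simulate ``coverage`` reads of one allele.

    ``manifest_wrap`` optionally provides the (forward, backward) flanking
    sequences ``forward_barcode + anchor_forward`` and
    ``backward_barcode + anchor_backward``; the backward element is
    reverse-complemented onto the 3' end, matching the dual-barcoded
    amplicon layout.
    """
    base_seq = _apply_snps(locus, spec)
    if manifest_wrap is not None:
        fwd_probe, bwd_probe = manifest_wrap
        template = fwd_probe + base_seq + revcomp(bwd_probe)
    else:
        template = base_seq
    reads = []
    qchar = error_model.quality_char()
    for i in range(coverage):
        seq = _mutate(template, error_model, rng)
        orientation = "forward"
        if rng.random() < flip_probability:
            seq = revcomp(seq)
            orientation = "reverse-complement"
        reads.append(
            SimulatedRead(
                read_id=f"{id_prefix}_{start_index + i:06d}",
                sequence=seq,
                quality=qchar * len(seq),
                sample=sample,
                allele=allele,
                true_m=spec.m,
                true_n=spec.n,
                orientation=orientation,
            )
        )
    return reads


def simulate_pool(config: SimulationConfig) -> GroundTruth:
    """Simulate a (possibly multiplexed) read pool with ground truth.

    With a barcode manifest, samples are wrapped with their barcode+anchor
    sequences in manifest order (sample i gets the i-th declared pair);
    without one, bare allele reads are produced.  Fully deterministic for a
    fixed ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    pairs: list[tuple[str, str] | None]
    if config.manifest is not None:
        sample_to_pair = {name: pair for pair, name in config.manifest.sample_map.items()}
        missing = [s.name for s in config.samples if s.name not in sample_to_pair]
        if missing:
            raise ValueError(f"samples missing from manifest: {missing}")
        pairs = []
        for spec in config.samples:
            fid, bid = sample_to_pair[spec.name]
            pairs.append(
                (
                    config.manifest.forward_barcodes[fid] + config.manifest.anchor_forward,
                    config.manifest.backward_barcodes[bid] + config.manifest.anchor_backward,
                )
            )
    else:
        pairs = [None] * len(config.samples)

    all_reads: list[SimulatedRead] = []
    index = 0
    for spec, wrap in zip(config.samples, pairs):
        for allele_name, allele_spec in (("allele1", spec.allele1), ("allele2", spec.allele2)):
            reads = simulate_allele_reads(
                config.locus,
                allele_spec,
                spec.coverage,
                config.error_model,
                rng,
                sample=spec.name,
                allele=allele_name,
                flip_probability=config.orientation_flip_probability,
                manifest_wrap=wrap,
                start_index=index,
            )
            index += len(reads)
            all_reads.extend(reads)
    sample_alleles = {
        s.name: {"allele1": s.allele1, "allele2": s.allele2} for s in config.samples
    }
    return GroundTruth(reads=tuple(all_reads), sample_alleles=sample_alleles)


def write_fastq(reads: list[SimulatedRead] | tuple[SimulatedRead, ...], path: str | Path) -> None:
    """Write simulated reads as a 4-line-record Phred+33 FASTQ file."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def simulate_cohort(
    n_individuals: int,
    haplotype_freqs: dict[str, list[tuple[tuple[int, ...], float]]],
    rng_seed: int,
) -> tuple[list, dict]:
    """Draw a cohort of phased panel genotypes from haplotype frequencies.

    ``haplotype_freqs`` maps each chromosome class (``"normal"`` and
    ``"expanded"``) to a list of ``(indicator vector, frequency)``;
    frequencies must sum to 1 within each class.  Returns the cohort (as
    :class:`~ampliphase.haplotypes.IndividualGenotypes` with panel SNPs
    named ``snp0``, ``snp1``, ...) and the realised haplotype counts, from
    which expected editability fractions can be computed exactly.
    """
    from .haplotypes import IndividualGenotypes

    for cls in ("normal", "expanded"):
        if cls not in haplotype_freqs:
            raise ValueError(f"haplotype_freqs missing class {cls!r}")
        total = sum(f for _, f in haplotype_freqs[cls])
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{cls} haplotype frequencies sum to {total}, not 1")
    panel_size = len(haplotype_freqs["normal"][0][0])
    snp_ids = [f"snp{i}" for i in range(panel_size)]
    rng = np.random.default_rng(rng_seed)

    cohort = []
    realised: dict[str, list[tuple[int, ...]]] = {"normal": [], "expanded": []}
    for i in range(n_individuals):
        chosen = {}
        for cls in ("normal", "expanded"):
            vectors = [v for v, _ in haplotype_freqs[cls]]
            freqs = np.array([f for _, f in haplotype_freqs[cls]])
            idx = rng.choice(len(vectors), p=freqs / freqs.sum())
            chosen[cls] = vectors[idx]
            realised[cls].append(vectors[idx])
        cohort.append(
            IndividualGenotypes(
                individual=f"ind{i:04d}",
                normal=dict(zip(snp_ids, chosen["normal"])),
                expanded=dict(zip(snp_ids, chosen["expanded"])),
            )
        )
    return cohort, {"panel": snp_ids, "drawn": realised}
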