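"""Run configuration and reproducibility plumbing.

A :class:`RunConfig` aggregates the pipeline thresholds (all of which
default to the values the method was characterised with) plus paths, and a
single global seed.  Per-stage seeds are derived from the global seed by
hashing the stage name, so any one stage can be re-run in isolation and
reproduce its output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .phasing import CHI2_CUTOFF_95

__all__ = ["RunConfig", "stage_seed", "load_run_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and paths of one pipeline run (all overridable)."""

    locus_path: str | None = None
    barcodes_path: str | None = None
    samples_path: str | None = None
    out_dir: str = "ampliphase_out"
    seed: int = 0

    min_mapq: int = 30
    min_reads: int = 50
    expansion_threshold: int = 36
    target_coverage: int = 200
    identity_threshold: float = 0.80
    word_size: int = 6
    chi2_cutoff: float = CHI2_CUTOFF_95
    homozygous_fraction: float = 0.7
    min_depth: int = 50
    decoy_units: int = 1000

    def to_provenance(self, version: str) -> dict:
        record = dataclasses.asdict(self)
        record["tool_version"] = version
        return record

    def write_provenance(self, path: str | Path, version: str) -> None:
        Path(path).write_text(json.dumps(self.to_provenance(version), indent=2) + "\n")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from TOML; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
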