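"""End-to-end pipeline orchestration.

Wires the stages (demux -> quantify -> phase -> call) over a shared output
directory, with structured per-stage accounting, a provenance record
sufficient to reproduce the run (config, seed, tool version), and
idempotent re-runs guarded by ``force``.  Each stage consumes the previous
stage's declared outputs, so any ordered subset of stages can be run as
long as its inputs exist.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .config import RunConfig, stage_seed
from .demux import BarcodeManifest, demux_run
from .locus import LocusModel
from .phasing import phase_sample
from .repeats import quantify_sample
from .variants import call_allele_snps, downsample_reads, write_vcf

__all__ = ["run_pipeline", "PIPELINE_STAGES", "PipelineError"]

PIPELINE_STAGES = ("demux", "quantify", "phase", "call")

logger = logging.getLogger("ampliphase")


class PipelineError(RuntimeError):
    """A stage failed or its inputs are missing."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: required input {path} does not exist")
    return path


def _read_fastq_ids_seqs(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def _sample_fastqs(demux_dir: Path) -> list[Path]:
    return sorted(
        p for p in demux_dir.glob("*.fastq") if p.stem != "unassigned"
    )


def run_pipeline(
    config: RunConfig,
    stages: list[str],
    fastq: str | Path | None = None,
    manifest: BarcodeManifest | None = None,
    locus: LocusModel | None = None,
    force: bool = False,
) -> dict:
    """Execute an ordered subset of pipeline stages.

    Returns the run report (also written to ``report.json`` in the output
    directory, next to ``provenance.json``).
    """
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}; valid: {PIPELINE_STAGES}")
    stages = sorted(set(stages), key=PIPELINE_STAGES.index)

    out_dir = Path(config.out_dir)
    report_path = out_dir / "report.json"
    if report_path.exists() and not force:
        raise PipelineError(
            f"output directory {out_dir} already holds a run report; "
            "pass force=True (--force) to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    config.write_provenance(out_dir / "provenance.json", __version__)

    report: dict = {"stages": {}}

    if "demux" in stages:
        if fastq is None or manifest is None:
            raise PipelineError("stage 'demux': needs a FASTQ and a barcode manifest")
        _require(Path(fastq), "demux")
        counts = demux_run(fastq, manifest, out_dir / "demux", config.min_mapq)
        logger.info("demux: %d bins, %d reads", len(counts), sum(counts.values()))
        report["stages"]["demux"] = {"bins": counts}

    if "quantify" in stages:
        if locus is None:
            raise PipelineError("stage 'quantify': needs a locus model")
        demux_dir = out_dir / "demux"
        if demux_dir.exists():
            sample_files = _sample_fastqs(demux_dir)
        elif fastq is not None:
            sample_files = [_require(Path(fastq), "quantify")]
        else:
            raise PipelineError("stage 'quantify': no demultiplexed samples or input FASTQ")
        quant_dir = out_dir / "quantify"
        quant_dir.mkdir(exist_ok=True)
        stage_report = {}
        for sample_file in sample_files:
            reads = _read_fastq_ids_seqs(sample_file)
            profiles, unquantified = quantify_sample(reads, locus, config.decoy_units)
            out_tsv = quant_dir / f"{sample_file.stem}.profiles.tsv"
            with open(out_tsv, "w", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t")
                writer.writerow(["read_id", "m", "n", "score"])
                for p in profiles:
                    writer.writerow([p.read_id, p.m, p.n, p.score])
            stage_report[sample_file.stem] = {
                "profiles": len(profiles),
                "unquantified": len(unquantified),
            }
            logger.info(
                "quantify[%s]: %d profiled, %d unquantified",
                sample_file.stem,
                len(profiles),
                len(unquantified),
            )
        report["stages"]["quantify"] = stage_report

    if "phase" in stages:
        quant_dir = _require(out_dir / "quantify", "phase")
        phase_dir = out_dir / "phase"
        phase_dir.mkdir(exist_ok=True)
        stage_report = {}
        from .repeats import RepeatProfile

        for tsv in sorted(quant_dir.glob("*.profiles.tsv")):
            sample = tsv.stem.replace(".profiles", "")
            profiles = []
            with open(tsv, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    profiles.append(
                        RepeatProfile(
                            read_id=row["read_id"],
                            m=int(row["m"]),
                            n=int(row["n"]),
                            score=int(row["score"]),
                            grid_evaluations=0,
                        )
                    )
            result = phase_sample(
                profiles,
                rng_seed=stage_seed(config.seed, f"phase:{sample}"),
                min_reads=config.min_reads,
                chi2_cutoff=config.chi2_cutoff,
                expansion_threshold=config.expansion_threshold,
            )
            summary = {
                "qc_pass": result.qc_pass,
                "qc_reason": result.qc_reason,
                "discarded_outliers": len(result.discarded_outliers),
                "discarded_low_probability": len(result.discarded_low_probability),
                "groups": [
                    {
                        "label": g.label,
                        "role": g.role,
                        "size": g.size,
                        "mean": list(g.mean),
                        "covariance": [list(row) for row in g.covariance],
                        "repeat_estimate": list(g.repeat_estimate),
                    }
                    for g in result.groups
                ],
            }
            (phase_dir / f"{sample}.phase.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )
            for g in result.groups:
                (phase_dir / f"{sample}.{g.role or g.label}.reads.txt").write_text(
                    "\n".join(sorted(g.read_ids)) + "\n"
                )
            stage_report[sample] = {
                "qc_pass": result.qc_pass,
                "groups": [g.size for g in result.groups],
            }
            logger.info("phase[%s]: qc_pass=%s", sample, result.qc_pass)
        report["stages"]["phase"] = stage_report

    if "call" in stages:
        if locus is None:
            raise PipelineError("stage 'call': needs a locus model")
        phase_dir = _require(out_dir / "phase", "call")
        call_dir = out_dir / "call"
        call_dir.mkdir(exist_ok=True)
        stage_report = {}
        for phase_json in sorted(phase_dir.glob("*.phase.json")):
            sample = phase_json.name.replace(".phase.json", "")
            summary = json.loads(phase_json.read_text())
            if not summary["qc_pass"]:
                stage_report[sample] = {"skipped": summary["qc_reason"]}
                continue
            demux_fastq = out_dir / "demux" / f"{sample}.fastq"
            source = demux_fastq if demux_fastq.exists() else Path(fastq or "")
            _require(source, "call")
            seq_by_id = dict(_read_fastq_ids_seqs(source))
            n_calls = {}
            for group in summary["groups"]:
                role = group["role"]
                m_star, n_star = group["repeat_estimate"]
                template = locus.build_template(m_star, n_star)
                ids_file = phase_dir / f"{sample}.{role}.reads.txt"
                read_ids = [
                    line.strip()
                    for line in ids_file.read_text().splitlines()
                    if line.strip()
                ]
                reads = [(rid, seq_by_id[rid]) for rid in read_ids if rid in seq_by_id]
                reads = downsample_reads(
                    reads,
                    amplicon_length=len(template),
                    target_coverage=config.target_coverage,
                    rng_seed=stage_seed(config.seed, f"call:{sample}:{role}"),
                )
                calls = call_allele_snps(
                    reads,
                    template,
                    allele=role,
                    min_depth=config.min_depth,
                    homozygous_fraction=config.homozygous_fraction,
                )
                write_vcf(
                    calls,
                    call_dir / f"{sample}.{role}.vcf",
                    contig=f"{sample}_{role}",
                    contig_length=len(template),
                )
                n_calls[role] = len(calls)
            stage_report[sample] = n_calls
            logger.info("call[%s]: %s", sample, n_calls)
        report["stages"]["call"] = stage_report

    report_path.write_text(json.dumps(report, indent=2) + "\n")
    return report
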