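"""Anchor-aware dual-barcode demultiplexing of amplicon long reads.

Each read of a dual-barcoded amplicon starts (in amplicon orientation) with
the forward barcode followed by the first stretch of amplicon sequence, and
ends with the reverse complement of the backward barcode preceded by the
reverse complement of the amplicon's terminal stretch.  Matching a bare
16-32 bp barcode against a noisy long read invites random internal hits, so
every candidate barcode is matched as a composite probe ``barcode + anchor``
where the anchor is the 256-bp amplicon sequence immediately next to the
barcode.  The anchor pins the alignment to the correct position; the
barcode's marginal score on top of an anchor-only baseline measures how
well the barcode itself is supported.

A read is assigned to a sample only when the barcodes on both sides are
confidently determined (Phred-scaled mapping quality >= 30 by default) in a
single coherent read orientation, and the (forward, backward) pair is
declared in the sample manifest.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .alignment import MAX_MAPQ, MappingConfidence, edit_distance_semiglobal, mapq_of, revcomp

__all__ = [
    "BarcodeManifest",
    "DemuxAssignment",
    "match_barcode_side",
    "demux_read",
    "demux_run",
]

#: Default Phred-scaled confidence required on each side.
DEFAULT_MAPQ_THRESHOLD = 30

#: A candidate barcode is considered only when its marginal score (matches
#: beyond the anchor-only baseline) reaches this fraction of the barcode
#: length; this rejects reads whose barcode region is unrelated sequence.
MIN_MARGINAL_FRACTION = 0.75

#: Extra target window beyond the probe length at each read end.
WINDOW_SLACK = 100


@dataclass(frozen=True)
class BarcodeManifest:
    """Barcode and sample definitions for one sequencing pool.

    ``anchor_forward`` is the amplicon sequence immediately 3' of the
    forward barcode (amplicon orientation).  ``anchor_backward`` is the
    sequence immediately 3' of the backward barcode *on the reverse
    strand*, i.e. ``barcode + anchor_backward`` is a prefix of the
    reverse-complemented read.
    """

    forward_barcodes: dict[str, str]
    backward_barcodes: dict[str, str]
    sample_map: dict[tuple[str, str], str]
    anchor_forward: str
    anchor_backward: str

    def __post_init__(self):
        for side_name, side in (
            ("forward", self.forward_barcodes),
            ("backward", self.backward_barcodes),
        ):
            if not side:
                raise ValueError(f"no {side_name} barcodes in manifest")
            if len(set(side.values())) != len(side):
                raise ValueError(f"duplicate {side_name} barcode sequences")
        if not self.anchor_forward or not self.anchor_backward:
            raise ValueError("manifest anchors must be non-empty")
        for fid, bid in self.sample_map:
            if fid not in self.forward_barcodes or bid not in self.backward_barcodes:
                raise ValueError(f"sample pair ({fid}, {bid}) uses unknown barcode ids")
        if len(set(self.sample_map.values())) != len(self.sample_map):
            raise ValueError("duplicate sample names in manifest")


@dataclass(frozen=True)
class DemuxAssignment:
    read_id: str
    forward: tuple[str, int] | None  # (barcode id, mapq)
    backward: tuple[str, int] | None
    sample: str | None
    orientation: str | None  # "forward" | "reverse-complement"
    reason: str = ""


def _side_candidates(
    window: str,
    barcodes: dict[str, str],
    anchor: str,
) -> list[tuple[str, int]]:
    """Marginal barcode scores within one read-end window.

    The probe ``barcode + anchor`` and the bare anchor are aligned
    semi-globally (probe consumed, window ends free); the candidate's score
    is the barcode's marginal match contribution
    ``barcode_length - (d_probe - d_anchor)`` clamped at zero.  Candidates
    below ``MIN_MARGINAL_FRACTION * barcode_length`` are dropped.
    """
    d_anchor = edit_distance_semiglobal(anchor, window)
    scored = []
    for bc_id, bc_seq in barcodes.items():
        d_probe = edit_distance_semiglobal(bc_seq + anchor, window)
        marginal = max(0, len(bc_seq) - (d_probe - d_anchor))
        if marginal >= MIN_MARGINAL_FRACTION * len(bc_seq):
            scored.append((bc_id, marginal))
    return scored


def _match_side_oriented(
    seq: str, side: str, manifest: BarcodeManifest
) -> tuple[str | None, MappingConfidence]:
    """Best barcode for one side of a read given in amplicon orientation."""
    if side == "forward":
        barcodes, anchor = manifest.forward_barcodes, manifest.anchor_forward
        end_seq = seq
    elif side == "backward":
        barcodes, anchor = manifest.backward_barcodes, manifest.anchor_backward
        end_seq = revcomp(seq)
    else:
        raise ValueError(f"unknown side {side!r}")
    probe_len = max(len(b) for b in barcodes.values()) + len(anchor)
    if len(seq) <= probe_len:
        return None, MappingConfidence(mapq=0, best_score=0, second_score=0)
    window = end_seq[: probe_len + WINDOW_SLACK]
    scored = _side_candidates(window, barcodes, anchor)
    if not scored:
        return None, MappingConfidence(mapq=0, best_score=0, second_score=0)
    conf = mapq_of([s for _, s in scored])
    best_id = max(scored, key=lambda x: x[1])[0]
    return best_id, conf


def match_barcode_side(
    read_seq: str, side: str, manifest: BarcodeManifest
) -> tuple[str | None, MappingConfidence]:
    """Best candidate barcode and its mapping confidence for one read side.

    Both read orientations are tried and the one with the higher best score
    wins.  Returns ``(None, zero-confidence)`` when the read is shorter
    than the probe or no candidate clears the marginal-score floor.
    """
    best: tuple[str | None, MappingConfidence] = (
        None,
        MappingConfidence(mapq=0, best_score=0, second_score=0),
    )
    for seq in (read_seq.upper(), revcomp(read_seq.upper())):
        bc_id, conf = _match_side_oriented(seq, side, manifest)
        if bc_id is not None and conf.best_score > best[1].best_score:
            best = (bc_id, conf)
    return best


def demux_read(
    read_id: str,
    read_seq: str,
    manifest: BarcodeManifest,
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
) -> DemuxAssignment:
    """Assign one read to a sample via its forward/backward barcode pair.

    Both sides must pass the MAPQ threshold in the same read orientation
    and the pair must exist in the sample map; otherwise the read is left
    unassigned with the failure reason recorded.  Score ties between
    candidate barcodes yield MAPQ 0 and therefore discard the read.
    """
    read_seq = read_seq.upper()
    best_orient: tuple[str, tuple, tuple] | None = None
    for orientation, seq in (
        ("forward", read_seq),
        ("reverse-complement", revcomp(read_seq)),
    ):
        fwd = _match_side_oriented(seq, "forward", manifest)
        bwd = _match_side_oriented(seq, "backward", manifest)
        combined = fwd[1].best_score + bwd[1].best_score
        if best_orient is None or combined > best_orient[0]:
            best_orient = (combined, orientation, fwd, bwd)
    _, orientation, (fwd_id, fwd_conf), (bwd_id, bwd_conf) = best_orient

    fwd_field = (fwd_id, fwd_conf.mapq) if fwd_id is not None else None
    bwd_field = (bwd_id, bwd_conf.mapq) if bwd_id is not None else None

    fails = []
    if fwd_id is None or fwd_conf.mapq < mapq_threshold:
        fails.append("forward")
    if bwd_id is None or bwd_conf.mapq < mapq_threshold:
        fails.append("backward")
    if fails:
        return DemuxAssignment(
            read_id,
            fwd_field,
            bwd_field,
            sample=None,
            orientation=None,
            reason="low_mapq_" + "_".join(fails),
        )
    sample = manifest.sample_map.get((fwd_id, bwd_id))
    if sample is None:
        return DemuxAssignment(
            read_id,
            fwd_field,
            bwd_field,
            sample=None,
            orientation=orientation,
            reason="unexpected_pair",
        )
    return DemuxAssignment(read_id, fwd_field, bwd_field, sample, orientation)


def demux_run(
    fastq_in: str | Path,
    manifest: BarcodeManifest,
    out_dir: str | Path,
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
) -> dict[str, int]:
    """Demultiplex a FASTQ file into one FASTQ per sample plus unassigned.

    Every input read lands in exactly one output file; a summary TSV
    (``demux_summary.tsv``) counts reads per sample and per failure reason.
    Returns the per-bin counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handles = {}
    counts: Counter[str] = Counter()
    reasons: Counter[str] = Counter()
    try:
        for idx, record in enumerate(SeqIO.parse(str(fastq_in), "fastq")):
            try:
                assignment = demux_read(record.id, str(record.seq), manifest, mapq_threshold)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(f"failed on FASTQ record {idx} ({record.id})") from exc
            bin_name = assignment.sample if assignment.sample else "unassigned"
            if assignment.sample is None:
                reasons[assignment.reason] += 1
            if bin_name not in handles:
                handles[bin_name] = open(out_dir / f"{bin_name}.fastq", "w")
            SeqIO.write(record, handles[bin_name], "fastq")
            counts[bin_name] += 1
    finally:
        for fh in handles.values():
            fh.close()
    with open(out_dir / "demux_summary.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["bin", "reads"])
        for name in sorted(counts):
            writer.writerow([name, counts[name]])
        for reason in sorted(reasons):
            writer.writerow([f"unassigned:{reason}", reasons[reason]])
    return dict(counts)


def load_manifest(
    barcodes_tsv: str | Path,
    samples_tsv: str | Path,
    anchor_forward: str,
    anchor_backward: str,
) -> BarcodeManifest:
    """Build a manifest from TSV files.

    ``barcodes_tsv`` columns: side (forward/backward), id, sequence.
    ``samples_tsv`` columns: sample, fwd_id, rev_id.
    """
    fwd: dict[str, str] = {}
    bwd: dict[str, str] = {}
    with open(barcodes_tsv, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            target = fwd if row["side"] == "forward" else bwd
            target[row["id"]] = row["sequence"].upper()
    sample_map: dict[tuple[str, str], str] = {}
    with open(samples_tsv, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sample_map[(row["fwd_id"], row["rev_id"])] = row["sample"]
    return BarcodeManifest(
        forward_barcodes=fwd,
        backward_barcodes=bwd,
        sample_map=sample_map,
        anchor_forward=anchor_forward.upper(),
        anchor_backward=anchor_backward.upper(),
    )
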