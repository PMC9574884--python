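"""Anchored dual-barcode demultiplexing: assignment rules and conservation."""

import numpy as np
import pytest
from Bio import SeqIO

from ampliphase.alignment import revcomp
from ampliphase.demux import demux_read, demux_run, match_barcode_side
from ampliphase.simulate import (
    AlleleSpec,
    ErrorModel,
    SampleSpec,
    SimulationConfig,
    simulate_pool,
    write_fastq,
)

from conftest import make_manifest, random_dna


def _exact_read(manifest, fwd_id, bwd_id, insert_len=300, seed=5):
    """Error-free read: fwd barcode+anchor, insert, revcomp(bwd barcode+anchor)."""
    rng = np.random.default_rng(seed)
    insert = random_dna(rng, insert_len)
    return (
        manifest.forward_barcodes[fwd_id]
        + manifest.anchor_forward
        + insert
        + revcomp(manifest.backward_barcodes[bwd_id] + manifest.anchor_backward)
    )


class TestMatchBarcodeSide:
    def test_exact_read_gets_capped_mapq(self, manifest):
        read = _exact_read(manifest, "F1", "B2")
        bc_id, conf = match_barcode_side(read, "forward", manifest)
        assert bc_id == "F1"
        assert conf.mapq == 60
        bc_id, conf = match_barcode_side(read, "backward", manifest)
        assert bc_id == "B2"
        assert conf.mapq == 60

    def test_reverse_complemented_read_still_matches(self, manifest):
        read = revcomp(_exact_read(manifest, "F0", "B0"))
        bc_id, conf = match_barcode_side(read, "forward", manifest)
        assert bc_id == "F0"
        assert conf.mapq >= 30

    def test_random_barcode_region_unassignable(self, manifest):
        """100 reads with randomised barcode regions: none pass MAPQ 30."""
        rng = np.random.default_rng(8)
        bc_len = len(manifest.forward_barcodes["F0"])
        passed = 0
        for _ in range(100):
            read = random_dna(rng, bc_len) + manifest.anchor_forward + random_dna(rng, 300)
            bc_id, conf = match_barcode_side(read, "forward", manifest)
            if bc_id is not None and conf.mapq >= 30:
                passed += 1
        assert passed == 0

    def test_one_mismatch_competitor_lowers_mapq(self):
        """Two barcodes differing by 1 bp: exact one wins, mapq is the
        hand-evaluated value of the fixed formula.

        Marginal scores are 16 (exact) and 13 (one substitution: the probe
        pays one mismatch more than the anchor baseline under unit costs,
        i.e. 16 - 3 under the affine-equivalent marginal used here), giving
        min(60, round(60 * (16 - 15) / 16)) for edit marginals 16 vs 15:
        the single-base edit costs 1, so second = 15 and mapq = round(60/16)
        = 4 — well under the assignment threshold.
        """
        rng = np.random.default_rng(13)
        bc = random_dna(rng, 16)
        # mutate one position to build the near-identical competitor
        pos = 7
        other = bc[:pos] + ("A" if bc[pos] != "A" else "C") + bc[pos + 1 :]
        manifest = make_manifest(n_forward=1, n_backward=1, seed=14)
        manifest.forward_barcodes.clear()
        manifest.forward_barcodes.update({"F0": bc, "F1": other})
        read = bc + manifest.anchor_forward + random_dna(rng, 200)
        bc_id, conf = match_barcode_side(read, "forward", manifest)
        assert bc_id == "F0"
        assert conf.best_score == 16
        assert conf.second_score == 15
        assert conf.mapq == round(60 * (16 - 15) / 16)

    def test_read_shorter_than_probe_is_unassignable(self, manifest):
        bc_id, conf = match_barcode_side("ACGT" * 10, "forward", manifest)
        assert bc_id is None
        assert conf.mapq == 0


class TestDemuxRead:
    def test_both_sides_pass_known_pair(self, manifest):
        read = _exact_read(manifest, "F2", "B1")
        assignment = demux_read("r1", read, manifest)
        assert assignment.sample == "s2_1"
        assert assignment.forward[0] == "F2"
        assert assignment.backward[0] == "B1"

    def test_one_weak_side_leaves_read_unassigned(self, manifest):
        rng = np.random.default_rng(17)
        bc_len = len(manifest.backward_barcodes["B0"])
        read = (
            manifest.forward_barcodes["F0"]
            + manifest.anchor_forward
            + random_dna(rng, 300)
            + revcomp(random_dna(rng, bc_len) + manifest.anchor_backward)
        )
        assignment = demux_read("r1", read, manifest)
        assert assignment.sample is None
        assert "backward" in assignment.reason

    def test_unknown_pair_is_reported(self, manifest):
        # restrict the sample map to a subset of pairs
        restricted = {("F0", "B0"): "only_sample"}
        manifest.sample_map.clear()
        manifest.sample_map.update(restricted)
        read = _exact_read(manifest, "F1", "B1")
        assignment = demux_read("r1", read, manifest)
        assert assignment.sample is None
        assert assignment.reason == "unexpected_pair"

    def test_threshold_monotonicity(self, manifest):
        """Raising the MAPQ threshold never increases assignments."""
        rng = np.random.default_rng(19)
        config = SimulationConfig(
            locus=_small_locus(),
            samples=(
                SampleSpec("s0_0", AlleleSpec(20, 7), AlleleSpec(45, 7), coverage=10),
                SampleSpec("s1_1", AlleleSpec(18, 10), AlleleSpec(50, 7), coverage=10),
            ),
            manifest=manifest,
            error_model=ErrorModel(0.02, 0.04, 0.04),
            rng_seed=55,
        )
        truth = simulate_pool(config)
        counts = []
        for threshold in (0, 30, 60):
            assigned = sum(
                1
                for r in truth.reads
                if demux_read(r.read_id, r.sequence, manifest, threshold).sample
            )
            counts.append(assigned)
        assert counts == sorted(counts, reverse=True)


def _small_locus():
    from ampliphase.locus import demo_locus

    return demo_locus()


class TestDemuxRun:
    def test_empty_fastq_gives_empty_outputs(self, manifest, tmp_path):
        fastq = tmp_path / "empty.fastq"
        fastq.write_text("")
        counts = demux_run(fastq, manifest, tmp_path / "out")
        assert counts == {}
        summary = (tmp_path / "out" / "demux_summary.tsv").read_text()
        assert summary.startswith("bin\treads")

    def test_error_free_pool_is_fully_recovered(self, manifest, tmp_path):
        """Zero error rate: per-sample counts equal the simulator's truth."""
        samples = tuple(
            SampleSpec(f"s{i}_{j}", AlleleSpec(20, 7), AlleleSpec(45, 7), coverage=5)
            for i in range(2)
            for j in range(2)
        )
        config = SimulationConfig(
            locus=_small_locus(),
            samples=samples,
            manifest=manifest,
            error_model=ErrorModel(0.0, 0.0, 0.0),
            rng_seed=23,
        )
        truth = simulate_pool(config)
        fastq = tmp_path / "pool.fastq"
        write_fastq(truth.reads, fastq)
        counts = demux_run(fastq, manifest, tmp_path / "out")
        for spec in samples:
            assert counts[spec.name] == 2 * spec.coverage
        assert "unassigned" not in counts

    def test_read_conservation_and_duplicate_ids(self, manifest, tmp_path):
        """Every input read lands in exactly one bin; duplicates count twice."""
        read = _exact_read(manifest, "F0", "B0")
        fastq = tmp_path / "dup.fastq"
        record = f"@dup\n{read}\n+\n{'I' * len(read)}\n"
        fastq.write_text(record * 2 + f"@junk\n{'ACGT' * 50}\n+\n{'I' * 200}\n")
        counts = demux_run(fastq, manifest, tmp_path / "out")
        assert sum(counts.values()) == 3
        assert counts["s0_0"] == 2
        out_reads = list(SeqIO.parse(str(tmp_path / "out" / "s0_0.fastq"), "fastq"))
        assert len(out_reads) == 2

    def test_noisy_pool_misassignment_below_one_percent(self, tmp_path):
        """32-bp barcodes, default error model: <1% cross-sample errors."""
        manifest = make_manifest(n_forward=3, n_backward=3, barcode_length=32, seed=61)
        samples = tuple(
            SampleSpec(f"s{i}_{j}", AlleleSpec(20, 7), AlleleSpec(45, 7), coverage=15)
            for i in range(3)
            for j in range(3)
        )
        config = SimulationConfig(
            locus=_small_locus(),
            samples=samples,
            manifest=manifest,
            error_model=ErrorModel(),
            rng_seed=67,
        )
        truth = simulate_pool(config)
        truth_by_id = {r.read_id: r.sample for r in truth.reads}
        wrong = assigned = 0
        for r in truth.reads:
            result = demux_read(r.read_id, r.sequence, manifest)
            if result.sample is not None:
                assigned += 1
                if result.sample != truth_by_id[r.read_id]:
                    wrong += 1
        assert assigned > 0
        assert wrong / max(assigned, 1) < 0.01
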