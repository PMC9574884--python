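"""Joint repeat quantification: bounds, grid argmax, ground-truth recovery."""

from collections import Counter

import numpy as np
import pytest

from ampliphase.alignment import revcomp
from ampliphase.locus import LocusModel
from ampliphase.repeats import (
    estimate_bounds,
    joint_refine,
    longest_exact_run,
    quantify_sample,
)
from ampliphase.simulate import AlleleSpec, ErrorModel, simulate_allele_reads

from _oracles import brute_force_longest_run, dp_align_score_both

from conftest import random_dna


class TestExactRunScanner:
    def test_agrees_with_brute_force_at_every_phase(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACG"), size=int(rng.integers(10, 120))))
            motif = "".join(rng.choice(list("ACG"), size=int(rng.integers(1, 4))))
            assert longest_exact_run(seq, motif) == brute_force_longest_run(seq, motif)

    def test_interrupted_run(self):
        seq = "TT" + "CAG" * 10 + "T" + "CAG" * 9 + "TT"
        assert longest_exact_run(seq, "CAG") == 10


class TestEstimateBounds:
    def test_error_free_read_brackets_truth(self, locus):
        read = locus.build_template(20, 7)
        lower, upper = estimate_bounds(read, "CAG")
        assert lower == 20
        assert upper >= 20

    def test_interrupted_tract_bounds(self, locus):
        read = locus.left_flank + "CAG" * 10 + "T" + "CAG" * 9 + locus.right_flank
        lower, upper = estimate_bounds(read, "CAG")
        assert lower == 10  # longest exact run
        assert upper >= 19  # alignment spans the interruption

    def test_motif_free_read_is_unbounded_at_zero(self, rng):
        read = "".join(rng.choice(list("AT"), size=200))  # no CCG possible
        assert estimate_bounds(read, "CCG") == (0, 0)

    def test_reverse_complement_read_gives_same_bounds(self, locus):
        read = locus.build_template(25, 10)
        assert estimate_bounds(read, "CAG") == estimate_bounds(revcomp(read), "CAG")


class TestJointRefine:
    def test_generative_identity(self, locus):
        """Error-free reads built from (m, n) are recovered exactly."""
        for m, n in [(17, 7), (10, 5), (25, 12)]:
            read = locus.build_template(m, n)
            profile = joint_refine("r", read, locus, (10, 25), (5, 12))
            assert (profile.m, profile.n) == (m, n)
            assert profile.score == 0  # unit-cost: perfect template match
            assert profile.grid_evaluations == 16 * 8

    def test_noisy_reads_recover_modal_truth(self, locus):
        """3% substitution noise, 20 replicates: mode exact, all within 1."""
        rng = np.random.default_rng(71)
        model = ErrorModel(substitution=0.03, insertion=0.0, deletion=0.0)
        reads = simulate_allele_reads(locus, AlleleSpec(45, 7), 20, model, rng)
        estimates = []
        for read in reads:
            profile = joint_refine(read.read_id, read.sequence, locus, (40, 50), (4, 10))
            estimates.append((profile.m, profile.n))
            assert abs(profile.m - 45) <= 1 and abs(profile.n - 7) <= 1
        assert Counter(estimates).most_common(1)[0][0] == (45, 7)

    def test_degenerate_grid_rejected(self, locus):
        with pytest.raises(ValueError):
            joint_refine("r", locus.build_template(5, 5), locus, (10, 5), (5, 12))

    def test_argmax_matches_dp_oracle_over_full_grid(self, rng):
        """Small locus: grid argmax equals exhaustive DP-oracle re-scoring."""
        small = LocusModel(
            left_flank=random_dna(rng, 60),
            motif1="CAT",
            interstitial="GTACGTAGGT",
            motif2="CGG",
            right_flank=random_dna(rng, 60),
        )
        model = ErrorModel(substitution=0.05, insertion=0.03, deletion=0.03)
        for true_m, true_n in [(4, 3), (6, 6)]:
            reads = simulate_allele_reads(
                small, AlleleSpec(true_m, true_n), 3, model, rng
            )
            for read in reads:
                profile = joint_refine(
                    read.read_id, read.sequence, small, (2, 8), (1, 8)
                )
                # oracle: unit-cost semi-global score of every grid template
                best = None
                for m in range(2, 9):
                    for n in range(1, 9):
                        score = dp_align_score_both(
                            small.build_template(m, n),
                            read.sequence,
                            "semi-global",
                            match=0,
                            mismatch=-1,
                            gap_open=0,
                            gap_extend=-1,
                        )
                        if best is None or score > best[0]:
                            best = (score, m, n)
                assert profile.score == best[0]
                assert (profile.m, profile.n) == (best[1], best[2])

    def test_tie_breaks_to_smallest_m_then_n(self, rng):
        """With identical motifs and no interstitial, every (m, n) of equal
        m + n scores identically; the deterministic winner is the smallest
        m, then the smallest n."""
        degenerate = LocusModel(
            left_flank=random_dna(rng, 60),
            motif1="AA",
            interstitial="",
            motif2="AA",
            right_flank=random_dna(rng, 60),
        )
        read = degenerate.left_flank + "AA" * 4 + degenerate.right_flank
        profile = joint_refine("r", read, degenerate, (0, 4), (0, 4))
        assert profile.score == 0
        assert (profile.m, profile.n) == (0, 4)


class TestQuantifySample:
    def test_two_clean_alleles_give_two_profiles(self, locus):
        rng = np.random.default_rng(73)
        clean = ErrorModel(0.0, 0.0, 0.0)
        reads = []
        for spec in (AlleleSpec(20, 7), AlleleSpec(45, 10)):
            reads.extend(
                simulate_allele_reads(
                    locus, spec, 10, clean, rng, id_prefix=f"a{spec.m}"
                )
            )
        profiles, unquantified = quantify_sample(
            [(r.read_id, r.sequence) for r in reads], locus
        )
        assert unquantified == []
        assert set((p.m, p.n) for p in profiles) == {(20, 7), (45, 10)}

    def test_unalignable_reads_are_reported_unquantified(self, locus):
        # an all-N read cannot align to either motif's decoy in any
        # orientation; alignable junk is instead filtered during phasing
        junk = [("junk0", "N" * 150)]
        good = [("good", locus.build_template(20, 7))]
        profiles, unquantified = quantify_sample(good + junk, locus)
        assert unquantified == ["junk0"]
        assert [p.read_id for p in profiles] == ["good"]

    def test_single_read_single_profile(self, locus):
        profiles, _ = quantify_sample([("only", locus.build_template(18, 7))], locus)
        assert len(profiles) == 1
        assert (profiles[0].m, profiles[0].n) == (18, 7)

    def test_empty_input_rejected(self, locus):
        with pytest.raises(ValueError):
            quantify_sample([], locus)


class TestRobustness:
    def test_low_error_reads_within_one_unit(self, locus):
        """<=1% substitution error: estimate within 1 unit in >=99% of reads."""
        rng = np.random.default_rng(79)
        model = ErrorModel(substitution=0.01, insertion=0.0, deletion=0.0)
        n_reads = 150
        reads = simulate_allele_reads(locus, AlleleSpec(42, 7), n_reads, model, rng)
        profiles, _ = quantify_sample([(r.read_id, r.sequence) for r in reads], locus)
        within = sum(
            1 for p in profiles if abs(p.m - 42) <= 1 and abs(p.n - 7) <= 1
        )
        assert len(profiles) == n_reads
        assert within / n_reads >= 0.99
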