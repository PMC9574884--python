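"""Gaussian-mixture allele phasing: outliers, model selection, QC, roles."""

import numpy as np
import pytest

from ampliphase.phasing import (
    CHI2_CUTOFF_95,
    assign_roles,
    fit_and_assign,
    phase_sample,
    remove_outliers,
    select_component_count,
)
from ampliphase.repeats import RepeatProfile


def _profiles(pairs, prefix="r"):
    return [
        RepeatProfile(f"{prefix}{i}", int(m), int(n), 0, 0)
        for i, (m, n) in enumerate(pairs)
    ]


def _cloud(rng, center, n, sd=1.0):
    pts = rng.normal(center, sd, size=(n, 2))
    return [(max(0, round(m)), max(0, round(cc))) for m, cc in pts]


class TestRemoveOutliers:
    def test_single_extreme_value_removed(self):
        pairs = [(20, 7)] * 100 + [(200, 7)]
        kept, removed = remove_outliers(_profiles(pairs))
        assert len(removed) == 1
        assert removed[0].m == 200
        assert len(kept) == 100

    def test_identical_profiles_untouched(self):
        kept, removed = remove_outliers(_profiles([(20, 7)] * 30))
        assert removed == []
        assert len(kept) == 30

    def test_two_sd_deviation_survives(self):
        rng = np.random.default_rng(5)
        values = list(rng.normal(20, 2, size=200))
        # clamp the most extreme values to exactly 2 sd
        mean, sd = np.mean(values), np.std(values)
        pairs = [(float(np.clip(v, mean - 2 * sd, mean + 2 * sd)), 7.0) for v in values]
        profiles = [
            RepeatProfile(f"r{i}", m, n, 0, 0) for i, (m, n) in enumerate(pairs)
        ]
        kept, removed = remove_outliers(profiles)
        assert removed == []

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            remove_outliers(_profiles([(20, 7)]))


class TestModelSelection:
    def test_well_separated_clusters_select_two(self):
        rng = np.random.default_rng(101)
        pairs = _cloud(rng, (20, 7), 100) + _cloud(rng, (45, 7), 100)
        n, warning = select_component_count(_profiles(pairs), rng_seed=11)
        assert n == 2 and warning == ""

    def test_single_cluster_selects_one(self):
        rng = np.random.default_rng(103)
        pairs = _cloud(rng, (20, 7), 200)
        n, warning = select_component_count(_profiles(pairs), rng_seed=11)
        assert n == 1

    def test_integer_collapsed_cluster_still_selects_one(self):
        """All reads identical (zero variance once rounded): the jitter is
        what keeps BIC from over-fitting rounded data."""
        n, _ = select_component_count(_profiles([(20, 7)] * 120), rng_seed=7)
        assert n == 1

    def test_tiny_input_guard(self):
        n, warning = select_component_count(_profiles([(20, 7), (45, 7), (44, 7)]), 3)
        assert n == 1
        assert "profiles" in warning


class TestFitAndAssign:
    def test_separated_clusters_fully_recovered(self):
        rng = np.random.default_rng(107)
        a = _cloud(rng, (20, 7), 80)
        b = _cloud(rng, (45, 7), 80)
        profiles = _profiles(a, "a") + _profiles(b, "b")
        result = fit_and_assign(profiles, 2, rng_seed=13)
        assert result.qc_pass
        by_label = {g.label: g for g in result.groups}
        # allele1 is the smaller-m component; every 'a' read must be there
        a_ids = {p.read_id for p in _profiles(a, "a")}
        kept_a = by_label["allele1"].read_ids
        assert kept_a <= a_ids
        assert by_label["allele1"].repeat_estimate[0] == 20
        assert by_label["allele2"].repeat_estimate[0] == 45

    def test_low_coverage_allele_fails_qc(self):
        rng = np.random.default_rng(109)
        pairs = _cloud(rng, (20, 7), 150) + _cloud(rng, (45, 7), 49)
        result = fit_and_assign(_profiles(pairs), 2, rng_seed=13)
        assert not result.qc_pass
        assert "less than 50 reads" in result.qc_reason

    def test_single_component_fails_qc(self):
        rng = np.random.default_rng(113)
        result = fit_and_assign(_profiles(_cloud(rng, (20, 7), 120)), 1, rng_seed=13)
        assert not result.qc_pass
        assert result.qc_reason == "only one allele detected"

    def test_distant_read_discarded_by_equiprobability_filter(self):
        """A read at squared Mahalanobis distance > 5.991 from both
        components is dropped; 9 > chi2_0.95(2)."""
        rng = np.random.default_rng(127)
        pairs = _cloud(rng, (20, 7), 100) + _cloud(rng, (45, 7), 100)
        profiles = _profiles(pairs)
        far = RepeatProfile("planted", 32, 7, 0, 0)  # between the clusters
        result = fit_and_assign(profiles + [far], 2, rng_seed=13)
        # verify the planted point is beyond the contour of its component
        d2 = []
        for g in result.groups:
            delta = np.array([32.0, 7.0]) - np.array(g.mean)
            d2.append(float(delta @ np.linalg.inv(g.covariance) @ delta))
        assert min(d2) > CHI2_CUTOFF_95
        assert "planted" in result.discarded_low_probability

    def test_filtering_monotonicity(self):
        """Every discarded read is farther from its component than any kept
        read of that component."""
        rng = np.random.default_rng(131)
        pairs = _cloud(rng, (20, 7), 120, sd=2.0) + _cloud(rng, (45, 7), 120, sd=2.0)
        profiles = _profiles(pairs)
        result = fit_and_assign(profiles, 2, rng_seed=17)
        by_id = {p.read_id: p for p in profiles}

        def dist2(pid, group):
            cov_inv = np.linalg.inv(group.covariance)
            delta = np.array(
                [by_id[pid].m - group.mean[0], by_id[pid].n - group.mean[1]]
            )
            return float(delta @ cov_inv @ delta)

        for g in result.groups:
            kept_max = max(dist2(pid, g) for pid in g.read_ids)
            assert kept_max <= CHI2_CUTOFF_95
        for pid in result.discarded_low_probability:
            # nearest component still places the read beyond every kept read
            nearest = min(result.groups, key=lambda g: dist2(pid, g))
            kept_max = max(dist2(p, nearest) for p in nearest.read_ids)
            assert dist2(pid, nearest) > kept_max


class TestDeterminismAndJitter:
    def test_identical_inputs_and_seed_identical_result(self):
        rng = np.random.default_rng(137)
        pairs = _cloud(rng, (20, 7), 100) + _cloud(rng, (45, 10), 100)
        profiles = _profiles(pairs)
        r1 = phase_sample(profiles, rng_seed=99)
        r2 = phase_sample(profiles, rng_seed=99)
        assert [g.read_ids for g in r1.groups] == [g.read_ids for g in r2.groups]
        assert [g.repeat_estimate for g in r1.groups] == [
            g.repeat_estimate for g in r2.groups
        ]

    def test_jitter_only_affects_model_selection(self):
        """Different jitter seeds with the same selected N give identical
        final assignments (the GMM is trained on the unjittered data)."""
        rng = np.random.default_rng(139)
        pairs = _cloud(rng, (20, 7), 100) + _cloud(rng, (45, 7), 100)
        profiles = _profiles(pairs)
        n1, _ = select_component_count(profiles, rng_seed=1)
        n2, _ = select_component_count(profiles, rng_seed=2)
        assert n1 == n2 == 2
        r1 = fit_and_assign(profiles, n1, rng_seed=7)
        r2 = fit_and_assign(profiles, n2, rng_seed=7)
        assert [g.read_ids for g in r1.groups] == [g.read_ids for g in r2.groups]


class TestRoles:
    def _result_with_estimates(self, m1, m2):
        rng = np.random.default_rng(149)
        pairs = _cloud(rng, (m1, 7), 80) + _cloud(rng, (m2, 7), 80)
        return fit_and_assign(_profiles(pairs), 2, rng_seed=19)

    def test_classic_expanded_pair(self):
        result = assign_roles(self._result_with_estimates(20, 45))
        roles = {g.repeat_estimate[0]: g.role for g in result.groups}
        assert roles[20] == "normal"
        assert roles[45] == "expanded"

    def test_intermediate_plus_expanded(self):
        """34/43: the smallest expanded-vs-intermediate gap observed in
        practice; 34 stays normal (intermediate), 43 is expanded."""
        result = assign_roles(self._result_with_estimates(34, 43))
        roles = {g.repeat_estimate[0]: g.role for g in result.groups}
        assert roles[34] == "normal"
        assert roles[43] == "expanded"

    def test_two_normal_alleles(self):
        result = assign_roles(self._result_with_estimates(20, 30))
        assert {g.role for g in result.groups} == {"normal"}

    def test_threshold_boundary(self):
        result = assign_roles(self._result_with_estimates(20, 36))
        roles = {g.repeat_estimate[0]: g.role for g in result.groups}
        assert roles[36] == "expanded"


class TestParameterRecovery:
    def test_profile_level_diploid_recovery(self):
        """50 simulated diploid profile clouds (estimate noise matching the
        quantifier's behaviour): both allele estimates within +/-1 of truth
        in >=95% of samples."""
        rng = np.random.default_rng(151)
        ok = 0
        n_samples = 50
        for s in range(n_samples):
            m_norm = int(rng.integers(15, 31))
            m_exp = int(rng.integers(40, 61))
            ccg_n = int(rng.choice([7, 10]))
            ccg_e = int(rng.choice([7, 10]))
            # per-read estimate noise: mostly exact, occasional +/-1
            def noisy(center, n_reads):
                noise = rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1], size=n_reads)
                noise_n = rng.choice([-1, 0, 1], p=[0.05, 0.9, 0.05], size=n_reads)
                return list(zip(center[0] + noise, center[1] + noise_n))

            pairs = noisy((m_norm, ccg_n), 100) + noisy((m_exp, ccg_e), 100)
            result = phase_sample(_profiles(pairs), rng_seed=1000 + s)
            if len(result.groups) == 2:
                est = sorted(g.repeat_estimate[0] for g in result.groups)
                if abs(est[0] - m_norm) <= 1 and abs(est[1] - m_exp) <= 1:
                    ok += 1
        assert ok / n_samples >= 0.95
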