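"""Allele phasing of per-read repeat profiles with a 2-D Gaussian mixture.

Reads of a diploid sample form one or two clusters in the (m, n) plane of
joint repeat counts.  Phasing proceeds in four steps:

1. Outlier removal: profiles more than three standard deviations from the
   mean in either dimension are dropped (single pass, per dimension).
2. Model selection: the number of mixture components N in {1, 2} is chosen
   by BIC.  Because the repeat counts are integers, BIC over-fits rounded
   data; uniform jitter U(-0.5, 0.5) is added to every m and n before model
   selection only.  The jittered data are shared across both candidate N.
3. Fitting and assignment: the mixture with the selected N is fitted on the
   original integer profiles (EM, k-means initialisation, 10 restarts);
   each read goes to its maximum-responsibility component, and reads whose
   squared Mahalanobis distance to their component exceeds the chi-square
   0.95 quantile (df=2, ~5.991; the 95% equi-probability surface) are
   discarded so that downstream consensus calling stays clean.
4. QC: a sample fails when only one allele was detected or when either
   allele retains fewer than ``min_reads`` (default 50) reads.

The per-allele repeat estimate is the mode of the assigned integer (m, n)
pairs, not the Gaussian mean: reported repeat sizes must be integers.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .repeats import RepeatProfile

__all__ = [
    "AlleleGroup",
    "PhasingResult",
    "remove_outliers",
    "select_component_count",
    "fit_and_assign",
    "assign_roles",
    "phase_sample",
]

DEFAULT_MIN_READS = 50
#: Alleles with at least this many motif1 units are called expanded.
DEFAULT_EXPANSION_THRESHOLD = 36
#: chi-square 0.95 quantile, 2 degrees of freedom: the squared Mahalanobis
#: radius of the 95% equi-probability surface of a 2-D Gaussian.
CHI2_CUTOFF_95 = float(stats.chi2.ppf(0.95, df=2))

#: Minimum profile count to even attempt a 2-component fit (the 2-component
#: full-covariance mixture has 11 free parameters).
_MIN_PROFILES_FOR_TWO = 11


@dataclass(frozen=True)
class AlleleGroup:
    """One phased allele: reads, fitted Gaussian, and integer estimate."""

    label: str  # "allele1" | "allele2"
    mean: tuple[float, float]
    covariance: np.ndarray
    read_ids: frozenset[str]
    size: int
    repeat_estimate: tuple[int, int]
    role: str = "unassigned-role"  # "normal" | "expanded" | "unassigned-role"


@dataclass(frozen=True)
class PhasingResult:
    groups: tuple[AlleleGroup, ...]
    discarded_outliers: frozenset[str]
    discarded_low_probability: frozenset[str]
    qc_pass: bool
    qc_reason: str = ""
    warnings: tuple[str, ...] = field(default=())


def _as_array(profiles: list[RepeatProfile]) -> np.ndarray:
    return np.array([(p.m, p.n) for p in profiles], dtype=float)


def remove_outliers(
    profiles: list[RepeatProfile],
) -> tuple[list[RepeatProfile], list[RepeatProfile]]:
    """Single-pass per-dimension 3-standard-deviation outlier filter.

    A profile is removed when |m - mean_m| > 3 sd_m or |n - mean_n| > 3
    sd_n (population standard deviation).  A dimension with zero spread
    removes nothing on that dimension.
    """
    if len(profiles) < 2:
        raise ValueError("outlier removal requires at least 2 profiles")
    data = _as_array(profiles)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    keep_mask = np.ones(len(profiles), dtype=bool)
    for dim in range(2):
        if sd[dim] > 0:
            keep_mask &= np.abs(data[:, dim] - mean[dim]) <= 3 * sd[dim]
    kept = [p for p, k in zip(profiles, keep_mask) if k]
    removed = [p for p, k in zip(profiles, keep_mask) if not k]
    return kept, removed


def select_component_count(
    profiles: list[RepeatProfile], rng_seed: int
) -> tuple[int, str]:
    """Choose N in {1, 2} by BIC on jittered (m, n) data.

    Returns ``(N, warning)`` where the warning is non-empty when the
    2-component fit was not attempted for lack of data.  Ties favour N=1.
    """
    if len(profiles) < 2:
        raise ValueError("model selection requires at least 2 profiles")
    if len(profiles) < _MIN_PROFILES_FOR_TWO:
        return 1, (
            f"only {len(profiles)} profiles; fewer than the "
            f"{_MIN_PROFILES_FOR_TWO} parameters of a 2-component mixture"
        )
    rng = np.random.default_rng(rng_seed)
    data = _as_array(profiles)
    jittered = data + rng.uniform(-0.5, 0.5, size=data.shape)
    bics = {}
    for n_comp in (1, 2):
        gmm = GaussianMixture(
            n_components=n_comp,
            covariance_type="full",
            n_init=10,
            init_params="kmeans",
            random_state=int(rng_seed) % (2**31),
        )
        gmm.fit(jittered)
        bics[n_comp] = gmm.bic(jittered)
    return (2, "") if bics[2] < bics[1] else (1, "")


def fit_and_assign(
    profiles: list[RepeatProfile],
    n_components: int,
    rng_seed: int,
    min_reads: int = DEFAULT_MIN_READS,
    chi2_cutoff: float = CHI2_CUTOFF_95,
    discarded_outliers: list[RepeatProfile] | None = None,
    extra_warnings: tuple[str, ...] = (),
) -> PhasingResult:
    """Fit the selected mixture on the original integer (m, n) profiles.

    Reads are assigned to their maximum-responsibility component; reads
    outside the 95% equi-probability surface of their component (squared
    Mahalanobis distance above ``chi2_cutoff``) are discarded.  QC fails
    when only one component was selected or a component keeps fewer than
    ``min_reads`` reads.

    Two fitted components whose means differ by less than one repeat unit
    in both dimensions describe alleles the data cannot distinguish (repeat
    counts are integers); such a fit collapses to a single component before
    QC, which protects deep homozygous samples from a spurious split of
    their rounding noise.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    data = _as_array(profiles)
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=10,
        init_params="kmeans",
        random_state=int(rng_seed) % (2**31),
        reg_covar=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm.fit(data)
    if n_components == 2:
        separation = np.abs(gmm.means_[0] - gmm.means_[1]).max()
        empty = len(set(gmm.predict(data))) < 2
        if separation < 1.0 or empty:
            reason = (
                "a component captured no reads"
                if empty
                else "component separation < 1 repeat unit"
            )
            return fit_and_assign(
                profiles,
                1,
                rng_seed,
                min_reads=min_reads,
                chi2_cutoff=chi2_cutoff,
                discarded_outliers=discarded_outliers,
                extra_warnings=extra_warnings
                + (f"2-component fit collapsed: {reason}",),
            )
    labels = gmm.predict(data)

    # order components by mean m so allele1 is always the smaller repeat
    order = np.argsort(gmm.means_[:, 0])
    rank = {int(old): new for new, old in enumerate(order)}

    discarded_low: set[str] = set()
    members: dict[int, list[RepeatProfile]] = {i: [] for i in range(n_components)}
    for profile, comp in zip(profiles, labels):
        mean = gmm.means_[comp]
        cov_inv = np.linalg.inv(gmm.covariances_[comp])
        delta = np.array([profile.m, profile.n], dtype=float) - mean
        d2 = float(delta @ cov_inv @ delta)
        if d2 > chi2_cutoff:
            discarded_low.add(profile.read_id)
        else:
            members[rank[int(comp)]].append(profile)

    groups = []
    for new_idx in range(n_components):
        comp_profiles = members[new_idx]
        old_idx = int(order[new_idx])
        mode_mn = _modal_estimate(comp_profiles)
        groups.append(
            AlleleGroup(
                label=f"allele{new_idx + 1}",
                mean=tuple(float(x) for x in gmm.means_[old_idx]),
                covariance=gmm.covariances_[old_idx].copy(),
                read_ids=frozenset(p.read_id for p in comp_profiles),
                size=len(comp_profiles),
                repeat_estimate=mode_mn,
            )
        )

    if n_components == 1:
        qc_pass, qc_reason = False, "only one allele detected"
    elif any(g.size < min_reads for g in groups):
        qc_pass, qc_reason = False, f"an allele has less than {min_reads} reads"
    else:
        qc_pass, qc_reason = True, ""
    return PhasingResult(
        groups=tuple(groups),
        discarded_outliers=frozenset(
            p.read_id for p in (discarded_outliers or [])
        ),
        discarded_low_probability=frozenset(discarded_low),
        qc_pass=qc_pass,
        qc_reason=qc_reason,
        warnings=extra_warnings,
    )


def _modal_estimate(profiles: list[RepeatProfile]) -> tuple[int, int]:
    """Per-group integer point estimate: the modal (m, n) pair.

    Ties resolve to the lexicographically smaller pair.
    """
    if not profiles:
        return (0, 0)
    counts = Counter((p.m, p.n) for p in profiles)
    top = max(counts.values())
    return min(mn for mn, c in counts.items() if c == top)


def assign_roles(
    result: PhasingResult,
    expansion_threshold: int = DEFAULT_EXPANSION_THRESHOLD,
) -> PhasingResult:
    """Label allele groups as normal or expanded.

    With two groups, the group with the larger motif1 estimate is labelled
    expanded iff its estimate reaches ``expansion_threshold`` (default 36
    units); otherwise both are normal.  A single group is labelled by the
    same threshold.
    """
    groups = []
    ranked = sorted(result.groups, key=lambda g: g.repeat_estimate[0])
    for idx, group in enumerate(result.groups):
        is_largest = group is ranked[-1] and len(result.groups) > 1
        m_star = group.repeat_estimate[0]
        if len(result.groups) == 1:
            role = "expanded" if m_star >= expansion_threshold else "normal"
        elif is_largest:
            role = "expanded" if m_star >= expansion_threshold else "normal"
        else:
            role = "normal"
        groups.append(
            AlleleGroup(
                label=group.label,
                mean=group.mean,
                covariance=group.covariance,
                read_ids=group.read_ids,
                size=group.size,
                repeat_estimate=group.repeat_estimate,
                role=role,
            )
        )
    return PhasingResult(
        groups=tuple(groups),
        discarded_outliers=result.discarded_outliers,
        discarded_low_probability=result.discarded_low_probability,
        qc_pass=result.qc_pass,
        qc_reason=result.qc_reason,
        warnings=result.warnings,
    )


def phase_sample(
    profiles: list[RepeatProfile],
    rng_seed: int,
    min_reads: int = DEFAULT_MIN_READS,
    chi2_cutoff: float = CHI2_CUTOFF_95,
    expansion_threshold: int = DEFAULT_EXPANSION_THRESHOLD,
) -> PhasingResult:
    """Full phasing pipeline: outliers -> model selection -> fit -> roles."""
    kept, removed = remove_outliers(profiles)
    n_components, warning = select_component_count(kept, rng_seed)
    result = fit_and_assign(
        kept,
        n_components,
        rng_seed,
        min_reads=min_reads,
        chi2_cutoff=chi2_cutoff,
        discarded_outliers=removed,
        extra_warnings=(warning,) if warning else (),
    )
    return assign_roles(result, expansion_threshold)
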