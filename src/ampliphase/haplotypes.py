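"""Haplotype assembly and allele-specific editability accounting.

Once every QC-passed individual has phased per-allele genotypes over a
fixed SNP panel, each chromosome class (normal and expanded) contributes
one haplotype per individual: the vector of alternative-allele indicators
over the panel.  Haplotype frequencies are normalised within each class;
the all-reference vector is labelled Hap1 and the remaining haplotypes are
numbered by decreasing pooled frequency.

An individual can be edited allele-specifically via an SNP when the SNP is
heterozygous and the allele configuration places the intact (loss-type) or
created (gain-type) high-efficiency PAM exclusively on the expanded
chromosome:

* loss-type SNP: the expanded chromosome carries the reference base (PAM
  intact) and the normal chromosome the alternative base (PAM destroyed);
* gain-type SNP: the expanded chromosome carries the alternative base (PAM
  created) and the normal chromosome the reference base.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pam import PamEffect

__all__ = [
    "IndividualGenotypes",
    "assemble_haplotypes",
    "editability_report",
]


@dataclass(frozen=True)
class IndividualGenotypes:
    """Phased 0/1 (ref/alt) indicators per panel SNP for one individual."""

    individual: str
    normal: dict[str, int]  # snp id -> indicator on the normal chromosome
    expanded: dict[str, int]


def assemble_haplotypes(
    cohort: list[IndividualGenotypes],
    snp_panel: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Haplotype table with within-class frequencies.

    Individuals missing a genotype at any panel SNP are excluded (their ids
    are returned alongside).  The result has one row per observed haplotype
    with columns ``name``, one indicator column per panel SNP,
    ``freq_normal`` and ``freq_expanded``; frequencies within each class sum
    to 1.
    """
    if not snp_panel:
        raise ValueError("snp_panel must be non-empty")
    excluded = []
    vectors: dict[str, list[tuple[int, ...]]] = {"normal": [], "expanded": []}
    for indiv in cohort:
        try:
            normal_vec = tuple(indiv.normal[s] for s in snp_panel)
            expanded_vec = tuple(indiv.expanded[s] for s in snp_panel)
        except KeyError:
            excluded.append(indiv.individual)
            continue
        vectors["normal"].append(normal_vec)
        vectors["expanded"].append(expanded_vec)

    observed = sorted(set(vectors["normal"]) | set(vectors["expanded"]))
    if not observed:
        raise ValueError("no individuals with complete panel genotypes")

    counts = {
        cls: pd.Series(vectors[cls]).value_counts() for cls in ("normal", "expanded")
    }
    rows = []
    for vec in observed:
        n_norm = int(counts["normal"].get(vec, 0))
        n_exp = int(counts["expanded"].get(vec, 0))
        rows.append(
            {
                "vector": vec,
                "freq_normal": n_norm / max(1, len(vectors["normal"])),
                "freq_expanded": n_exp / max(1, len(vectors["expanded"])),
                "pooled": n_norm + n_exp,
            }
        )
    table = pd.DataFrame(rows)

    # Hap1 = all-reference haplotype; others numbered by pooled abundance.
    ref_vec = tuple(0 for _ in snp_panel)
    table["is_ref"] = table["vector"] == ref_vec
    table = table.sort_values(
        by=["is_ref", "pooled"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
    names = []
    next_id = 2 if table["is_ref"].any() else 1
    for _, row in table.iterrows():
        if row["is_ref"]:
            names.append("Hap1")
        else:
            names.append(f"Hap{next_id}")
            next_id += 1
    table["name"] = names
    for i, snp in enumerate(snp_panel):
        table[snp] = [v[i] for v in table["vector"]]
    table = table[["name", *snp_panel, "freq_normal", "freq_expanded"]]
    return table, excluded


def editability_report(
    cohort: list[IndividualGenotypes],
    pam_effects: list[PamEffect],
) -> dict:
    """Per-SNP and cohort-level allele-specific editability summary.

    For each SNP carrying at least one gain/loss PAM effect, individuals
    are classified by where the targetable PAM ends up; the report gives
    per-SNP editable fractions, the fraction editable via any SNP, and the
    four-way SNP distribution (alt on both chromosomes / expanded only /
    normal only / neither).
    """
    effect_type: dict[str, set[str]] = {}
    for eff in pam_effects:
        if eff.effect in ("gain", "loss"):
            effect_type.setdefault(eff.snp_id, set()).add(eff.effect)

    per_snp: dict[str, dict] = {}
    editable_any: set[str] = set()
    n = len(cohort)
    for snp_id, effects in sorted(effect_type.items()):
        editable = []
        breakdown = {"both": 0, "expanded_only": 0, "normal_only": 0, "neither": 0}
        for indiv in cohort:
            if snp_id not in indiv.normal or snp_id not in indiv.expanded:
                continue
            g_norm, g_exp = indiv.normal[snp_id], indiv.expanded[snp_id]
            if g_norm and g_exp:
                breakdown["both"] += 1
            elif g_exp:
                breakdown["expanded_only"] += 1
            elif g_norm:
                breakdown["normal_only"] += 1
            else:
                breakdown["neither"] += 1
            if g_norm == g_exp:
                continue  # homozygous: no allele-specific handle
            # heterozygous: which chromosome keeps/gains the PAM?
            can_edit = ("loss" in effects and g_exp == 0 and g_norm == 1) or (
                "gain" in effects and g_exp == 1 and g_norm == 0
            )
            if can_edit:
                editable.append(indiv.individual)
        editable_any.update(editable)
        per_snp[snp_id] = {
            "effects": sorted(effects),
            "editable_fraction": len(editable) / n if n else 0.0,
            "editable_individuals": sorted(editable),
            "breakdown": breakdown,
        }
    return {
        "n_individuals": n,
        "per_snp": per_snp,
        "any_snp_editable_fraction": len(editable_any) / n if n else 0.0,
        "editable_individuals": sorted(editable_any),
    }
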