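"""Merge PGM variants with VCF sites and classify allele concordance.

Weights attach to alleles by their base string, not by REF/ALT labels, so a
model whose effect allele happens to be the VCF REF ("effect_switch") is
informational, not an error: the dosage simply counts REF copies.  True
problems are strand flips (model alleles reported on the opposite strand,
detectable by complementing both alleles), palindromic A/T or C/G pairs
(where a strand flip is indistinguishable from an effect-direction flip) and
outright mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import pandas as pd

from .exceptions import PolicyError
from .vcf import GenotypeTable, VcfSite
from .weights import PGSModel, WeightEntry

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class MatchCategory(str, Enum):
    DEFAULT_MATCH = "default_match"
    EFFECT_SWITCH = "effect_switch"
    STRAND_FLIP = "strand_flip"
    EFFECT_SWITCH_WITH_STRAND_FLIP = "effect_switch_with_strand_flip"
    AMBIGUOUS_FLIP = "ambiguous_flip"
    INDEL = "indel"
    MISSING_SITE = "missing_site"
    MISMATCH = "mismatch"


#: categories whose effect allele can be located literally in the site alleles
_LITERAL_SCOREABLE = {
    MatchCategory.DEFAULT_MATCH,
    MatchCategory.EFFECT_SWITCH,
    MatchCategory.AMBIGUOUS_FLIP,
    MatchCategory.INDEL,
}

_STRAND_FLIPPED = {
    MatchCategory.STRAND_FLIP,
    MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP,
}


@dataclass(frozen=True)
class MergedVariant:
    """One model variant joined (or not) to its VCF site."""

    weight: WeightEntry
    site: Optional[VcfSite]
    site_idx: Optional[int]
    category: MatchCategory
    #: index into (REF,) + ALTs of the allele whose copies are counted as
    #: dosage; None when the variant cannot be scored.
    effect_allele_index: Optional[int]
    removed: bool = False  # dropped from scoring by policy (e.g. ambiguous)


def reverse_complement(allele: str) -> str:
    """Reverse complement of an A/C/G/T allele string.

    Indel alleles are never complemented by the matcher (complementing an
    indel is ambiguous without left/right normalization), but the primitive
    itself accepts any ACGT string.
    """
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement non-ACGT allele {allele!r}") from exc


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the single-base pair is strand-ambiguous: {A,T} or {C,G}."""
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


def assess_allele_match(weight: WeightEntry, site: VcfSite) -> MatchCategory:
    """Classify model-vs-VCF allele concordance for one variant.

    Decision order:

    1. any allele longer than one base on either side → ``indel`` when the
       model alleles match the site alleles literally, else ``mismatch``
       (indels are never complemented);
    2. palindromic model pair (A/T or C/G) → ``ambiguous_flip`` whenever both
       alleles appear at the site — apparent orientation cannot distinguish a
       strand flip from an effect-direction flip;
    3. both model alleles found as-reported among {REF} ∪ ALTs →
       ``effect_switch`` when the effect allele is REF, else ``default_match``;
    4. both model alleles found only after complementing → ``strand_flip``
       (complemented effect allele is an ALT) or
       ``effect_switch_with_strand_flip`` (complemented effect allele is REF);
    5. otherwise ``mismatch``.

    With no ``other_allele`` in the model, strand-flip detection is disabled
    and only ``default_match``/``effect_switch``/``mismatch`` are possible.
    """
    eff = weight.effect_allele
    oth = weight.other_allele
    site_alleles = set(site.alleles)

    model_has_indel = len(eff) > 1 or (oth is not None and len(oth) > 1)
    site_has_indel = any(len(a) > 1 for a in site.alleles)
    if model_has_indel or site_has_indel:
        literal = eff in site_alleles and (oth is None or oth in site_alleles)
        return MatchCategory.INDEL if literal else MatchCategory.MISMATCH

    if oth is not None and is_palindromic(eff, oth):
        if {eff, oth} <= site_alleles:
            return MatchCategory.AMBIGUOUS_FLIP
        return MatchCategory.MISMATCH

    if oth is None:
        if eff == site.ref:
            return MatchCategory.EFFECT_SWITCH
        if eff in site.alts:
            return MatchCategory.DEFAULT_MATCH
        return MatchCategory.MISMATCH

    if eff in site_alleles and oth in site_alleles:
        return (
            MatchCategory.EFFECT_SWITCH if eff == site.ref else MatchCategory.DEFAULT_MATCH
        )

    ceff, coth = reverse_complement(eff), reverse_complement(oth)
    if ceff in site_alleles and coth in site_alleles:
        return (
            MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP
            if ceff == site.ref
            else MatchCategory.STRAND_FLIP
        )
    return MatchCategory.MISMATCH


def _effect_index(
    weight: WeightEntry, site: VcfSite, category: MatchCategory, correct_strand_flips: bool
) -> Optional[int]:
    """Index of the dosage-counted allele in (REF,) + ALTs, or None."""
    if category in _LITERAL_SCOREABLE:
        try:
            return site.alleles.index(weight.effect_allele)
        except ValueError:  # indel category with only partial literal match
            return None
    if category in _STRAND_FLIPPED and correct_strand_flips:
        try:
            return site.alleles.index(reverse_complement(weight.effect_allele))
        except ValueError:
            return None
    return None


def combine_vcf_with_pgs(
    genotypes: GenotypeTable, model: PGSModel
) -> tuple[list[MergedVariant], list[WeightEntry]]:
    """Join model entries to VCF sites on chr-prefix-insensitive (chrom, pos).

    Every model entry appears exactly once in the output, in model order;
    entries with no VCF site are categorized ``missing_site`` and also
    returned in the missing report.  VCF sites absent from the model are
    simply not represented.
    """
    merged: list[MergedVariant] = []
    missing: list[WeightEntry] = []
    for weight in model.entries:
        site_idx = genotypes.find_site(weight.chrom, weight.pos)
        if site_idx is None:
            missing.append(weight)
            merged.append(
                MergedVariant(
                    weight=weight,
                    site=None,
                    site_idx=None,
                    category=MatchCategory.MISSING_SITE,
                    effect_allele_index=None,
                )
            )
            continue
        site = genotypes.sites[site_idx]
        category = assess_allele_match(weight, site)
        merged.append(
            MergedVariant(
                weight=weight,
                site=site,
                site_idx=site_idx,
                category=category,
                effect_allele_index=_effect_index(weight, site, category, False),
            )
        )
    return merged, missing


def apply_flip_policy(
    merged: list[MergedVariant],
    max_strand_flips: int = 0,
    remove_ambiguous: bool = False,
    correct_strand_flips: bool = False,
) -> tuple[list[MergedVariant], dict]:
    """Enforce the cohort-level strand QC policy on a merged variant list.

    More than ``max_strand_flips`` strand-flipped variants (including
    effect-switch-with-strand-flip) raises a :class:`PolicyError` advising
    strand verification — a flip count above a handful usually means the
    whole file is on the wrong strand, not that a few variants are.  When
    ``correct_strand_flips`` is set, surviving strand-flipped variants are
    scored against the complemented effect allele; otherwise they are treated
    as unscoreable (like mismatches).  ``remove_ambiguous`` drops palindromic
    ``ambiguous_flip`` variants from scoring; by default they are scored
    as-reported.

    Returns the annotated list plus a report dict of category counts and
    removed variant ids.
    """
    flips = [m for m in merged if m.category in _STRAND_FLIPPED]
    if len(flips) > max_strand_flips:
        raise PolicyError(
            f"{len(flips)} strand-flipped variant(s) exceed max_strand_flips="
            f"{max_strand_flips}; verify the strand convention of the weight file "
            "or raise the threshold / enable correct_strand_flips"
        )

    out: list[MergedVariant] = []
    removed_ids: list[str] = []
    for m in merged:
        if m.category == MatchCategory.AMBIGUOUS_FLIP and remove_ambiguous:
            out.append(replace(m, effect_allele_index=None, removed=True))
            removed_ids.append(m.weight.variant_id)
        elif m.category in _STRAND_FLIPPED and correct_strand_flips:
            idx = _effect_index(m.weight, m.site, m.category, True)
            out.append(replace(m, effect_allele_index=idx))
        else:
            out.append(m)

    counts: dict[str, int] = {}
    for m in out:
        counts[m.category.value] = counts.get(m.category.value, 0) + 1
    report = {
        "category_counts": counts,
        "n_strand_flips": len(flips),
        "removed_ambiguous": removed_ids,
        "n_scoreable": sum(1 for m in out if m.effect_allele_index is not None and not m.removed),
    }
    if report["n_scoreable"] == 0:
        warnings.warn("no scoreable variants remain after applying the flip policy")
    return out, report


def match_report_frame(merged: list[MergedVariant]) -> pd.DataFrame:
    """Per-variant allele-concordance report as a DataFrame."""
    rows = []
    for m in merged:
        rows.append(
            {
                "variant_id": m.weight.variant_id,
                "chrom": m.weight.chrom,
                "pos": m.weight.pos,
                "effect_allele": m.weight.effect_allele,
                "other_allele": m.weight.other_allele or ".",
                "vcf_ref": m.site.ref if m.site else ".",
                "vcf_alt": ",".join(m.site.alts) if m.site else ".",
                "category": m.category.value,
            }
        )
    return pd.DataFrame(rows)


def write_match_report(merged: list[MergedVariant], path) -> None:
    match_report_frame(merged).to_csv(path, sep="\t", index=False)
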