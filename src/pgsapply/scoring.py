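"""Per-sample effect-allele dosages and the weighted-sum polygenic score.

The score for individual *i* over the *M* scoreable model variants is

    PGS_i = sum_m beta_m * dosage_im

where dosage is the number of effect-allele copies carried at the variant:
0–2 for diploid calls, 0–1 for haploid (hemizygous) calls.  No per-allele
normalization is applied; the output is the raw weighted sum.

Missing genotypes are handled two ways, reported side by side:

* ``PGS`` — missing dosages contribute 0 to the sum;
* ``PGS.with.replaced.missing`` (``mean.dosage`` method) — a missing dosage
  is replaced by the variant's mean dosage over non-missing samples.

A half-missing diploid call (``0/.``) contributes its observed allele to the
dosage and counts 0.5 toward the sample's missing-genotype tally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DataError
from .matching import MergedVariant, apply_flip_policy, match_report_frame
from .vcf import GenotypeCall, GenotypeTable

#: canonical output column names
PGS_COL = "PGS"
PGS_REPLACED_COL = "PGS.with.replaced.missing"


def compute_dosage(call: GenotypeCall, effect_allele_index: int) -> float:
    """Count effect-allele copies in a call; NaN for a fully missing call.

    A haploid effect-allele call scores 1 (hemizygous dosage); a partially
    missing diploid call contributes only its observed allele.
    """
    observed = [i for i in call.allele_indices if i is not None]
    if not observed:
        return math.nan
    return float(sum(1 for i in observed if i == effect_allele_index))


def missingness_weight(call: GenotypeCall) -> float:
    """Contribution of a call to the sample's missing-genotype count.

    Fully missing → 1; half-missing diploid → 0.5; complete → 0.
    """
    n_missing = sum(1 for i in call.allele_indices if i is None)
    if n_missing == 0:
        return 0.0
    return n_missing / len(call.allele_indices)


@dataclass
class DosageMatrix:
    """samples × scoreable-variants dosage grid (NaN = fully missing call)."""

    values: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    #: per-entry missingness weights (1 full, 0.5 half-missing diploid)
    missing_weights: np.ndarray
    #: variants whose dosage was missing in every sample (set by mean replacement)
    all_missing_variants: list[str] = field(default_factory=list)


def build_dosage_matrix(
    merged: list[MergedVariant], genotypes: GenotypeTable
) -> DosageMatrix:
    """Dosages for every scoreable merged variant across all samples."""
    scoreable = [
        m for m in merged if m.effect_allele_index is not None and not m.removed
    ]
    if not scoreable:
        raise DataError("no scoreable variants: nothing to compute a PGS from")
    n, m = genotypes.n_samples, len(scoreable)
    values = np.empty((n, m))
    missing = np.zeros((n, m))
    for j, mv in enumerate(scoreable):
        row = genotypes.calls[mv.site_idx]
        for i in range(n):
            call = row[i]
            values[i, j] = compute_dosage(call, mv.effect_allele_index)
            missing[i, j] = missingness_weight(call)
    return DosageMatrix(
        values=values,
        sample_ids=list(genotypes.samples),
        variant_ids=[mv.weight.variant_id for mv in scoreable],
        missing_weights=missing,
    )


def mean_dosage_replace(dosages: DosageMatrix) -> DosageMatrix:
    """Replace missing dosages with each variant's mean non-missing dosage.

    Variants missing in every sample are replaced with 0 and flagged in
    ``all_missing_variants``.  Non-missing entries are untouched.
    """
    values = dosages.values.copy()
    all_missing: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column means
        col_means = np.nanmean(values, axis=0)
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = np.isnan(col)
        if not mask.any():
            continue
        if mask.all():
            col[mask] = 0.0
            all_missing.append(dosages.variant_ids[j])
        else:
            col[mask] = col_means[j]
    return DosageMatrix(
        values=values,
        sample_ids=dosages.sample_ids,
        variant_ids=dosages.variant_ids,
        missing_weights=dosages.missing_weights,
        all_missing_variants=all_missing,
    )


def percentile_rank(scores) -> pd.DataFrame:
    """Fractional ascending percentile rank with max-tie rule, plus coarsenings.

    percentile = rank/n where tied scores all take their group's maximum
    rank, so the top score always sits at percentile 1.0 and an all-equal
    cohort ranks uniformly at 1.0.  decile = ceil(10·percentile),
    quartile = ceil(4·percentile).
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    if len(s) == 0:
        raise ValueError("percentile_rank needs at least one score")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    pct = s.rank(method="max") / len(s)
    return pd.DataFrame(
        {
            "percentile": pct,
            "decile": np.ceil(10 * pct).astype(int),
            "quartile": np.ceil(4 * pct).astype(int),
        }
    )


@dataclass
class ScoreResult:
    """Output bundle of :func:`apply_polygenic_score`."""

    table: pd.DataFrame
    match_report: pd.DataFrame
    flip_report: dict
    dosages: DosageMatrix
    replaced_dosages: Optional[DosageMatrix] = None
    associations: Optional[list] = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def apply_polygenic_score(
    merged: list[MergedVariant],
    genotypes: GenotypeTable,
    missing_method: str = "mean.dosage",
    phenotypes: Optional[pd.DataFrame] = None,
    phenotype_id_col: str = "sample_id",
    max_strand_flips: int = 0,
    remove_ambiguous: bool = False,
    correct_strand_flips: bool = False,
) -> ScoreResult:
    """Compute per-sample polygenic scores from merged, assessed variants.

    The strand-flip policy is applied first (see
    :func:`pgsapply.matching.apply_flip_policy`).  ``missing_method`` is
    ``"none"`` (missing dosages contribute 0) or ``"mean.dosage"`` (adds the
    ``PGS.with.replaced.missing`` column with per-variant mean replacement).
    Percentile, decile and quartile ranks are computed from the ``PGS``
    column relative to the full cohort.  ``percent.missing`` uses the number
    of scoreable variants as denominator, so it reflects genotype absence,
    not model/VCF incompatibility.

    When ``phenotypes`` is given it is left-joined on ``phenotype_id_col``
    and an association is automatically computed between the PGS and each
    phenotype column (see :mod:`pgsapply.association`).
    """
    if missing_method not in ("none", "mean.dosage"):
        raise ValueError(f"unknown missing_method {missing_method!r}")

    annotated, flip_report = apply_flip_policy(
        merged,
        max_strand_flips=max_strand_flips,
        remove_ambiguous=remove_ambiguous,
        correct_strand_flips=correct_strand_flips,
    )
    dosages = build_dosage_matrix(annotated, genotypes)
    betas = np.array(
        [
            mv.weight.beta
            for mv in annotated
            if mv.effect_allele_index is not None and not mv.removed
        ]
    )

    pgs = np.nansum(dosages.values * betas, axis=1)
    n_missing = dosages.missing_weights.sum(axis=1)
    n_scoreable = dosages.values.shape[1]

    table = pd.DataFrame(
        {
            "sample_id": dosages.sample_ids,
            PGS_COL: pgs,
            "n.missing.genotypes": n_missing,
            "percent.missing": 100.0 * n_missing / n_scoreable,
        }
    )

    replaced = None
    if missing_method == "mean.dosage":
        replaced = mean_dosage_replace(dosages)
        table.insert(2, PGS_REPLACED_COL, (replaced.values * betas).sum(axis=1))

    table = pd.concat([table, percentile_rank(pgs)], axis=1)

    associations = None
    if phenotypes is not None:
        table, associations = _join_phenotypes(table, phenotypes, phenotype_id_col)

    return ScoreResult(
        table=table,
        match_report=match_report_frame(annotated),
        flip_report=flip_report,
        dosages=dosages,
        replaced_dosages=replaced,
        associations=associations,
    )


def _join_phenotypes(
    table: pd.DataFrame, phenotypes: pd.DataFrame, id_col: str
) -> tuple[pd.DataFrame, list]:
    from . import association as assoc

    if id_col not in phenotypes.columns:
        raise DataError(f"phenotype table has no {id_col!r} column")
    pheno = phenotypes.rename(columns={id_col: "sample_id"})
    unmatched = set(pheno["sample_id"]) - set(table["sample_id"])
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} phenotype sample id(s) match no genotype sample: "
            f"{sorted(unmatched)[:5]}..."
        )
    joined = table.merge(pheno, on="sample_id", how="left")
    results = []
    for col in pheno.columns:
        if col == "sample_id":
            continue
        try:
            results.append(assoc.auto_associate(joined[PGS_COL], joined[col], name=col))
        except (DataError, ValueError) as exc:
            warnings.warn(f"association with phenotype {col!r} skipped: {exc}")
    return joined, results
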