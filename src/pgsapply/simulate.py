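"""Deterministic synthetic cohorts: VCF + weight file + phenotypes + truth.

The generator plants the exact edge cases the scorer and matcher must
handle — effect-switch variants (effect allele written as REF), palindromic
A/T / C/G pairs, merged multiallelic records with the effect allele as the
second ALT, strand-flipped weight entries (model alleles complemented
relative to the VCF), haploid calls on chromosome X, and randomly masked
genotypes — and records the ground truth for every one of them.

Genotypes are drawn under Hardy–Weinberg equilibrium with independent
variants (no linkage disequilibrium): the additive scoring model assumes
independence, so LD structure adds nothing to testing it.  The continuous
phenotype is built from the standardized true score so that the score
explains a chosen fraction ``h2`` of phenotype variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: non-palindromic single-base pairs (ref, alt)
_NONPAL_PAIRS = [
    (a, b) for a in _BASES for b in _BASES if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_samples: int = 100
    m_variants: int = 50
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.3
    fraction_effect_switch: float = 0.3
    fraction_palindromic: float = 0.1
    fraction_multiallelic: float = 0.05
    fraction_haploid: float = 0.05
    fraction_strand_flip: float = 0.0
    missing_rate: float = 0.0
    binary_prevalence: Optional[float] = 0.3

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.m_variants < 1:
            raise ConfigError("m_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.h2 <= 1:
            raise ConfigError("h2 must be in [0, 1]")
        fractions = {
            "fraction_effect_switch": self.fraction_effect_switch,
            "fraction_palindromic": self.fraction_palindromic,
            "fraction_multiallelic": self.fraction_multiallelic,
            "fraction_haploid": self.fraction_haploid,
            "fraction_strand_flip": self.fraction_strand_flip,
            "missing_rate": self.missing_rate,
        }
        for name, value in fractions.items():
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        structural = (
            self.fraction_effect_switch
            + self.fraction_palindromic
            + self.fraction_multiallelic
            + self.fraction_haploid
            + self.fraction_strand_flip
        )
        if structural > 1:
            raise ConfigError(
                f"structural fractions sum to {structural:.3f} > 1; no variants left"
            )
        if self.binary_prevalence is not None and not 0 < self.binary_prevalence < 1:
            raise ConfigError("binary_prevalence must be in (0, 1)")


@dataclass
class SimulatedCohort:
    """In-memory truth plus (optionally) the paths of the written files."""

    config: SimConfig
    sample_ids: list[str]
    variants: pd.DataFrame  # one row per variant, incl. planted class & beta
    true_dosages: np.ndarray  # samples x variants, pre-masking effect-allele counts
    observed_missing: np.ndarray  # bool mask of genotypes written as missing
    true_pgs: np.ndarray
    phenotypes: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _plant_classes(rng: np.random.Generator, cfg: SimConfig) -> list[str]:
    counts = {
        "effect_switch": int(round(cfg.fraction_effect_switch * cfg.m_variants)),
        "palindromic": int(round(cfg.fraction_palindromic * cfg.m_variants)),
        "multiallelic": int(round(cfg.fraction_multiallelic * cfg.m_variants)),
        "haploid": int(round(cfg.fraction_haploid * cfg.m_variants)),
        "strand_flip": int(round(cfg.fraction_strand_flip * cfg.m_variants)),
    }
    if sum(counts.values()) > cfg.m_variants:
        raise ConfigError("rounded structural counts exceed m_variants")
    classes = ["default"] * cfg.m_variants
    pool = list(rng.permutation(cfg.m_variants))
    for name, k in counts.items():
        for _ in range(k):
            classes[pool.pop()] = name
    return classes


_EXPECTED_CATEGORY = {
    "default": "default_match",
    "effect_switch": "effect_switch",
    "palindromic": "ambiguous_flip",
    "multiallelic": "default_match",
    "haploid": "default_match",
    "strand_flip": "strand_flip",
}


def simulate_cohort(config: SimConfig, prefix=None) -> SimulatedCohort:
    """Generate one cohort; write ``PREFIX.vcf``/``.pgs.txt``/``.pheno.tsv``/
    truth tables when ``prefix`` is given.

    Identical configs produce byte-identical output files.  The truth tables
    carry the planted class, the expected allele-match category, the true
    (pre-masking) dosages and the generator's own weighted-sum score, so
    downstream results can be checked exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.m_variants
    sample_ids = [f"sample_{i + 1:04d}" for i in range(n)]
    classes = _plant_classes(rng, cfg)

    rows = []
    true_dosages = np.zeros((n, m))
    gt_matrix: list[list[str]] = []  # per variant, per sample GT string
    pos_auto, pos_x = 10_000, 10_000

    for j, cls in enumerate(classes):
        freq = float(rng.uniform(*cfg.maf_range))
        beta = float(rng.standard_normal())

        if cls == "multiallelic":
            # ref + two single-base ALTs; effect allele is the second ALT
            ref, alt1 = _NONPAL_PAIRS[rng.integers(len(_NONPAL_PAIRS))]
            alt2 = next(
                b
                for b in rng.permutation(_BASES)
                if b not in (ref, alt1) and {b, ref} not in ({"A", "T"}, {"C", "G"})
            )
            alts = (alt1, alt2)
            effect, other = alt2, ref
            f1 = float(rng.uniform(0.02, 0.10))  # minor first ALT
            probs = np.array([1 - f1 - freq, f1, freq])
            draws = rng.choice(3, size=(n, 2), p=probs / probs.sum())
            dosage = (draws == 2).sum(axis=1).astype(float)
            gts = ["/".join(str(a) for a in sorted(d)) for d in draws]
        elif cls == "palindromic":
            ref, alt = _PAL_PAIRS[rng.integers(len(_PAL_PAIRS))]
            alts = (alt,)
            effect, other = alt, ref
            alt_counts = rng.binomial(2, freq, size=n)
            dosage = alt_counts.astype(float)
            gts = [("0/0", "0/1", "1/1")[c] for c in alt_counts]
        elif cls == "haploid":
            ref, alt = _NONPAL_PAIRS[rng.integers(len(_NONPAL_PAIRS))]
            alts = (alt,)
            effect, other = alt, ref
            hap = rng.binomial(1, freq, size=n)
            dosage = hap.astype(float)
            gts = [str(c) for c in hap]
        else:
            ref, alt = _NONPAL_PAIRS[rng.integers(len(_NONPAL_PAIRS))]
            alts = (alt,)
            alt_counts = rng.binomial(2, freq, size=n)
            gts = [("0/0", "0/1", "1/1")[c] for c in alt_counts]
            if cls == "effect_switch":
                effect, other = ref, alt
                dosage = (2 - alt_counts).astype(float)
            elif cls == "strand_flip":
                # weight file reports the opposite strand; intended dosage
                # still counts copies of the VCF ALT
                effect, other = _COMP[alt], _COMP[ref]
                dosage = alt_counts.astype(float)
            else:
                effect, other = alt, ref
                dosage = alt_counts.astype(float)

        chrom = "X" if cls == "haploid" else "1"
        if cls == "haploid":
            pos_x += 10
            pos = pos_x
        else:
            pos_auto += 10
            pos = pos_auto

        true_dosages[:, j] = dosage
        gt_matrix.append(gts)
        rows.append(
            {
                "variant_id": f"sim{j + 1}",
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alts": ",".join(alts),
                "effect_allele": effect,
                "other_allele": other,
                "beta": beta,
                "effect_freq": freq,
                "planted": cls,
                "expected_category": _EXPECTED_CATEGORY[cls],
            }
        )

    variants = pd.DataFrame(rows)
    missing_mask = rng.random((n, m)) < cfg.missing_rate

    true_pgs = true_dosages @ variants["beta"].to_numpy()

    # phenotype: sqrt(h2) * standardized true score + sqrt(1-h2) * noise
    noise = rng.standard_normal(n)
    sd = true_pgs.std(ddof=0)
    z = (true_pgs - true_pgs.mean()) / sd if sd > 0 else np.zeros(n)
    pheno = np.sqrt(cfg.h2) * z + np.sqrt(1 - cfg.h2) * noise

    pheno_df = pd.DataFrame({"sample_id": sample_ids, "pheno_continuous": pheno})
    if cfg.binary_prevalence is not None:
        threshold = float(np.quantile(pheno, 1 - cfg.binary_prevalence))
        pheno_df["pheno_binary"] = (pheno >= threshold).astype(int)
    pheno_df["group"] = rng.choice(["groupA", "groupB", "groupC"], size=n)

    cohort = SimulatedCohort(
        config=cfg,
        sample_ids=sample_ids,
        variants=variants,
        true_dosages=true_dosages,
        observed_missing=missing_mask,
        true_pgs=true_pgs,
        phenotypes=pheno_df,
    )
    if prefix is not None:
        _write_cohort(cohort, gt_matrix, Path(prefix))
    else:
        cohort.paths = {}
        cohort._gt_matrix = gt_matrix  # kept for deferred writing in tests
    return cohort


def write_cohort(cohort: SimulatedCohort, prefix) -> dict:
    """Write a cohort generated without a prefix; returns the path dict."""
    _write_cohort(cohort, cohort._gt_matrix, Path(prefix))
    return cohort.paths


def _write_cohort(cohort: SimulatedCohort, gt_matrix, prefix: Path) -> None:
    cfg = cohort.config
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = Path(str(prefix) + ".vcf")
    pgs_path = Path(str(prefix) + ".pgs.txt")
    pheno_path = Path(str(prefix) + ".pheno.tsv")
    truth_path = Path(str(prefix) + ".truth.tsv")
    truth_variants_path = Path(str(prefix) + ".truth_variants.tsv")

    variants = cohort.variants
    n = cfg.n_samples

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=pgsapply-simulate seed={cfg.seed}\n")
        fh.write("##contig=<ID=1>\n##contig=<ID=X>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(cohort.sample_ids) + "\n")
        order = sorted(
            range(len(variants)),
            key=lambda j: (variants.at[j, "chrom"] != "1", variants.at[j, "pos"]),
        )
        for j in order:
            row = variants.iloc[j]
            gts = list(gt_matrix[j])
            for i in range(n):
                if cohort.observed_missing[i, j]:
                    gts[i] = "." if row["chrom"] == "X" else "./."
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alts']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )

    with open(pgs_path, "w") as fh:
        fh.write(f"#pgs_id=PGSSIM{cfg.seed}\n")
        fh.write("#genome_build=GRCh38\n#HmPOS_build=GRCh38\n")
        fh.write(f"#source=pgsapply-simulate seed={cfg.seed}\n")
        fh.write(
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\t"
            "effect_weight\thm_chr\thm_pos\n"
        )
        for row in variants.itertuples(index=False):
            fh.write(
                f"{row.variant_id}\t{row.chrom}\t{row.pos}\t{row.effect_allele}\t"
                f"{row.other_allele}\t{row.beta:.17g}\t{row.chrom}\t{row.pos}\n"
            )

    cohort.phenotypes.to_csv(pheno_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": cohort.sample_ids, "true_pgs": cohort.true_pgs}
    ).to_csv(truth_path, sep="\t", index=False, float_format="%.12g")
    variants.to_csv(truth_variants_path, sep="\t", index=False, float_format="%.12g")

    cohort.paths = {
        "vcf": str(vcf_path),
        "weights": str(pgs_path),
        "phenotypes": str(pheno_path),
        "truth": str(truth_path),
        "truth_variants": str(truth_variants_path),
    }


def simulate_null_labels(n: int, prevalence: float, seed: int) -> np.ndarray:
    """Bernoulli labels independent of any score; reproducible by seed."""
    if not 0 < prevalence < 1:
        raise ConfigError("prevalence must be in (0, 1)")
    return np.random.default_rng(seed).binomial(1, prevalence, size=n)
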