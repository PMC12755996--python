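# Methods

## Scoring model

The package implements the standard additive model of polygenic risk: the
score of individual *i* is `PGS_i = Σ_m β_m · dosage_im` over the model's
scoreable variants, where `dosage_im` counts the copies of variant *m*'s
effect allele carried by *i*. The model assumes each variant's effect is
independent of all others and that effects combine linearly; no dominance,
epistasis or copy-number adjustment is modelled, and no per-allele
normalization (score averaging) is applied — the output is the raw weighted
sum.

Dosage is allele-count based and ploidy-aware:

- diploid calls contribute 0, 1 or 2;
- haploid calls (taken verbatim from the VCF GT field, e.g. male X/Y)
  contribute 0 or 1 — a hemizygous effect-allele call scores exactly 1;
- a partially missing diploid call (`0/.`) contributes its one observed
  allele and counts 0.5 toward the sample's missing-genotype tally. This
  preserves the observed information without inventing an allele; the
  alternative (treating the call as fully missing) discards a known allele.
- a fully missing call contributes 0 to the plain `PGS` column.

No pseudoautosomal-region logic is applied: genotypes are interpreted
exactly as formatted in the input VCF, and mixed diploid/haploid encodings
on the sex chromosomes are the caller's responsibility.

## Allele matching

Weights attach to alleles by base string, never by REF/ALT label. For each
model variant joined to a VCF site (on chromosome-prefix-insensitive
chromosome + position), the concordance category is decided in this order:

1. any allele longer than one base on either side → `indel`, matched by
   literal string comparison only (indels are never complemented: without
   left/right normalization the complemented representation is ambiguous);
   a failed literal match is a `mismatch`;
2. palindromic model pair (A/T or C/G) present at the site →
   `ambiguous_flip`: apparent orientation cannot distinguish a strand flip
   from an effect-direction flip;
3. both model alleles found as reported → `effect_switch` when the effect
   allele is the REF, else `default_match`;
4. both model alleles found only after complementing → `strand_flip` when
   the complemented effect allele is an ALT, `effect_switch_with_strand_flip`
   when it is the REF. This convention keeps two symmetries exact:
   swapping effect/other alleles exchanges `default_match ↔ effect_switch`
   and `strand_flip ↔ effect_switch_with_strand_flip`, and complementing
   both model alleles exchanges `default_match ↔ strand_flip`;
5. otherwise `mismatch`. Model variants with no VCF site are
   `missing_site`.

When the model omits the other allele, only the effect allele is checked
and strand-flip detection is disabled for that variant (it can only be
`default_match`, `effect_switch` or `mismatch`) — a conservative choice,
since one allele cannot witness a flip.

### Flip policy

The cohort-level QC policy has three dials, applied before scoring:

- `max_strand_flips` (default 0): more detected strand flips than this is a
  hard error. A nonzero flip count in an otherwise concordant file usually
  indicates the entire weight file is on the wrong strand; silently
  correcting would mask that.
- `correct_strand_flips` (default off): when on, surviving strand-flipped
  variants are scored against the complemented effect allele; when off they
  are excluded from scoring.
- `remove_ambiguous` (default off): palindromic variants are scored
  as-reported by default, which is appropriate once a cohort-level check
  has shown no flips among non-palindromic variants; removing them is the
  conservative alternative.

`effect_switch` is never "corrected" — it needs no correction, because the
dosage already counts the right base.

## Missing data

Two columns are reported side by side. `PGS` lets missing dosages
contribute 0. Under the `mean.dosage` method, `PGS.with.replaced.missing`
replaces each missing dosage with the variant's arithmetic-mean dosage over
non-missing samples (variants missing in every sample are replaced with 0
and flagged). Replacement is mean-preserving per variant, and samples with
no missing genotypes have identical values in both columns.
`percent.missing` uses the number of *scoreable* variants as its
denominator, so it measures genotype absence rather than model/VCF
incompatibility; `mismatch`, `missing_site` and removed-ambiguous variants
count toward neither numerator nor denominator. Half-missing diploid calls
count 0.5.

## Percentiles

Percentile rank is the fractional ascending rank `r/n` with tied scores
sharing their group's **maximum** rank, so the top score always has
percentile 1.0 and an all-equal cohort ranks uniformly at 1.0 (a documented
dialect choice; the common alternative, mean ranks, breaks that anchor).
Deciles and quartiles are `ceil(10·p)` and `ceil(4·p)` — coarsenings of the
percentile. Ranks are computed from the unadjusted `PGS` column.

## Association

All tests are two-sided at α = 0.05, with significance stars at .05 / .01 /
.001.

- Continuous phenotype: ordinary least squares of phenotype on PGS,
  complete-case, with the slope's two-sided p-value and R² (equal to
  squared Pearson correlation in this univariable fit).
- Binary phenotype: logistic regression fitted by iteratively reweighted
  least squares (tolerance 1e-8, at most 25 iterations; statsmodels GLM
  under the hood). Non-convergence and perfect separation are flagged,
  never silently accepted. The ROC is computed from the PGS ranking itself
  when no covariates are given — this makes the reported AUC identical to
  the Mann–Whitney probability U/(n₁·n₀) that a random case outranks a
  random control, including when the score anti-predicts — and from the
  fitted linear predictor when covariates are included. AUC is the
  trapezoidal area under the curve. Continuous phenotypes can be
  dichotomized at a threshold (label positive when value ≥ threshold;
  missing stays missing).
- Categorical phenotype: Wilcoxon rank-sum for two groups; Kruskal–Wallis
  omnibus plus all pairwise rank-sum tests for more, each raw p multiplied
  by the number of pairs (Bonferroni) and capped at 1. Rank-sum p-values
  use exact enumeration for small untied samples and the tie-corrected
  normal approximation otherwise (scipy's automatic rule). Groups with
  fewer than two observations are skipped pair-wise with a warning.
- The automatic association run after a phenotype join dispatches on
  shape: exactly two distinct non-missing values → logistic/ROC; other
  numeric → linear; non-numeric → group comparison. The automatic fit is
  strictly univariable; covariates enter only on explicit request.

## Visualization

Five plot functions (density, grouped boxplot with significance stars, PGS
vs continuous phenotype scatter/hexbin, percentile-rank strip with
covariate bars, ROC) each write an image and return the numeric summary
they drew, so correctness is asserted on numbers, never pixels. Kernel
densities use a Gaussian kernel with Silverman's-rule bandwidth on a
512-point grid spanning the data range ± 3 bandwidths; box whiskers extend
to the most extreme points within 1.5·IQR. The functions accept any
DataFrame with the documented columns, not only this package's scorer
output.

## Synthetic cohorts

The simulator emulates exactly the structure the matcher and scorer must
handle, with deterministic, seed-reproducible output (identical
configurations give byte-identical files; the seed is embedded in every
file header):

- independent variants under Hardy–Weinberg equilibrium, allele
  frequencies uniform on a configurable range (default 0.05–0.5);
- per-variant weights drawn standard normal;
- planted fractions of effect-switch (effect allele written as REF,
  default 30%), palindromic pairs (10%), merged multiallelic records with
  the effect allele as second ALT (5%), haploid chromosome-X variants
  (5%), strand-flipped weight entries (0% by default) and
  missing-masked genotypes (0% by default);
- a continuous phenotype `√h²·z + √(1−h²)·ε` built from the standardized
  true score z, so the true score explains a chosen variance fraction h²
  (default 0.3); an optional binary phenotype thresholded at the quantile
  matching a target prevalence; and a random three-level categorical
  column for grouped analyses.

Truth tables record every planted class, the expected match category, the
pre-masking dosages and the generator's own weighted sum, enabling exact
(≤1e-12) end-to-end checks when nothing is masked.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: linkage disequilibrium, population
structure and ancestry gradients, realistic site-frequency spectra,
genotyping/imputation error, and weight files with coordinate or build
inconsistencies. The generator validates the scorer's arithmetic and the
matcher's logic, not the epidemiological behaviour of real polygenic
scores.

## Numerical and design choices

- Coordinates: weight files and VCF are 1-based; BED output is 0-based
  half-open; slop-expanded intervals clamp at 0. Indels emit the single
  base at POS (region filters match VCF records by POS).
- Chromosome names: model/VCF joining and BED region filtering ignore a
  `chr` prefix; BED output can force either style. BED intervals sort
  numerically for 1–22, then X, Y, MT.
- Duplicate (chrom, pos) VCF records are an error, not a warning — split
  multiallelics corrupt dosages, and silent acceptance is the one failure
  mode that produces plausible-looking wrong scores.
- Weight-file rows that cannot be used (missing coordinate or effect
  allele, non-numeric or non-finite weight, non-ACGT allele codes such as
  structured HLA alleles, exact duplicates) are rejected row-by-row with
  reasons, never guessed at; parsing continues.
- Scoring uses dense sample × variant dosage matrices; time and memory
  scale linearly in that product.
- Acceptance problem sizes: oracle comparisons run on 25 cohorts up to
  50 × 200, label-invariance on 10 cohorts up to 40 × 60, heritability
  recovery on ten 2000-sample cohorts of 40 variants — sizes at which all
  statistical bands are comfortably tight while a full run stays fast on a
  single CPU.

## Known limitations

- No genotype-probability (DS/GP) dosages; only GT is consumed.
- No liftover, rsID validation, allele-frequency-based resolution of
  palindromic ambiguity, or reference-panel calibration of scores.
- The FILTER column is ignored; pre-filter with standard tools.
- PAR-aware and sex-aware dosage interpretation is out of scope; haploid
  and diploid calls are scored exactly as encoded.
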