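"""Statistical association of polygenic scores with phenotypes.

Three entry points, matching the three phenotype shapes:

* continuous → :func:`linear_association`, ordinary least squares of the
  phenotype on the PGS;
* binary → :func:`analyze_binary_predictiveness`, logistic regression
  (optionally covariate-adjusted) plus an ROC curve and its AUC;
* categorical → :func:`compare_groups`, rank-based tests (Wilcoxon rank-sum
  for two groups, Kruskal–Wallis omnibus plus Bonferroni-adjusted pairwise
  rank-sum tests for more).

All tests are two-sided; the conventional star thresholds are
p < .05 (*), p < .01 (**) and p < .001 (***).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .exceptions import DataError


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class LinearAssociation:
    """Univariable OLS fit of a continuous phenotype on the PGS."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int
    n_dropped: int = 0
    phenotype: str = ""

    def summary(self) -> str:
        return (
            f"linear association [{self.phenotype}]: slope={self.slope:.4g} "
            f"intercept={self.intercept:.4g} p={self.p_value:.3g} "
            f"R2={self.r_squared:.4f} n={self.n}"
        )


@dataclass
class RocResult:
    """Logistic-regression predictiveness of a binary phenotype, with ROC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR, ordered along the curve
    specificity: np.ndarray  # 1 - FPR
    auc: float
    coefficients: pd.DataFrame  # term, estimate, p_value
    n_cases: int
    n_controls: int
    converged: bool = True
    separation_flag: bool = False
    phenotype: str = ""

    def summary(self) -> str:
        flags = "" if self.converged else " (non-converged)"
        flags += " (perfect separation)" if self.separation_flag else ""
        return (
            f"binary predictiveness [{self.phenotype}]: AUC={self.auc:.4f} "
            f"cases={self.n_cases} controls={self.n_controls}{flags}"
        )


@dataclass
class GroupComparison:
    """Rank-based comparison of a value across phenotype groups."""

    groups: list
    group_sizes: dict
    omnibus_p: Optional[float]  # Kruskal–Wallis, only when >2 groups
    pairs: pd.DataFrame  # group1, group2, raw_p, adjusted_p, stars
    n_pairs: int
    skipped_pairs: list = field(default_factory=list)
    phenotype: str = ""

    def summary(self) -> str:
        om = f" omnibus_p={self.omnibus_p:.3g}" if self.omnibus_p is not None else ""
        return (
            f"group comparison [{self.phenotype}]: {len(self.groups)} groups,"
            f"{om} {self.n_pairs} pairwise test(s)"
        )


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep], int((~keep).sum())


def linear_association(pgs, phenotype, name: str = "") -> LinearAssociation:
    """OLS of phenotype on PGS; two-sided slope p-value; complete-case."""
    x, y, dropped = _complete_pairs(pgs, phenotype)
    if len(x) < 3:
        raise DataError(f"linear association needs >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise DataError("degenerate fit: PGS has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearAssociation(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n=len(x),
        n_dropped=dropped,
        phenotype=name,
    )


def dichotomize(phenotype, threshold: float) -> np.ndarray:
    """Binary labels: 1 where value >= threshold, 0 below, NaN stays NaN."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = np.asarray(phenotype, dtype=float)
    labels = np.where(values >= threshold, 1.0, 0.0)
    labels[~np.isfinite(values)] = np.nan
    return labels


def _rank_auc(score: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann–Whitney probability that a case outranks a control."""
    cases = score[labels == 1]
    controls = score[labels == 0]
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u1 = ranks[: len(cases)].sum() - len(cases) * (len(cases) + 1) / 2
    return float(u1 / (len(cases) * len(controls)))


def analyze_binary_predictiveness(
    pgs,
    labels,
    covariates: Optional[pd.DataFrame] = None,
    name: str = "",
) -> RocResult:
    """Logistic regression of binary labels on the PGS, with ROC/AUC.

    With covariates the ROC is computed from the fitted linear predictor of
    the covariate-adjusted model; without covariates it is computed directly
    from the PGS ranking (identical to the fitted model's ROC whenever the
    PGS coefficient is positive, and equal to the Mann–Whitney U-statistic
    AUC in general).  The logistic model is fitted by iteratively reweighted
    least squares (tolerance 1e-8, at most 25 iterations); non-convergence
    and perfect separation are flagged, never silently accepted — AUC is
    still computed from the score ranking.
    """
    pgs = np.asarray(pgs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    X = pd.DataFrame({"PGS": pgs})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    keep = np.isfinite(labels) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    X, y = X.loc[keep].reset_index(drop=True), labels[keep]
    if len(y) < 10:
        warnings.warn(
            f"binary predictiveness fitted on only {len(y)} complete-case rows; "
            "estimates will be unstable"
        )
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("labels contain a single class; cannot fit a case/control model")

    Xc = sm.add_constant(X.astype(float))
    converged, separation = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(
                maxiter=25, tol=1e-8
            )
            converged = bool(fit.converged)
            params = fit.params
            pvalues = fit.pvalues
            lp = np.asarray(fit.predict(Xc, which="linear"))
            separation = bool(np.abs(params).max() > 1e3)
        except Exception:
            converged = False
            separation = True
            params = pd.Series(np.nan, index=Xc.columns)
            pvalues = pd.Series(np.nan, index=Xc.columns)
            lp = pgs[keep]

    score = lp if covariates is not None and converged else pgs[keep]
    fpr, tpr, thresholds = roc_curve(y, score)
    auc = _rank_auc(score, y)

    coef = pd.DataFrame(
        {
            "term": list(Xc.columns),
            "estimate": np.asarray(params, dtype=float),
            "p_value": np.asarray(pvalues, dtype=float),
        }
    )
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1 - fpr,
        auc=auc,
        coefficients=coef,
        n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
        converged=converged,
        separation_flag=separation,
        phenotype=name,
    )


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small untied samples,
    normal approximation with tie correction otherwise (scipy's auto rule)."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def compare_groups(values, group_labels, name: str = "") -> GroupComparison:
    """Rank-based group comparison with Bonferroni-adjusted pairwise tests.

    Two groups: a single Wilcoxon rank-sum test.  More than two: a
    Kruskal–Wallis omnibus test plus all pairwise rank-sum tests, each raw p
    multiplied by the number of pairs tested and capped at 1.  Groups with
    fewer than 2 observations are excluded pair-wise with a warning.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels, dtype=object)
    keep = np.isfinite(values) & pd.notna(group_labels)
    values, group_labels = values[keep], group_labels[keep]

    groups = sorted(set(group_labels), key=str)
    if len(groups) < 2:
        raise DataError("compare_groups needs at least 2 non-empty groups")
    data = {g: values[group_labels == g] for g in groups}
    sizes = {g: len(data[g]) for g in groups}

    testable = [g for g in groups if sizes[g] >= 2]
    skipped = []
    for g in groups:
        if sizes[g] < 2:
            warnings.warn(f"group {g!r} has fewer than 2 observations; its pairs are skipped")
    pair_list = list(itertools.combinations(testable, 2))
    for pair in itertools.combinations(groups, 2):
        if pair not in pair_list:
            skipped.append(pair)
    n_pairs = len(pair_list)

    rows = []
    for g1, g2 in pair_list:
        raw = _rank_sum_p(data[g1], data[g2])
        adj = min(1.0, raw * n_pairs)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "raw_p": raw,
                "adjusted_p": adj,
                "stars": significance_stars(adj),
            }
        )
    pairs = pd.DataFrame(rows, columns=["group1", "group2", "raw_p", "adjusted_p", "stars"])

    omnibus = None
    if len(testable) > 2:
        omnibus = float(stats.kruskal(*[data[g] for g in testable]).pvalue)

    return GroupComparison(
        groups=groups,
        group_sizes=sizes,
        omnibus_p=omnibus,
        pairs=pairs,
        n_pairs=n_pairs,
        skipped_pairs=skipped,
        phenotype=name,
    )


def bonferroni(p: float, n_tests: int) -> float:
    """min(1, p * n_tests)."""
    return min(1.0, p * n_tests)


def auto_associate(pgs, phenotype, name: str = ""):
    """Dispatch on phenotype shape: 2 distinct values → logistic/ROC,
    other numeric → linear, non-numeric → group comparison."""
    pheno = pd.Series(phenotype)
    non_missing = pheno.dropna()
    distinct = non_missing.unique()
    if len(distinct) == 2:
        codes = pd.Categorical(pheno).codes.astype(float)
        codes[codes < 0] = np.nan
        return analyze_binary_predictiveness(pgs, codes, name=name)
    if pd.api.types.is_numeric_dtype(non_missing):
        return linear_association(pgs, pheno.astype(float), name=name)
    return compare_groups(pgs, pheno.to_numpy(), name=name)


def association_report_frame(results: list) -> pd.DataFrame:
    """Flatten association results into the report TSV schema."""
    rows = []
    for res in results:
        if isinstance(res, LinearAssociation):
            rows.append(
                {
                    "phenotype": res.phenotype,
                    "model": "linear",
                    "term": "PGS",
                    "estimate": res.slope,
                    "p_value": res.p_value,
                    "statistic": res.r_squared,
                    "statistic_name": "r_squared",
                    "n": res.n,
                }
            )
        elif isinstance(res, RocResult):
            for _, row in res.coefficients.iterrows():
                rows.append(
                    {
                        "phenotype": res.phenotype,
                        "model": "logistic",
                        "term": row["term"],
                        "estimate": row["estimate"],
                        "p_value": row["p_value"],
                        "statistic": res.auc,
                        "statistic_name": "auc",
                        "n": res.n_cases + res.n_controls,
                    }
                )
        elif isinstance(res, GroupComparison):
            for _, row in res.pairs.iterrows():
                rows.append(
                    {
                        "phenotype": res.phenotype,
                        "model": "rank_sum",
                        "term": f"{row['group1']} vs {row['group2']}",
                        "estimate": np.nan,
                        "p_value": row["adjusted_p"],
                        "statistic": row["raw_p"],
                        "statistic_name": "raw_p",
                        "n": sum(res.group_sizes.values()),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype",
            "model",
            "term",
            "estimate",
            "p_value",
            "statistic",
            "statistic_name",
            "n",
        ],
    )
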