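"""Standard visual summaries of score + phenotype tables.

Five plots: density curves, grouped boxplots with significance stars, PGS vs
continuous phenotype scatter/hexbin, percentile-rank strips with covariate
bars, and ROC curves.  Every function writes an image file AND returns the
numeric summary it drew from, so tests (and downstream reporting) assert on
numbers, never on pixels.  The functions accept any DataFrame carrying the
documented columns — they are not coupled to this package's scorer output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, pearsonr

from . import association as assoc
from .exceptions import DataError

_KDE_GRID_POINTS = 512
_KDE_GRID_PAD_BW = 3.0  # grid spans data range ± this many bandwidths


@dataclass
class PlotSpec:
    """Declarative description of one plot."""

    kind: str = "density"  # density | boxplot | scatter_continuous | rank | roc
    output_path: str = "plot.png"
    group_col: Optional[str] = None
    score_col: str = "PGS"
    image_format: str = "png"
    width: float = 7.0
    height: float = 5.0
    hexbin: bool = False
    covariate_cols: Sequence[str] = field(default_factory=list)


def _require_column(df: pd.DataFrame, col: str) -> None:
    if col not in df.columns:
        raise DataError(f"column {col!r} not found in the score table")


def _save(fig, spec: PlotSpec) -> str:
    fig.savefig(spec.output_path, format=spec.image_format, dpi=100)
    plt.close(fig)
    return str(spec.output_path)


def _silverman_kde(values: np.ndarray):
    kde = gaussian_kde(values, bw_method="silverman")
    bandwidth = float(kde.factor * values.std(ddof=1))
    return kde, bandwidth


def plot_pgs_density(scores: pd.DataFrame, spec: PlotSpec) -> tuple[str, dict]:
    """Kernel-density curves of the PGS, cohort-wide and optionally by group.

    Gaussian kernel with Silverman's-rule bandwidth on a shared 512-point
    grid spanning the data range ± 3 bandwidths; the grid and every curve
    are returned in the summary.
    """
    _require_column(scores, spec.score_col)
    values = scores[spec.score_col].dropna().to_numpy(dtype=float)
    if len(values) < 2:
        raise DataError("density plot needs at least 2 samples")

    kde, bandwidth = _silverman_kde(values)
    grid = np.linspace(
        values.min() - _KDE_GRID_PAD_BW * bandwidth,
        values.max() + _KDE_GRID_PAD_BW * bandwidth,
        _KDE_GRID_POINTS,
    )
    curves: dict[str, np.ndarray] = {"cohort": kde(grid)}

    if spec.group_col is not None:
        _require_column(scores, spec.group_col)
        for group, sub in scores.groupby(spec.group_col, observed=True):
            sub_values = sub[spec.score_col].dropna().to_numpy(dtype=float)
            if len(sub_values) < 2:
                continue
            gkde, _ = _silverman_kde(sub_values)
            curves[str(group)] = gkde(grid)

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    for label, density in curves.items():
        ax.plot(grid, density, label=label, lw=2 if label == "cohort" else 1.2)
    ax.set_xlabel(spec.score_col)
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    path = _save(fig, spec)
    return path, {"grid": grid, "curves": curves, "bandwidth": bandwidth}


def plot_pgs_boxplot(
    scores: pd.DataFrame, spec: PlotSpec, annotate_significance: bool = False
) -> tuple[str, dict]:
    """Grouped boxplots (median, quartiles, 1.5·IQR whiskers), optionally with
    significance stars from Bonferroni-adjusted pairwise rank-sum tests."""
    if spec.group_col is None:
        raise DataError("boxplot needs a grouping column")
    _require_column(scores, spec.score_col)
    _require_column(scores, spec.group_col)

    stats_rows = {}
    groups, data = [], []
    for group, sub in scores.groupby(spec.group_col, observed=True):
        vals = sub[spec.score_col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        stats_rows[str(group)] = {
            "median": med,
            "q1": q1,
            "q3": q3,
            "whisker_low": lo,
            "whisker_high": hi,
            "n": len(vals),
        }
        groups.append(str(group))
        data.append(vals)

    comparison = None
    if annotate_significance and len(groups) >= 2:
        comparison = assoc.compare_groups(
            scores[spec.score_col].to_numpy(dtype=float),
            scores[spec.group_col].astype(str).to_numpy(),
            name=spec.group_col,
        )

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    ax.boxplot(data, tick_labels=groups, whis=1.5)
    ax.set_xlabel(spec.group_col)
    ax.set_ylabel(spec.score_col)
    if comparison is not None:
        top = max(r["whisker_high"] for r in stats_rows.values())
        step = 0.06 * (top - min(r["whisker_low"] for r in stats_rows.values()) or 1.0)
        pos = {g: i + 1 for i, g in enumerate(groups)}
        level = 0
        for _, row in comparison.pairs.iterrows():
            if not row["stars"]:
                continue
            level += 1
            y = top + step * level
            x1, x2 = pos[str(row["group1"])], pos[str(row["group2"])]
            ax.plot([x1, x1, x2, x2], [y, y + step / 4, y + step / 4, y], c="k", lw=0.8)
            ax.text((x1 + x2) / 2, y + step / 4, row["stars"], ha="center")
    path = _save(fig, spec)
    summary = {"box_stats": stats_rows}
    if comparison is not None:
        summary["pairwise"] = comparison.pairs
        summary["stars"] = {
            (r["group1"], r["group2"]): r["stars"] for _, r in comparison.pairs.iterrows()
        }
    return path, summary


def plot_pgs_vs_continuous(
    scores: pd.DataFrame, phenotype_col: str, spec: PlotSpec
) -> tuple[str, dict]:
    """PGS against a continuous phenotype as scatter or hexbin, with the
    least-squares line and Pearson correlation annotated."""
    _require_column(scores, spec.score_col)
    _require_column(scores, phenotype_col)
    df = scores[[spec.score_col, phenotype_col]].dropna()
    x = df[spec.score_col].to_numpy(dtype=float)
    y = df[phenotype_col].to_numpy(dtype=float)
    if len(x) < 3:
        raise DataError("scatter plot needs at least 3 complete pairs")

    fit = assoc.linear_association(x, y, name=phenotype_col)
    r = float(pearsonr(x, y).statistic)

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    hex_counts = None
    if spec.hexbin:
        hb = ax.hexbin(x, y, gridsize=25, mincnt=1)
        hex_counts = hb.get_array().astype(int)
        fig.colorbar(hb, ax=ax, label="count")
    else:
        ax.scatter(x, y, s=8, alpha=0.6)
    xs = np.array([x.min(), x.max()])
    ax.plot(xs, fit.intercept + fit.slope * xs, c="firebrick")
    ax.annotate(f"r = {r:.2f}", xy=(0.05, 0.95), xycoords="axes fraction", va="top")
    ax.set_xlabel(spec.score_col)
    ax.set_ylabel(phenotype_col)
    path = _save(fig, spec)
    return path, {
        "correlation": r,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "n": fit.n,
        "hexbin_counts": hex_counts,
    }


def plot_pgs_rank(scores: pd.DataFrame, spec: PlotSpec) -> tuple[str, dict]:
    """Percentile-rank strip: samples in ascending percentile order with one
    covariate bar per requested column (categorical → color classes,
    continuous → heat scale)."""
    _require_column(scores, "percentile")
    for col in spec.covariate_cols:
        _require_column(scores, col)

    ordered = scores.sort_values("percentile", kind="mergesort").reset_index(drop=True)
    n = len(ordered)
    bars: dict[str, dict] = {}
    for col in spec.covariate_cols:
        series = ordered[col]
        if pd.api.types.is_numeric_dtype(series):
            bars[col] = {"kind": "continuous", "values": series.to_numpy(dtype=float)}
        else:
            cat = pd.Categorical(series)
            bars[col] = {
                "kind": "categorical",
                "codes": cat.codes.copy(),
                "classes": list(map(str, cat.categories)),
            }

    n_panels = 1 + len(bars)
    fig, axes = plt.subplots(
        n_panels,
        1,
        figsize=(spec.width, spec.height),
        sharex=True,
        gridspec_kw={"height_ratios": [4] + [0.6] * len(bars)},
    )
    axes = np.atleast_1d(axes)
    axes[0].bar(np.arange(n), ordered["percentile"], width=1.0)
    axes[0].set_ylabel("percentile")
    for ax, (col, bar) in zip(axes[1:], bars.items()):
        row = bar["values"] if bar["kind"] == "continuous" else bar["codes"]
        ax.imshow(
            np.asarray(row, dtype=float)[None, :],
            aspect="auto",
            interpolation="nearest",
            cmap="viridis" if bar["kind"] == "continuous" else "tab10",
        )
        ax.set_yticks([])
        ax.set_ylabel(col, rotation=0, ha="right", va="center")
    path = _save(fig, spec)
    return path, {
        "sample_order": ordered["sample_id"].tolist() if "sample_id" in ordered else list(ordered.index),
        "percentiles": ordered["percentile"].to_numpy(dtype=float),
        "bars": bars,
    }


def plot_roc(roc: assoc.RocResult, spec: PlotSpec) -> tuple[str, dict]:
    """Draw an ROC curve with its AUC annotation and the chance diagonal."""
    fpr = 1 - roc.specificity
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    ax.plot(fpr, roc.sensitivity, lw=2)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
    annotation = f"AUC = {roc.auc:.2f}"
    ax.annotate(annotation, xy=(0.6, 0.1), xycoords="axes fraction")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    path = _save(fig, spec)
    return path, {
        "fpr": np.asarray(fpr, dtype=float),
        "tpr": np.asarray(roc.sensitivity, dtype=float),
        "auc": roc.auc,
        "annotation": annotation,
    }
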