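"""Group-comparison statistics and report generation.

Conventions: unpaired t-tests for across-well comparisons, paired t-tests
for within-well (baseline vs treatment) comparisons, two-way ANOVA
(type-II sums of squares) with Tukey HSD posthoc for factorial designs,
and an optional Bonferroni correction for families of t-tests.  Fold
difference is mean(condition) / mean(control).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "compare_two_groups",
    "two_way_anova",
    "bonferroni",
    "render_report",
]


@dataclass
class GroupComparison:
    """Two-group t-test with descriptive statistics."""

    metric: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    fold_difference: float  # mean_b / mean_a
    paired: bool


def compare_two_groups(
    table: pd.DataFrame,
    metric: str,
    groups: tuple[str, str],
    paired: bool = False,
    group_col: str = "group",
    value_col: str = "value",
    well_col: str = "well",
) -> GroupComparison:
    """t-test between two groups of a long-format metric table.

    ``table`` rows: one value per (well, metric).  For paired tests the two
    groups are matched on well id.  Fold difference is mean(B)/mean(A), A
    being the first (control) group.
    """
    sub = table[table["metric"] == metric] if "metric" in table.columns else table
    a = sub[sub[group_col] == groups[0]]
    b = sub[sub[group_col] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        merged = a.merge(b, on=well_col, suffixes=("_a", "_b"))
        if len(merged) < 2:
            raise ValueError("paired test needs at least 2 matched wells")
        va = merged[f"{value_col}_a"].to_numpy(dtype=float)
        vb = merged[f"{value_col}_b"].to_numpy(dtype=float)
        t, p = stats.ttest_rel(va, vb)
        df = len(va) - 1
    else:
        va = a[value_col].to_numpy(dtype=float)
        vb = b[value_col].to_numpy(dtype=float)
        t, p = stats.ttest_ind(va, vb)
        df = len(va) + len(vb) - 2
    return GroupComparison(
        metric=metric,
        group_a=groups[0],
        group_b=groups[1],
        mean_a=float(va.mean()),
        sd_a=float(va.std(ddof=1)),
        mean_b=float(vb.mean()),
        sd_b=float(vb.std(ddof=1)),
        n_a=len(va),
        n_b=len(vb),
        t=float(t),
        df=float(df),
        p=float(p),
        fold_difference=float(vb.mean() / va.mean()) if va.mean() != 0 else float("nan"),
        paired=paired,
    )


def two_way_anova(
    table: pd.DataFrame,
    metric: str,
    factor_a: str,
    factor_b: str,
    value_col: str = "value",
) -> dict:
    """Two-way ANOVA with interaction (type-II SS) plus Tukey HSD posthoc.

    Every design cell needs at least 2 replicates so the interaction is
    estimable.  Returns the ANOVA table, per-factor Tukey results, and the
    fitted model.
    """
    sub = table[table["metric"] == metric] if "metric" in table.columns else table
    sub = sub.copy()
    for f in (factor_a, factor_b):
        if sub[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    cell_sizes = sub.groupby([factor_a, factor_b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [sub[factor_a].unique(), sub[factor_b].unique()], names=[factor_a, factor_b]
    )
    cell_sizes = cell_sizes.reindex(full, fill_value=0)
    bad = cell_sizes[cell_sizes < 2]
    if len(bad):
        cell = bad.index[0]
        raise ValueError(
            f"design cell {cell} has {int(bad.iloc[0])} replicate(s); need >= 2"
        )
    sub = sub.rename(columns={value_col: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_y ~ C(_fa) * C(_fb)", data=sub).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out = {
        "anova": anova,
        "p_a": float(anova.loc["C(_fa)", "PR(>F)"]),
        "p_b": float(anova.loc["C(_fb)", "PR(>F)"]),
        "p_interaction": float(anova.loc["C(_fa):C(_fb)", "PR(>F)"]),
        "model": model,
    }
    # Tukey pairwise comparisons on the crossed cells
    cells = sub["_fa"].astype(str) + ":" + sub["_fb"].astype(str)
    if cells.nunique() > 1:
        out["tukey"] = pairwise_tukeyhsd(sub["_y"].to_numpy(dtype=float), cells.to_numpy())
    return out


def bonferroni(p_values: list[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted p-values and rejection flags for a test family."""
    reject, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="bonferroni")
    return p_adj, reject


def render_report(results: dict, outputs_dir: str | Path, seed: int | None = None) -> list[Path]:
    """Write summary tables, figures and run metadata for a pipeline run.

    ``results`` may carry any of: ``well_summary`` (DataFrame),
    ``pixel_summary`` (DataFrame), ``sweep`` (DataFrame with threshold,
    class, fraction), ``distance_curve`` (DataFrame), ``heatmap`` (pixels x
    time array), ``metrics`` (long DataFrame for box plots), and
    ``parameters`` (dict echoed into the metadata JSON).  Missing inputs
    produce explicit "no data" placeholders, never silent absences.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outputs_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out}: {exc}") from exc
    written: list[Path] = []

    def save_csv(name: str, df: pd.DataFrame | None) -> None:
        path = out / name
        if df is None or len(df) == 0:
            path.write_text("no data\n")
        else:
            df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    save_csv("well_summary.csv", results.get("well_summary"))
    save_csv("pixel_summary.csv", results.get("pixel_summary"))
    save_csv("threshold_sweep.csv", results.get("sweep"))
    save_csv("correlation_vs_distance.csv", results.get("distance_curve"))

    # figures
    heat = results.get("heatmap")
    fig, ax = plt.subplots(figsize=(6, 4))
    if heat is not None and np.size(heat):
        ax.imshow(np.asarray(heat), aspect="auto", interpolation="nearest", cmap="viridis")
        ax.set_xlabel("frame")
        ax.set_ylabel("pixel (ranked)")
    else:
        ax.text(0.5, 0.5, "no data", ha="center", va="center")
    fig.savefig(out / "spike_raster_heatmap.png", dpi=120)
    plt.close(fig)
    written.append(out / "spike_raster_heatmap.png")

    sweep = results.get("sweep")
    fig, ax = plt.subplots(figsize=(5, 4))
    if sweep is not None and len(sweep):
        for cls, g in sweep.groupby("class"):
            ax.plot(g["threshold"], g["fraction"], label=cls)
        ax.set_xlabel("prominence threshold")
        ax.set_ylabel("fraction of spikes retained")
        ax.legend()
    else:
        ax.text(0.5, 0.5, "no data", ha="center", va="center")
    fig.savefig(out / "threshold_sweep.png", dpi=120)
    plt.close(fig)
    written.append(out / "threshold_sweep.png")

    curve = results.get("distance_curve")
    fig, ax = plt.subplots(figsize=(5, 4))
    if curve is not None and len(curve):
        ax.plot(curve["bin_center_um"], curve["mean_r"], "-o")
        if curve["ci_lo"].notna().any():
            ax.fill_between(curve["bin_center_um"], curve["ci_lo"], curve["ci_hi"], alpha=0.3)
        ax.set_xlabel("pixel distance (um)")
        ax.set_ylabel("mean Pearson r")
    else:
        ax.text(0.5, 0.5, "no data", ha="center", va="center")
    fig.savefig(out / "correlation_vs_distance.png", dpi=120)
    plt.close(fig)
    written.append(out / "correlation_vs_distance.png")

    metrics = results.get("metrics")
    fig, ax = plt.subplots(figsize=(5, 4))
    if metrics is not None and len(metrics):
        groups = sorted(metrics["group"].unique())
        data = [metrics[metrics["group"] == g]["value"].to_numpy() for g in groups]
        ax.boxplot(data, tick_labels=groups, whis=1.5)
        for i, vals in enumerate(data, start=1):
            ax.plot(np.full(len(vals), i) + np.linspace(-0.1, 0.1, len(vals)), vals, "k.", alpha=0.6)
        ax.set_ylabel("value")
    else:
        ax.text(0.5, 0.5, "no data", ha="center", va="center")
    fig.savefig(out / "group_boxplot.png", dpi=120)
    plt.close(fig)
    written.append(out / "group_boxplot.png")

    meta = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "parameters": results.get("parameters", {}),
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1, default=str))
    written.append(meta_path)
    return written
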