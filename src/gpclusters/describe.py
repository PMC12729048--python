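"""Cluster characterisation: measure, sociodemographic and workforce
summaries in the shape of published practice-characteristics tables.

All summaries are descriptive — unweighted means with sample (n-1)
standard deviations, categorical counts with percentages over non-missing
values, and workforce figures restricted to practices with workforce data
(coverage reported). No inferential tests are run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import AGE_BAND_COLUMNS, REGISTRY_FTE_ROLES
from .measures import MEASURE_COLUMNS

CATEGORICAL_FIELDS = ["region", "imd_quintile", "rural_urban"]


def _mean_sd(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    stats = frame[columns].agg(["mean", "std", "count"]).T
    stats.columns = ["mean", "sd", "n"]
    return stats


@dataclass
class ClusterSummary:
    """Per-group descriptive tables.

    ``measure_stats``: group x measure mean/SD. ``triage``: count and % of
    practices with any triage use. ``registry_stats``: list size, ethnicity
    share, mean age and age-band distribution. ``categoricals``: counts (%)
    by region, IMD quintile and rural–urban status over non-missing values.
    ``workforce``: FTE per 10 000 by role among practices with workforce
    data. ``missing``: missing-value counts per field and group.
    """

    group_sizes: dict
    measure_stats: pd.DataFrame | None
    triage: pd.DataFrame | None
    registry_stats: pd.DataFrame
    categoricals: dict[str, pd.DataFrame]
    age_distribution: pd.DataFrame
    workforce: pd.DataFrame
    workforce_coverage: dict
    missing: pd.DataFrame

    def to_markdown(self) -> str:
        parts = ["# Cluster summary", ""]
        parts.append(
            "Practices per group: "
            + ", ".join(f"{g}: {n}" for g, n in self.group_sizes.items())
        )
        if self.measure_stats is not None:
            parts += ["", "## Appointment-system measures, mean (SD)", ""]
            table = self.measure_stats.copy()
            for g in self.group_sizes:
                table[g] = (
                    table[(g, "mean")].map("{:.2f}".format)
                    + " ("
                    + table[(g, "sd")].map("{:.2f}".format)
                    + ")"
                )
            parts.append(table[list(self.group_sizes)].to_markdown())
        if self.triage is not None:
            parts += ["", "## Practices using clinical triage", "", self.triage.to_markdown()]
        parts += ["", "## Registry characteristics", "", self.registry_stats.to_markdown()]
        for fieldname, table in self.categoricals.items():
            parts += ["", f"## {fieldname}", "", table.to_markdown()]
        parts += ["", "## Age distribution (%)", "", self.age_distribution.round(1).to_markdown()]
        parts += [
            "",
            "## Workforce, FTE per 10 000 patients, mean (SD)",
            "",
            f"Workforce data available: "
            + ", ".join(f"{g}: {n}" for g, n in self.workforce_coverage.items()),
            "",
            self.workforce.round(2).to_markdown(),
        ]
        return "\n".join(parts)


def plot_cluster_profiles(summary: "ClusterSummary", ax=None):
    """Grouped bar chart of per-cluster measure means (proportions only).

    Returns the matplotlib Axes; needs ``measure_stats`` (i.e. a summary
    built with measure vectors).
    """
    import matplotlib.pyplot as plt

    if summary.measure_stats is None:
        raise ValueError("summary has no measure statistics to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    proportions = [m for m in MEASURE_COLUMNS if m != "appt_rate"]
    groups = list(summary.group_sizes)
    width = 0.8 / len(groups)
    x = np.arange(len(proportions))
    for i, g in enumerate(groups):
        means = [summary.measure_stats.loc[m, (g, "mean")] for m in proportions]
        sds = [summary.measure_stats.loc[m, (g, "sd")] for m in proportions]
        ax.bar(x + i * width, means, width=width, yerr=sds, capsize=2,
               label=f"cluster {g} (n={summary.group_sizes[g]})")
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(proportions, rotation=45, ha="right")
    ax.set_ylabel("mean (SD)")
    ax.legend()
    return ax


def summarise_clusters(
    registry: pd.DataFrame,
    labels: pd.Series,
    measure_vectors: pd.DataFrame | None = None,
) -> ClusterSummary:
    """Describe each cluster's measures, sociodemographics and workforce.

    ``labels`` is a cluster Series indexed by practice_id; ``registry``
    the validated registry; ``measure_vectors`` the (unscaled) window-
    averaged measures. Every labelled practice must be present in the
    registry; empty groups are an error.
    """
    return compare_groups(registry, labels, measure_vectors)


def compare_groups(
    registry: pd.DataFrame,
    grouping: pd.Series,
    measure_vectors: pd.DataFrame | None = None,
) -> ClusterSummary:
    """As :func:`summarise_clusters` for an arbitrary group assignment
    (e.g. included vs excluded practices)."""
    grouping = grouping.dropna()
    groups = sorted(grouping.unique())
    if len(groups) == 0:
        raise ValueError("empty grouping")
    reg = registry.loc[grouping.index]
    group_sizes = {g: int((grouping == g).sum()) for g in groups}
    if any(n == 0 for n in group_sizes.values()):
        raise ValueError("empty group in grouping")

    measure_stats = None
    triage = None
    if measure_vectors is not None:
        mv = measure_vectors.loc[grouping.index]
        blocks = {}
        tri_rows = []
        for g in groups:
            sub = mv[grouping == g]
            stats = _mean_sd(sub, MEASURE_COLUMNS)
            blocks[g] = stats[["mean", "sd"]]
            n_tri = int((sub["triage_use"] > 0).sum())
            tri_rows.append(
                {"group": g, "n_using_triage": n_tri, "pct": 100.0 * n_tri / len(sub)}
            )
        measure_stats = pd.concat(blocks, axis=1)
        triage = pd.DataFrame(tri_rows).set_index("group")

    reg_rows = {}
    for g in groups:
        sub = reg[grouping == g]
        reg_rows[g] = {
            "n": len(sub),
            "list_size_mean": sub["list_size"].mean(),
            "list_size_sd": sub["list_size"].std(),
            "white_share_mean": sub["white_share"].mean(),
            "white_share_sd": sub["white_share"].std(),
            "mean_age_mean": sub["mean_age"].mean(),
            "mean_age_sd": sub["mean_age"].std(),
        }
    registry_stats = pd.DataFrame(reg_rows).T

    categoricals = {}
    for fieldname in CATEGORICAL_FIELDS:
        tables = {}
        for g in groups:
            sub = reg.loc[grouping == g, fieldname].dropna()
            counts = sub.value_counts().sort_index()
            pct = 100.0 * counts / counts.sum() if counts.sum() else counts
            tables[g] = pd.DataFrame({"n": counts, "pct": pct.round(1)})
        categoricals[fieldname] = pd.concat(tables, axis=1).fillna(0)

    age = pd.DataFrame(
        {
            g: 100.0 * reg.loc[grouping == g, AGE_BAND_COLUMNS].mean()
            for g in groups
        }
    )

    fte_cols = [f"fte_{r}" for r in REGISTRY_FTE_ROLES]
    wf_rows = {}
    coverage = {}
    for g in groups:
        sub = reg.loc[grouping == g, fte_cols].dropna(how="all")
        coverage[g] = int(len(sub))
        stats = _mean_sd(sub, fte_cols)[["mean", "sd"]]
        stats.index = [c.removeprefix("fte_") for c in fte_cols]
        wf_rows[g] = stats
    workforce = pd.concat(wf_rows, axis=1)

    missing = pd.DataFrame(
        {
            g: reg[grouping == g][CATEGORICAL_FIELDS + fte_cols].isna().sum()
            for g in groups
        }
    )

    return ClusterSummary(
        group_sizes=group_sizes,
        measure_stats=measure_stats,
        triage=triage,
        registry_stats=registry_stats,
        categoricals=categoricals,
        age_distribution=age,
        workforce=workforce,
        workforce_coverage=coverage,
        missing=missing,
    )
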