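"""Figure helpers: gene dose/time profiles, GFE trajectory panels, dendrogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .study import CONTROL, dose_rank

_DOSE_COLORS = {"control": "tab:red", "low": "tab:blue", "middle": "tab:purple", "high": "tab:green"}


def plot_gene_profile(study, gene: str, compound: str, ax=None):
    """Per-gene expression over time, one line per dose level."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    s = study.samples[study.samples["compound"] == compound]
    for dose in study.dose_levels:
        sub = s[s["dose_level"] == dose].sort_values("time_h")
        if sub.empty:
            continue
        grouped = (
            study.values.loc[gene, sub["sample_id"].tolist()]
            .groupby(sub.set_index("sample_id")["time_h"])
            .mean()
        )
        ax.plot(grouped.index, grouped.values, marker="o",
                color=_DOSE_COLORS.get(dose), label=dose)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("log2 expression")
    ax.set_title(f"{gene} under {compound}")
    ax.legend(fontsize=7)
    return ax


def plot_gfe_trajectories(traj, set_name: str, group: str, dose_levels=None):
    """One panel per dose: GFE versus time for a (set, group)."""
    sub = traj[(traj["set"] == set_name) & (traj["group"] == group)]
    doses = [d for d in (dose_levels or sorted(sub["dose_level"].unique()))
             if d != CONTROL and d in set(sub["dose_level"])]
    fig, axes = plt.subplots(1, max(len(doses), 1), figsize=(3 * max(len(doses), 1), 3),
                             sharey=True, squeeze=False)
    for ax, dose in zip(axes[0], doses):
        pts = sub[sub["dose_level"] == dose].sort_values("time_h")
        ax.plot(pts["time_h"], pts["gfe"], marker="o", color=_DOSE_COLORS.get(dose, "k"))
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_title(f"{dose} dose", fontsize=9)
        ax.set_xlabel("time (h)")
    axes[0][0].set_ylabel("GFE")
    fig.suptitle(f"{set_name} — {group}", fontsize=10)
    fig.tight_layout()
    return fig


def plot_dendrogram(solution, ax=None):
    """Figure-style dendrogram of the compound clustering."""
    from scipy.cluster.hierarchy import dendrogram

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.35 * len(solution.compounds)), 3.5))
    dendrogram(
        np.asarray(solution.merges, dtype=float),
        labels=list(solution.compounds),
        color_threshold=_cut_height(solution),
        ax=ax,
    )
    ax.set_ylabel("Ward.D2 merge height")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    return ax


def _cut_height(solution) -> float:
    n = len(solution.compounds)
    k = solution.chosen_k
    heights = solution.merges[:, 2]
    if k <= 1:
        return float(heights[-1] * 1.01)
    idx = n - k  # first merge NOT performed in the k-cut
    return float((heights[idx - 1] + heights[idx]) / 2) if 0 < idx < len(heights) else float(heights[-1] * 1.01)
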