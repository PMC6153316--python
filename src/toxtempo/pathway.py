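"""Parametric gene-set scoring (PAGE) and Gene Fold Enrichment trajectories.

PAGE scores a gene set against the global fold-change distribution of one
condition with a normal z-statistic::

    Z = (Sm - mu) * sqrt(m) / sigma

where mu and sigma are the mean and (sample) standard deviation of all gene
fold changes in the condition, and Sm is the mean over the m set members
present in the data.  Under gene randomization Z is approximately standard
normal, giving a parametric two-sided p.

The Gene Fold Enrichment (GFE) score summarises how strongly *and* how
broadly a pathway responds in a condition::

    GFE = (k / K) * stat_mean

with k the number of set members called deregulated in the condition, K the
set size among measured genes, and stat_mean the set's mean log2 fold change
(signed, so trajectories distinguish up- from down-regulation; the PAGE z is
available as an alternative statistic).  Tracking GFE across time within
each dose level yields pathway-level dose/time trajectories, per compound or
pooled over compound clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .genesets import GeneSetCollection
from .study import dose_rank

logger = logging.getLogger(__name__)

PAGE_COLUMNS = ["set", "compound", "dose_level", "time_h", "m", "s_m", "mu", "sigma", "z_score", "p_value"]
GFE_COLUMNS = ["set", "group", "dose_level", "time_h", "gfe", "k_dereg", "k_total", "stat_mean"]


@dataclass
class PageResult:
    m: int
    s_m: float
    mu: float
    sigma: float
    z_score: float
    p_value: float
    absent: bool = False


@dataclass
class GfeResult:
    k_dereg: int
    k_total: int
    stat_mean: float
    gfe: float
    absent: bool = False


def page_score(fold_changes: pd.Series, members) -> PageResult:
    """PAGE z for one condition.

    ``fold_changes`` is a Series indexed by gene id (all genes of the
    condition); ``members`` the set's gene ids.  Sets with no measured
    member return an ``absent`` result; a degenerate background
    (sigma = 0 or fewer than 2 genes) raises ``ValueError``.
    """
    values = fold_changes.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("PAGE needs at least 2 genes in the background")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate background: sigma = 0")
    present = fold_changes.index.intersection(pd.Index(members))
    m = len(present)
    if m == 0:
        return PageResult(0, np.nan, mu, sigma, np.nan, np.nan, absent=True)
    s_m = float(fold_changes.loc[present].mean())
    z = (s_m - mu) * np.sqrt(m) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    return PageResult(m, s_m, mu, sigma, float(z), float(p))


def page_permutation_p(fold_changes: pd.Series, members, n_perm: int = 1000,
                       rng=None) -> float:
    """Gene-randomization check on the parametric p: the two-sided tail
    frequency of |z| over random same-size sets (add-one correction)."""
    rng = np.random.default_rng(rng)
    obs = page_score(fold_changes, members)
    if obs.absent:
        return np.nan
    values = fold_changes.to_numpy(dtype=float)
    mu, sigma, m = obs.mu, obs.sigma, obs.m
    hits = 0
    for _ in range(n_perm):
        s_m = values[rng.choice(values.size, size=m, replace=False)].mean()
        z = (s_m - mu) * np.sqrt(m) / sigma
        if abs(z) >= abs(obs.z_score):
            hits += 1
    return (hits + 1) / (n_perm + 1)


def gfe_score(fold_changes: pd.Series, dereg_flags: pd.Series, members) -> GfeResult:
    """GFE for one condition: (k/K) times the set's mean log2 fold change.

    ``dereg_flags`` must be boolean and share the gene index of
    ``fold_changes``.  Sets without measured members return ``absent``.
    """
    present = fold_changes.index.intersection(pd.Index(members))
    k_total = len(present)
    if k_total == 0:
        return GfeResult(0, 0, np.nan, np.nan, absent=True)
    k = int(dereg_flags.loc[present].sum())
    stat_mean = float(fold_changes.loc[present].mean())
    return GfeResult(k, k_total, stat_mean, (k / k_total) * stat_mean)


def page_table(fold_changes: pd.DataFrame, collection: GeneSetCollection,
               dose_levels=None) -> pd.DataFrame:
    """PAGE results for every (set, compound, dose, time) condition.

    ``fold_changes`` is the long table from
    :func:`toxtempo.preprocess.compute_fold_changes`.  Sets are restricted
    to measured genes first; conditions are processed in deterministic
    (compound, dose rank, time) order.
    """
    genes = fold_changes["gene"].unique()
    restricted = collection.restrict_to(genes)
    rows = []
    for (compound, dose, t), grp in _ordered_conditions(fold_changes, dose_levels):
        fc = grp.set_index("gene")["log2fc"]
        for name in restricted:
            r = page_score(fc, restricted[name])
            if r.absent:
                continue
            rows.append((name, compound, dose, t, r.m, r.s_m, r.mu, r.sigma, r.z_score, r.p_value))
    return pd.DataFrame(rows, columns=PAGE_COLUMNS)


def _ordered_conditions(fold_changes: pd.DataFrame, dose_levels=None):
    if dose_levels is None:
        seen = list(dict.fromkeys(fold_changes["dose_level"]))
        ranks = {d: i for i, d in enumerate(seen)}
    else:
        ranks = dose_rank(dose_levels)
    groups = fold_changes.groupby(["compound", "dose_level", "time_h"], sort=False)
    for key in sorted(groups.groups, key=lambda k: (k[0], ranks[k[1]], k[2])):
        yield key, groups.get_group(key)


def gfe_trajectories(deg_table: pd.DataFrame, fold_changes: pd.DataFrame,
                     collection: GeneSetCollection, grouping: str = "compound",
                     cluster_labels: dict | None = None, stat: str = "mean_fc",
                     dose_levels=None) -> pd.DataFrame:
    """GFE over time per (set, group, dose).

    grouping="compound" emits one trajectory per compound; every point
    satisfies gfe == (k_dereg / k_total) * stat_mean exactly.
    grouping="cluster" pools member compounds by averaging their
    per-compound GFE at matching (dose, time); pooled rows carry NaN
    components, since an average of products has no single (k, K, mean)
    decomposition.

    ``stat="page_z"`` replaces the set mean fold change with the PAGE z as
    the trajectory statistic; the output is labelled via the ``stat``
    attribute in ``DataFrame.attrs``.
    """
    if grouping not in ("compound", "cluster"):
        raise ConfigError(f"grouping must be 'compound' or 'cluster', got {grouping!r}")
    if stat not in ("mean_fc", "page_z"):
        raise ConfigError(f"stat must be 'mean_fc' or 'page_z', got {stat!r}")
    if grouping == "cluster" and cluster_labels is None:
        raise ConfigError("grouping='cluster' needs cluster_labels")

    genes = fold_changes["gene"].unique()
    restricted = collection.restrict_to(genes)
    flags = (
        deg_table.set_index(["compound", "dose_level", "time_h", "gene"])["is_deregulated"]
        .sort_index()
    )

    rows = []
    for (compound, dose, t), grp in _ordered_conditions(fold_changes, dose_levels):
        fc = grp.set_index("gene")["log2fc"]
        try:
            cond_flags = flags.loc[(compound, dose, t)].reindex(fc.index).fillna(False)
        except KeyError:
            logger.info("gfe: no deregulation flags for %s %s %s h; point omitted", compound, dose, t)
            continue
        for name in restricted:
            r = gfe_score(fc, cond_flags, restricted[name])
            if r.absent:
                continue
            stat_val = r.stat_mean
            if stat == "page_z":
                stat_val = page_score(fc, restricted[name]).z_score
            gfe = (r.k_dereg / r.k_total) * stat_val
            rows.append((name, compound, dose, t, gfe, r.k_dereg, r.k_total, stat_val))
    table = pd.DataFrame(rows, columns=GFE_COLUMNS)

    if grouping == "cluster":
        table["group"] = table["group"].map(
            lambda c: f"cluster{cluster_labels[c]}" if c in cluster_labels else None
        )
        dropped = table["group"].isna()
        if dropped.any():
            logger.info("gfe: %d points from unlabelled compounds omitted", int(dropped.sum()))
        table = (
            table[~dropped]
            .groupby(["set", "group", "dose_level", "time_h"], sort=False, as_index=False)
            .agg(gfe=("gfe", "mean"))
        )
        table["k_dereg"] = np.nan
        table["k_total"] = np.nan
        table["stat_mean"] = np.nan
        table = table[GFE_COLUMNS]

    table = table.sort_values(
        ["set", "group", "dose_level", "time_h"],
        key=lambda s: s.map(dose_rank(dose_levels)) if s.name == "dose_level" and dose_levels else s,
    ).reset_index(drop=True)
    table.attrs["stat"] = stat
    return table


def rank_pathways(results: pd.DataFrame, top_n: int | None = None,
                  p_threshold: float = 0.05) -> pd.DataFrame:
    """Significant PAGE hits ordered by |z| (desc), ties by set name."""
    sig = results[results["p_value"] < p_threshold].copy()
    sig["_absz"] = sig["z_score"].abs()
    sig = sig.sort_values(["_absz", "set"], ascending=[False, True], kind="mergesort")
    sig = sig.drop(columns="_absz").reset_index(drop=True)
    if top_n is not None:
        sig = sig.head(top_n)
    return sig
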