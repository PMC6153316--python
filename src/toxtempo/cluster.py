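"""Compound clustering on fold-change signatures.

Compounds are described by the log2 fold changes of their genes across the
requested (dose, time) slices and clustered agglomeratively with Euclidean
distances under the Ward.D2 criterion (Lance-Williams update on squared
distances, merge heights reported on the distance scale — the behaviour of
R's ``hclust(method="ward.D2")`` and of scipy's ``ward``).  The number of
clusters is chosen with the elbow method: the within-cluster sum of squared
errors SER(k) is computed for k = 1..10 and the selected k maximises the
curvature (second difference) of that curve.

Compounds profiled at fewer than two time points are excluded up front, as
their trajectories cannot inform the grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, StudyError
from .study import dose_rank

logger = logging.getLogger(__name__)


@dataclass
class CompoundFeatures:
    """Compounds x features matrix of log2 fold changes.

    Each feature is one (gene, dose, time) slice; ``provenance`` records the
    filters applied and any compounds or incomplete features dropped.
    """

    matrix: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def compounds(self) -> list:
        return list(self.matrix.index)


@dataclass
class ClusterSolution:
    """Ward merge history plus the elbow-selected flat clustering."""

    merges: np.ndarray           # (n-1, 4): id_a, id_b, height, size
    ser_by_k: dict               # k -> within-cluster sum of squared errors
    chosen_k: int
    labels: dict                 # compound -> cluster index (0-based)
    compounds: list = field(default_factory=list)


def build_features(fold_changes: pd.DataFrame, time_filter=None, doses=None,
                   genes=None, min_timepoints: int = 2,
                   compounds=None, dose_levels=None) -> CompoundFeatures:
    """Pivot a fold-change table into a compounds x features matrix.

    Compounds with data for fewer than ``min_timepoints`` distinct times
    (counted before the time filter) are dropped and logged.  ``time_filter``
    restricts features to the given times (e.g. ``[24]`` for the 24 h
    slice), ``doses``/``genes``/``compounds`` restrict the other axes.
    Features not observed for every kept compound are dropped.  Column
    order is deterministic: sorted by (gene, dose rank, time).
    """
    fc = fold_changes
    if compounds is not None:
        fc = fc[fc["compound"].isin(set(compounds))]
    counts = fc.groupby("compound")["time_h"].nunique()
    kept = counts[counts >= min_timepoints].index
    dropped = sorted(set(counts.index) - set(kept))
    if dropped:
        logger.info("clustering: excluded %s (fewer than %d timepoints)", dropped, min_timepoints)
    fc = fc[fc["compound"].isin(kept)]
    if time_filter is not None:
        fc = fc[fc["time_h"].isin({float(t) for t in time_filter})]
    if doses is not None:
        fc = fc[fc["dose_level"].isin(set(doses))]
    if genes is not None:
        fc = fc[fc["gene"].isin(set(genes))]
    if fc.empty:
        raise StudyError("no compounds survive the feature filters")
    wide = fc.pivot_table(index="compound", columns=["gene", "dose_level", "time_h"],
                          values="log2fc", aggfunc="mean")
    incomplete = wide.columns[wide.isna().any(axis=0)]
    if len(incomplete):
        logger.info("clustering: dropped %d incomplete features", len(incomplete))
        wide = wide.drop(columns=incomplete)
    if wide.shape[1] == 0:
        raise StudyError("no complete features remain after filtering")
    ranks = dose_rank(dose_levels) if dose_levels else None
    ordered = sorted(
        wide.columns,
        key=lambda c: (c[0], ranks[c[1]] if ranks else c[1], c[2]),
    )
    wide = wide[ordered]
    wide = wide.loc[sorted(wide.index)]
    return CompoundFeatures(
        matrix=wide,
        provenance={
            "time_filter": list(time_filter) if time_filter is not None else None,
            "doses": sorted(doses) if doses is not None else None,
            "n_genes": int(fc["gene"].nunique()),
            "dropped_compounds": dropped,
            "dropped_features": int(len(incomplete)),
        },
    )


def ward_cluster(features: CompoundFeatures) -> np.ndarray:
    """Agglomerate with the Ward.D2 criterion.

    Returns a scipy-style merge history: row s merges cluster ids ``a`` and
    ``b`` (originals are 0..n-1, merged clusters n+s) at ``height`` into a
    cluster of ``size`` members.  Ties in the merge criterion are broken by
    the lexicographically smallest (a, b) pair, making the result
    independent of platform and input order.
    """
    X = features.matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise StudyError("clustering needs at least 2 compounds")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        slots = sorted(active)
        best = None
        for ai in range(len(slots)):
            for bi in range(ai + 1, len(slots)):
                i, j = slots[ai], slots[bi]
                key = (d2[i, j], min(active[i][0], active[j][0]),
                       max(active[i][0], active[j][0]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        id_i, si = active[i]
        id_j, sj = active[j]
        height = float(np.sqrt(max(d2[i, j], 0.0)))
        Z[step] = (min(id_i, id_j), max(id_i, id_j), height, si + sj)
        # Lance-Williams Ward update on squared distances
        for k in slots:
            if k in (i, j):
                continue
            sk = active[k][1]
            d2[i, k] = d2[k, i] = (
                (si + sk) * d2[i, k] + (sj + sk) * d2[j, k] - sk * d2[i, j]
            ) / (si + sj + sk)
        del active[j]
        active[i] = (n + step, si + sj)
    return Z


def cut_to_k(merges: np.ndarray, k: int, n: int | None = None) -> np.ndarray:
    """Flat labels from the first n-k merges.

    Label ids are assigned by order of first appearance over the original
    leaf order (0-based).
    """
    if n is None:
        n = merges.shape[0] + 1
    if not 1 <= k <= n:
        raise ConfigError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + merges.shape[0]))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(merges[step, 0]), int(merges[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    labels = np.empty(n, dtype=int)
    seen = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen)
        labels[leaf] = seen[root]
    return labels


def _ser(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        centroid = block.mean(axis=0)
        total += float(((block - centroid) ** 2).sum())
    return total


def elbow_select(features: CompoundFeatures, k_range=(1, 10)):
    """SER curve over k and the maximum-curvature knee.

    Returns (ser_by_k, chosen_k).  chosen_k maximises the second difference
    SER(k-1) - 2 SER(k) + SER(k+1) over interior k; ties go to the smaller
    k.  A k_range exceeding the number of compounds is truncated with a log
    message.
    """
    X = features.matrix.to_numpy(dtype=float)
    n = X.shape[0]
    lo, hi = int(k_range[0]), int(k_range[-1])
    if lo < 1:
        raise ConfigError(f"k_range must start at >= 1, got {k_range}")
    if hi > n:
        logger.info("clustering: k range truncated to %d compounds", n)
        hi = n
    merges = ward_cluster(features)
    ser_by_k = {}
    for k in range(lo, hi + 1):
        labels = cut_to_k(merges, k, n)
        ser_by_k[k] = _ser(X, labels)
    interior = [k for k in ser_by_k if (k - 1) in ser_by_k and (k + 1) in ser_by_k]
    if not interior:
        chosen = min(ser_by_k)
    else:
        curvature = {k: ser_by_k[k - 1] - 2 * ser_by_k[k] + ser_by_k[k + 1] for k in interior}
        chosen = min(interior, key=lambda k: (-curvature[k], k))
    return ser_by_k, chosen


def cluster_compounds(features: CompoundFeatures, k_range=(1, 10),
                      k_override: int | None = None) -> ClusterSolution:
    """Full clustering stage: Ward merges, SER curve, elbow cut, labels."""
    merges = ward_cluster(features)
    ser_by_k, chosen = elbow_select(features, k_range)
    if k_override is not None:
        chosen = int(k_override)
    labels = cut_to_k(merges, chosen, len(features.compounds))
    return ClusterSolution(
        merges=merges,
        ser_by_k=ser_by_k,
        chosen_k=chosen,
        labels=dict(zip(features.compounds, labels.tolist())),
        compounds=features.compounds,
    )


def to_newick(merges: np.ndarray, leaf_names) -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights.

    A child's branch length is the parent's merge height minus the child's
    own height (0 for leaves).
    """
    n = len(leaf_names)
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaf_names[i]) for i in range(n)}
    for step in range(merges.shape[0]):
        a, b, h, _ = merges[step]
        a, b = int(a), int(b)
        new = n + step
        la = h - height[a]
        lb = h - height[b]
        node[new] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
        height[new] = h
    return node[n + merges.shape[0] - 1] + ";"
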