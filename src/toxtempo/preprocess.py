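"""Concerted normalization, replicate averaging and fold changes.

The three preprocessing steps applied before any testing:

1. **Quantile normalization** across *all* arrays at once ("concerted"), so
   every sample shares one reference distribution (the across-column mean of
   order statistics).  This removes array-level technical offsets.
2. **Replicate averaging** within each (compound, dose, time, batch) cell on
   the log2 scale.
3. **Fold changes**: log2FC = mean log2 treated − mean log2 of the matched
   vehicle control for the same compound and time (equivalently, the log2 of
   the intensity ratio, since RMA output is already log2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import StudyError
from .study import CONTROL, ExpressionStudy, dose_rank

FC_COLUMNS = ["gene", "compound", "dose_level", "time_h", "log2fc"]


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample onto the mean order-statistic distribution.

    Tied values within a column receive the mean of the mean-order-statistics
    of the positions they occupy (average-rank convention), which keeps the
    transform deterministic and idempotent.
    """
    V = study.values.to_numpy(dtype=float)
    if V.shape[1] < 2:
        raise StudyError("quantile normalization needs at least 2 samples")
    if np.isnan(V).any():
        raise StudyError("expression matrix contains missing values")
    mean_sorted = np.sort(V, axis=0).mean(axis=1)
    out = np.empty_like(V)
    n = V.shape[0]
    for j in range(V.shape[1]):
        col = V[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = mean_sorted
        sorted_vals = col[order]
        # average assigned quantiles over runs of ties
        start = 0
        for i in range(1, n + 1):
            if i == n or sorted_vals[i] != sorted_vals[start]:
                if i - start > 1:
                    assigned[order[start:i]] = mean_sorted[start:i].mean()
                start = i
        out[:, j] = assigned
    return ExpressionStudy(
        values=pd.DataFrame(out, index=study.values.index, columns=study.values.columns),
        samples=study.samples,
        dose_levels=study.dose_levels,
    )


def average_replicates(study: ExpressionStudy) -> ExpressionStudy:
    """Average replicate arrays per (compound, dose, time, batch) cell.

    Idempotent: averaged studies pass through unchanged (one sample per
    cell already).  The averaged sample keeps batch and the negative-control
    flag; its replicate index is set to 0 to mark it as a cell mean.
    """
    s = study.samples
    keys = ["compound", "dose_level", "time_h", "batch", "is_negative_control"]
    ranks = dose_rank(study.dose_levels)
    groups = s.groupby(keys, sort=False)
    order = sorted(
        groups.groups,
        key=lambda k: (k[0], k[2], ranks[k[1]], k[3]),
    )
    new_rows, new_cols = [], {}
    for key in order:
        compound, dose, t, batch, neg = key
        ids = groups.get_group(key)["sample_id"].tolist()
        if not ids:
            raise StudyError(f"condition with no samples: {key}")
        new_id = f"{compound}_{dose}_{t:g}h_avg"
        new_rows.append(
            {
                "sample_id": new_id,
                "compound": compound,
                "dose_level": dose,
                "time_h": t,
                "replicate": 0,
                "batch": batch,
                "is_negative_control": neg,
            }
        )
        new_cols[new_id] = study.values[ids].mean(axis=1)
    return ExpressionStudy(
        values=pd.DataFrame(new_cols, index=study.values.index),
        samples=pd.DataFrame(new_rows),
        dose_levels=study.dose_levels,
    )


def compute_fold_changes(study: ExpressionStudy) -> pd.DataFrame:
    """Log2 fold change of every treated cell against its matched control.

    Accepts raw or replicate-averaged studies (cell means are taken either
    way).  Returns a long table with :data:`FC_COLUMNS`, one row per
    (gene, compound, non-control dose, time).

    Raises :class:`StudyError` naming any treated condition without a
    matched control.
    """
    s = study.samples
    ranks = dose_rank(study.dose_levels)
    cell_ids = s.groupby(["compound", "dose_level", "time_h"], sort=False).groups
    cell_means = {
        key: study.values[s.loc[idx, "sample_id"].tolist()].mean(axis=1).to_numpy()
        for key, idx in cell_ids.items()
    }
    genes = study.values.index.to_numpy()
    treated = sorted(
        (k for k in cell_means if k[1] != CONTROL),
        key=lambda k: (k[0], ranks[k[1]], k[2]),
    )
    frames = []
    for compound, dose, t in treated:
        ctrl_key = (compound, CONTROL, t)
        if ctrl_key not in cell_means:
            raise StudyError(
                f"treated condition without matched control: compound={compound} "
                f"dose={dose} time={t}"
            )
        fc = cell_means[(compound, dose, t)] - cell_means[ctrl_key]
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "compound": compound,
                    "dose_level": dose,
                    "time_h": t,
                    "log2fc": fc,
                }
            )
        )
    if not frames:
        raise StudyError("study has no treated conditions")
    out = pd.concat(frames, ignore_index=True)
    if not np.isfinite(out["log2fc"]).all():
        raise StudyError("non-finite fold changes")
    return out
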