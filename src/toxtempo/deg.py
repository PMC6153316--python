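"""Per-gene differential expression with negative-control subtraction.

For every gene and every treated (compound, dose, time) condition the module
tests the contrast against the matched vehicle control with an ordinary
least-squares linear model — the two-group t-test Y = α + xβ + ε, optionally
with batch dummies in the design.  P-values are controlled for multiple
testing (Bonferroni by default, Benjamini–Hochberg available) and a gene is
called deregulated in a condition when both gates pass:

    adjusted p <= alpha     and     |log2FC| >= log2(fc_threshold)

Genes that meet the same criteria under the negative-control (non-steatotic)
compounds are removed from the steatotic deregulated list, on the premise
that they reflect generic culture/toxicity responses rather than the adverse
outcome under study.

Variance estimation.  With duplicate arrays a purely condition-local t-test
has 2 residual degrees of freedom.  The pipeline therefore defaults to a
cell-means model per (gene, compound): one mean per (dose, time) cell, with
the residual variance pooled over all of the compound's cells (batches are
nested within cells and absorbed).  Condition-local testing is available via
``variance="per_condition"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DesignError, StudyError
from .study import CONTROL, ExpressionStudy, dose_rank

DEG_COLUMNS = [
    "gene", "compound", "dose_level", "time_h",
    "log2fc", "t_stat", "p_raw", "p_adj", "is_deregulated",
]


@dataclass
class DegConfig:
    """Thresholds of the deregulation call.

    alpha : significance level on the adjusted p-value (default 0.05)
    fc_threshold : linear-scale fold change (default 1.5, i.e.
        |log2FC| >= log2 1.5 ~= 0.585)
    adjust_method : "bonferroni" or "bh"
    family : "global" (all tests of the analysis form one family, controlling
        the family-wise error of the union gene list) or "condition"
        (one family per (compound, dose, time))
    variance : "pooled" (cell-means model per compound) or "per_condition"
    """

    alpha: float = 0.05
    fc_threshold: float = 1.5
    adjust_method: str = "bonferroni"
    family: str = "global"
    variance: str = "pooled"

    def validate(self) -> "DegConfig":
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.fc_threshold < 1.0:
            raise ConfigError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if self.adjust_method not in ("bonferroni", "bh"):
            raise ConfigError(f"adjust_method must be 'bonferroni' or 'bh', got {self.adjust_method!r}")
        if self.family not in ("global", "condition"):
            raise ConfigError(f"family must be 'global' or 'condition', got {self.family!r}")
        if self.variance not in ("pooled", "per_condition"):
            raise ConfigError(f"variance must be 'pooled' or 'per_condition', got {self.variance!r}")
        return self


def fit_gene_model(y, group, batch=None):
    """Two-group OLS for one gene: y = alpha + group*beta (+ batch dummies).

    Parameters
    ----------
    y : per-sample log2 values
    group : 0/1 indicator (1 = treated)
    batch : optional per-sample batch labels, entered as dummies

    Returns
    -------
    (alpha_hat, beta_hat, t_stat, p_raw)
        With a single batch this is exactly the classical pooled two-sample
        t-test.  Degenerate zero-residual fits return t=0, p=1 when the
        group effect is 0, and ±inf, p=0 otherwise.

    Raises
    ------
    DesignError
        If the design is rank deficient, e.g. the group indicator is
        constant or confounded with the batch structure (the message names
        the offending batches).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if y.shape != group.shape:
        raise DesignError("y and group have different lengths")
    if np.unique(group).size < 2:
        raise DesignError("group indicator is constant")
    X = pd.DataFrame({"intercept": np.ones_like(y), "group": group})
    if batch is not None:
        batch = pd.Series(list(batch), name="batch")
        levels = list(dict.fromkeys(batch))
        for lev in levels[1:]:  # first level is the reference
            X[f"batch[{lev}]"] = (batch == lev).astype(float).to_numpy()
        confounded = [
            lev for lev in levels
            if np.unique(group[(batch == lev).to_numpy()]).size < 2
        ]
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise DesignError(
                "rank-deficient design: group is confounded with batch "
                f"term(s) {confounded or levels}"
            )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("rank-deficient design")
    n, k = X.shape
    if n - k < 0:
        raise DesignError(f"{n} samples cannot support {k} design columns")
    res = sm.OLS(y, X).fit()
    alpha_hat = float(res.params["intercept"])
    beta_hat = float(res.params["group"])
    se = float(res.bse["group"])
    scale = max(1.0, float(np.abs(y).max()))
    if se <= 1e-12 * scale or not math.isfinite(se):
        # zero residual variance: the group effect is either exactly absent
        # or fits perfectly
        if abs(beta_hat) <= 1e-10 * scale:
            return alpha_hat, 0.0, 0.0, 1.0
        return alpha_hat, beta_hat, math.copysign(math.inf, beta_hat), 0.0
    return alpha_hat, beta_hat, float(res.tvalues["group"]), float(res.pvalues["group"])


def _guarded_t(fc, se, df):
    """Vectorised t and two-sided p with zero-variance guards."""
    fc = np.asarray(fc, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
        zero_se = se == 0.0
        t = np.where(zero_se & (fc == 0.0), 0.0, t)
        t = np.where(zero_se & (fc != 0.0), np.sign(fc) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.clip(p, 0.0, 1.0)


def condition_contrasts(study: ExpressionStudy, compounds=None, variance="pooled") -> pd.DataFrame:
    """Fit every (gene, compound, dose, time) contrast against its matched control.

    Returns a long DataFrame with columns gene, compound, dose_level, time_h,
    log2fc, t_stat, p_raw (flags are added by :func:`call_degs`).
    """
    s = study.samples
    ranks = dose_rank(study.dose_levels)
    if compounds is None:
        compounds = study.compounds
    genes = study.values.index.to_numpy()
    frames = []
    for compound in compounds:
        sub = s[s["compound"] == compound]
        if sub.empty:
            raise StudyError(f"no samples for compound {compound}")
        cells = {}
        for key, grp in sub.groupby(["dose_level", "time_h"], sort=False):
            cells[key] = study.values[grp["sample_id"].tolist()].to_numpy()
        n_total = sum(v.shape[1] for v in cells.values())
        if variance == "pooled":
            df_resid = n_total - len(cells)
            if df_resid < 1:
                raise StudyError(
                    f"compound {compound}: no residual degrees of freedom "
                    "(need replicated cells for the pooled variance)"
                )
            sse = np.zeros(len(genes))
            for v in cells.values():
                sse += ((v - v.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            sigma2 = sse / df_resid
        treated = sorted(
            (k for k in cells if k[0] != CONTROL),
            key=lambda k: (ranks[k[0]], k[1]),
        )
        for dose, t in treated:
            ctrl_key = (CONTROL, t)
            if ctrl_key not in cells:
                raise StudyError(
                    f"treated condition without matched control: compound={compound} "
                    f"dose={dose} time={t}"
                )
            vt, vc = cells[(dose, t)], cells[ctrl_key]
            r1, r2 = vt.shape[1], vc.shape[1]
            fc = vt.mean(axis=1) - vc.mean(axis=1)
            if variance == "pooled":
                se = np.sqrt(sigma2 * (1.0 / r1 + 1.0 / r2))
                dof = df_resid
            else:
                if r1 < 2 or r2 < 2:
                    raise StudyError(
                        f"compound {compound} ({dose}, {t} h): per-condition "
                        "testing needs >=2 samples per group"
                    )
                s2 = (
                    ((vt - vt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                    + ((vc - vc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                ) / (r1 + r2 - 2)
                se = np.sqrt(s2 * (1.0 / r1 + 1.0 / r2))
                dof = r1 + r2 - 2
            t_stat, p_raw = _guarded_t(fc, se, dof)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "compound": compound,
                        "dose_level": dose,
                        "time_h": t,
                        "log2fc": fc,
                        "t_stat": t_stat,
                        "p_raw": p_raw,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def bonferroni(p_values, m=None):
    """min(1, m * p) with m defaulting to the family size len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def _adjust(p, method):
    if method == "bonferroni":
        return bonferroni(p)
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame, config: DegConfig) -> pd.DataFrame:
    """Add adjusted p-values and deregulation flags to a fitted table.

    is_deregulated = (p_adj <= alpha) AND (|log2fc| >= log2(fc_threshold)),
    with the adjustment family set by ``config.family``.
    """
    cfg = config.validate()
    out = table.copy()
    if cfg.family == "global":
        out["p_adj"] = _adjust(out["p_raw"].to_numpy(), cfg.adjust_method)
    else:
        out["p_adj"] = (
            out.groupby(["compound", "dose_level", "time_h"], sort=False)["p_raw"]
            .transform(lambda p: _adjust(p.to_numpy(), cfg.adjust_method))
        )
    log2_thr = math.log2(cfg.fc_threshold)
    out["is_deregulated"] = (out["p_adj"] <= cfg.alpha) & (out["log2fc"].abs() >= log2_thr)
    return out


def union_over_conditions(deg_table: pd.DataFrame) -> set:
    """Genes deregulated in at least one condition (set semantics)."""
    flagged = deg_table.loc[deg_table["is_deregulated"], "gene"]
    return set(flagged)


def subtract_negative_controls(deg_steatotic: set, deg_negative: set) -> set:
    """Remove genes also deregulated by the negative controls (set difference)."""
    return set(deg_steatotic) - set(deg_negative)


@dataclass
class DegResult:
    """Bundle returned by :func:`run_deg`."""

    table: pd.DataFrame              # steatotic rows, flags after subtraction
    negative_table: pd.DataFrame     # negative-control rows with flags
    union_genes: set                 # steatotic union before subtraction
    negative_genes: set              # union over negative-control conditions
    final_genes: set                 # union after subtraction
    config: DegConfig = field(default_factory=DegConfig)


def run_deg(study: ExpressionStudy, config: DegConfig | None = None) -> DegResult:
    """The full differential-expression stage on a (normalized) study.

    Fits all contrasts for every compound in one analysis (one adjustment
    family when ``family="global"``), splits the table into steatotic and
    negative-control parts, and clears the flags of genes the negative
    controls also call, so downstream pathway scoring counts only
    outcome-specific deregulation.
    """
    cfg = (config or DegConfig()).validate()
    table = condition_contrasts(study, variance=cfg.variance)
    table = call_degs(table, cfg)
    negatives = set(study.negative_control_compounds)
    neg_mask = table["compound"].isin(negatives)
    neg_table = table[neg_mask].reset_index(drop=True)
    ste_table = table[~neg_mask].reset_index(drop=True)
    union_genes = union_over_conditions(ste_table)
    negative_genes = union_over_conditions(neg_table)
    final_genes = subtract_negative_controls(union_genes, negative_genes)
    ste_table.loc[ste_table["gene"].isin(negative_genes), "is_deregulated"] = False
    return DegResult(
        table=ste_table,
        negative_table=neg_table,
        union_genes=union_genes,
        negative_genes=negative_genes,
        final_genes=final_genes,
        config=cfg,
    )
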