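"""Two-stage temporal gene selection per compound.

The procedure follows the classical two-stage strategy for short time-course
microarray designs: per compound, each gene is fit with a polynomial
regression over (standardized) time, dose-group dummies and dose x time
interactions; genes whose global F-test survives a Benjamini-Hochberg FDR
screen then go through backward stepwise refinement, and only genes whose
selected model explains enough variance (R^2 >= 0.6 by default) are kept.
A plain-text exclusion list (e.g. cell-cycle genes from GO) can be removed
from the final sets.

Design columns, in deterministic order: intercept; time powers t, t^2 (time
centered on the mean of the distinct time points and scaled by their range);
dose dummies with control as the reference; dose x time interactions grouped
by time power.  With times {2, 8, 24}, four dose levels and degree 2 this is
1 + 2 + 3 + 6 = 12 columns.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DesignError
from .study import CONTROL, ExpressionStudy

logger = logging.getLogger(__name__)

FIT_COLUMNS = [
    "gene", "compound", "p_global", "q_bh", "selected_terms",
    "r_squared", "passes",
]


@dataclass
class TimeDesign:
    """A fixed-order design matrix over one compound's samples.

    matrix : DataFrame, rows aligned to the samples used to build it,
        columns named "intercept", "t", "t2", "dose_<level>",
        "dose_<level>:t", ...
    degree : polynomial degree in time
    term_order : map column -> polynomial order, used for stepwise
        tie-breaking (higher-order terms are dropped first on equal p).
    """

    matrix: pd.DataFrame
    degree: int
    time_center: float
    time_scale: float
    term_order: dict = field(default_factory=dict)

    @property
    def terms(self) -> list:
        return [c for c in self.matrix.columns if c != "intercept"]


def build_time_design(sample_table: pd.DataFrame, degree: int = 2,
                      dose_levels=None) -> TimeDesign:
    """Build the regression design for one compound's samples.

    Raises :class:`DesignError` when the degree is not supported by the
    number of distinct time points (degree must be < #times).
    """
    times = np.sort(sample_table["time_h"].unique())
    if degree < 1:
        raise DesignError(f"degree must be >= 1, got {degree}")
    if len(times) < 2:
        raise DesignError("need at least 2 distinct time points")
    if degree >= len(times):
        raise DesignError(
            f"degree {degree} needs more than {len(times)} distinct time points"
        )
    center = float(times.mean())
    scale = float(times.max() - times.min())
    s = (sample_table["time_h"].to_numpy(dtype=float) - center) / scale

    if dose_levels is None:
        seen = list(dict.fromkeys(sample_table["dose_level"]))
        dose_levels = [CONTROL] + [d for d in seen if d != CONTROL]
    treated_levels = [d for d in dose_levels if d != CONTROL]

    cols = {"intercept": np.ones(len(sample_table))}
    order = {}
    for p in range(1, degree + 1):
        name = "t" if p == 1 else f"t{p}"
        cols[name] = s ** p
        order[name] = p
    for d in treated_levels:
        name = f"dose_{d}"
        cols[name] = (sample_table["dose_level"] == d).to_numpy(dtype=float)
        order[name] = 1
    for p in range(1, degree + 1):
        tname = "t" if p == 1 else f"t{p}"
        for d in treated_levels:
            name = f"dose_{d}:{tname}"
            cols[name] = cols[f"dose_{d}"] * cols[tname]
            order[name] = p + 1
    X = pd.DataFrame(cols, index=sample_table.index)
    return TimeDesign(matrix=X, degree=degree, time_center=center,
                      time_scale=scale, term_order=order)


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with coefficient t-test p-values via the pseudo-inverse."""
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    resid = y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sse = float(resid @ resid)
    sigma2 = sse / df if df > 0 else np.nan
    cov_diag = np.einsum("ij,ij->i", pinv, pinv) * sigma2
    se = np.sqrt(np.maximum(cov_diag, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df) if df > 0 else np.full(k, np.nan)
    pvals = np.where(se == 0.0, np.where(beta == 0.0, 1.0, 0.0), pvals)
    return beta, pvals, sse


def global_fit(y, design: TimeDesign) -> float:
    """P-value of the F-test of the full model against intercept-only.

    Constant y (no variance) returns p = 1; an exact fit returns p ~ 0.
    """
    X = design.matrix.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, k_full = X.shape
    k = k_full - 1  # non-intercept terms
    if n <= k_full:
        raise DesignError(f"{n} observations cannot support {k_full} design columns")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0.0:
        return 1.0
    beta, _, sse = _ols(X, y)
    df2 = n - k_full
    if sse <= 0.0:
        return 0.0
    f = ((sst - sse) / k) / (sse / df2)
    return float(stats.f.sf(f, k, df2))


def global_fits(Y: np.ndarray, X: np.ndarray):
    """Vectorised global F-tests for a genes x samples block.

    Returns (p_global, r_squared_full) arrays.
    """
    n, k_full = X.shape
    k = k_full - 1
    df2 = n - k_full
    if df2 < 1:
        raise DesignError(f"{n} observations cannot support {k_full} design columns")
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T                     # genes x k_full
    resid = Y - beta @ X.T
    sse = (resid ** 2).sum(axis=1)
    centered = Y - Y.mean(axis=1, keepdims=True)
    sst = (centered ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((sst - sse) / k) / (sse / df2)
        r2 = 1.0 - sse / sst
    p = stats.f.sf(f, k, df2)
    p = np.where(sst <= 0.0, 1.0, p)
    p = np.where((sse <= 0.0) & (sst > 0.0), 0.0, p)
    r2 = np.where(sst <= 0.0, 0.0, np.clip(r2, 0.0, 1.0))
    return p, r2


def fdr_bh(p_values):
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def backward_stepwise(y, design: TimeDesign, alpha_in: float = 0.05):
    """Backward elimination starting from the full model.

    At each step the non-intercept term with the largest coefficient
    p-value above *alpha_in* is dropped (ties broken by dropping the
    higher-order term, then the later column); iteration stops when every
    remaining term is significant or only the intercept remains.

    Returns
    -------
    (selected_terms, coefficients, r_squared)
        selected_terms : list of retained non-intercept column names, in
        design order; coefficients : pandas Series over intercept +
        selected terms; r_squared : R^2 of the final model (0.0 for the
        intercept-only model).
    """
    y = np.asarray(y, dtype=float)
    Xfull = design.matrix
    terms = list(design.terms)
    positions = {c: i for i, c in enumerate(Xfull.columns)}
    while terms:
        X = Xfull[["intercept"] + terms].to_numpy(dtype=float)
        beta, pvals, sse = _ols(X, y)
        term_p = dict(zip(terms, pvals[1:]))
        droppable = [c for c in terms if not (term_p[c] <= alpha_in)]
        if not droppable:
            break
        worst = max(
            droppable,
            key=lambda c: (
                term_p[c] if np.isfinite(term_p[c]) else np.inf,
                design.term_order.get(c, 0),
                positions[c],
            ),
        )
        terms.remove(worst)
    X = Xfull[["intercept"] + terms].to_numpy(dtype=float)
    beta, _, sse = _ols(X, y)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if (sst <= 0.0 or not terms) else max(0.0, 1.0 - sse / sst)
    coef = pd.Series(beta, index=["intercept"] + terms)
    return terms, coef, float(r2)


def select_time_genes(fits: pd.DataFrame, r2_cutoff: float = 0.6,
                      q_cutoff: float = 0.05) -> dict:
    """Per-compound sets of genes passing both gates and a non-empty model."""
    out = {}
    for compound, grp in fits.groupby("compound", sort=False):
        mask = (
            (grp["q_bh"] < q_cutoff)
            & (grp["r_squared"] >= r2_cutoff)
            & (grp["selected_terms"].astype(str).str.len() > 0)
        )
        out[compound] = set(grp.loc[mask.fillna(False), "gene"])
    return out


def exclude_genes(gene_set, exclusion_list) -> set:
    """Set difference against an exclusion list (e.g. cell-cycle genes)."""
    return set(gene_set) - set(exclusion_list)


def read_exclusion_list(path) -> set:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def run_timeseries(study: ExpressionStudy, compounds=None, degree: int = 2,
                   q_cutoff: float = 0.05, r2_cutoff: float = 0.6,
                   alpha_stepwise: float = 0.05):
    """The full temporal-selection stage.

    Per compound: global F-test for every gene, BH correction across the
    compound's genes, backward stepwise refinement of the BH-passing
    candidates, R^2 gate on the selected model.  Genes not reaching the
    stepwise stage keep NaN r_squared and passes=False.

    Compounds whose sampling cannot support the design (fewer distinct
    time points than degree+1) are skipped and reported, not errored.

    Returns
    -------
    (fits, skipped)
        fits : DataFrame with :data:`FIT_COLUMNS`; skipped : list of
        (compound, reason) pairs.
    """
    if compounds is None:
        compounds = study.steatotic_compounds
    genes = study.values.index.to_numpy()
    frames, skipped = [], []
    for compound in compounds:
        sub = study.samples[study.samples["compound"] == compound]
        try:
            design = build_time_design(sub, degree=degree, dose_levels=study.dose_levels)
        except DesignError as exc:
            skipped.append((compound, str(exc)))
            logger.info("timeseries: skipping %s (%s)", compound, exc)
            continue
        X = design.matrix.to_numpy(dtype=float)
        Y = study.values[sub["sample_id"].tolist()].to_numpy(dtype=float)
        p_global, _ = global_fits(Y, X)
        q = fdr_bh(p_global)
        sel_terms = np.full(len(genes), "", dtype=object)
        r2 = np.full(len(genes), np.nan)
        for i in np.flatnonzero(q < q_cutoff):
            terms, _, r2_i = backward_stepwise(Y[i], design, alpha_in=alpha_stepwise)
            sel_terms[i] = ";".join(terms)
            r2[i] = r2_i
        passes = (q < q_cutoff) & (np.nan_to_num(r2, nan=-1.0) >= r2_cutoff) \
            & (np.char.str_len(sel_terms.astype(str)) > 0)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "compound": compound,
                    "p_global": p_global,
                    "q_bh": q,
                    "selected_terms": sel_terms,
                    "r_squared": r2,
                    "passes": passes,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=FIT_COLUMNS), skipped
    return pd.concat(frames, ignore_index=True), skipped
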