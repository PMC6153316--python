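"""Synthetic toxicogenomics studies with known ground truth.

The generator emulates the design of a primary-human-hepatocyte compound
screen: each compound is profiled on a dose × time grid (three dose levels
plus matched vehicle controls; 2, 8 and 24 h) with two replicates per cell,
array-level batch effects and Gaussian measurement noise, all on the log2
scale of RMA-summarised intensities.  A subset of *steatotic* compounds
perturbs planted dose- and time-responsive genes with pathway-coherent
directions; *negative-control* compounds perturb only a disjoint set of
confounder genes (which the steatotic compounds hit as well), so that the
negative-control subtraction filter downstream has real work to do.

The generative model for the log2 value of gene g in sample s is::

    y[g, s] = baseline[g] + batch_shift[batch(s)] + effect[g, s] + noise[g, s]

with, for a responsive gene under a perturbing compound,

    effect = amplitude * direction * f(time) * g(dose)

where ``f(t) = u(t) ** degree`` on the unit-scaled time
``u = (t - t_min) / (t_max - t_min)`` (degree 1 or 2 per gene, matching the
quadratic regression the three-timepoint design supports downstream) and
``g(dose)`` maps dose rank onto {0, 1/3, 2/3, 1} — a unitless monotone dose
surrogate, since real doses are compound-specific.  Compounds planted in the
same class share the per-gene direction pattern, which is what the compound
clustering stage is meant to recover.  The batch shift is a scalar per array
batch (one batch per (compound, time) pair) shared across genes, the kind of
technical offset that concerted quantile normalization removes.

All randomness flows from one root seed through named substreams, so each
component (baseline, effects, membership, batch, noise) is independently
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genesets import GeneSetCollection, write_gmt
from .study import CONTROL, DEFAULT_DOSE_LEVELS, ExpressionStudy, dose_fraction, write_study

_SUBSTREAMS = ("baseline", "effects", "membership", "batch", "noise")


@dataclass
class SimConfig:
    """Generator configuration.  Defaults are a desk-scale rendition of the
    screen design: full dose × time grids with duplicate arrays, log2-scale
    effects of 2.0 against noise of 0.25 sd and batch shifts of 0.3 sd."""

    n_genes: int = 2000
    n_steatotic_compounds: int = 8
    n_negative_controls: int = 3
    times: tuple = (2.0, 8.0, 24.0)
    dose_levels: tuple = DEFAULT_DOSE_LEVELS
    n_replicates: int = 2
    n_response_genes: int = 150
    n_confounder_genes: int = 60
    n_gene_sets: int = 30
    set_size_range: tuple = (15, 50)
    enriched_set_fraction: float = 0.2
    effect_size: float = 2.0
    batch_sd: float = 0.3
    noise_sd: float = 0.25
    n_compound_clusters: int = 2
    seed: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    def validate(self) -> "SimConfig":
        for name in ("n_genes", "n_steatotic_compounds", "n_replicates",
                     "n_gene_sets", "n_compound_clusters"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count, got {getattr(self, name)}")
        for name in ("n_negative_controls", "n_response_genes", "n_confounder_genes"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        times = [float(t) for t in self.times]
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError(f"times must be >=2 strictly increasing values, got {self.times}")
        if len(self.dose_levels) < 2 or self.dose_levels[0] != CONTROL:
            raise ConfigError(
                f"dose_levels must start with '{CONTROL}' and contain >=1 treated level, "
                f"got {self.dose_levels}"
            )
        if self.n_response_genes + self.n_confounder_genes > self.n_genes:
            raise ConfigError(
                "n_response_genes + n_confounder_genes exceeds n_genes "
                f"({self.n_response_genes} + {self.n_confounder_genes} > {self.n_genes})"
            )
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"set_size_range must satisfy 1 <= min <= max, got {self.set_size_range}")
        if not 0.0 <= self.enriched_set_fraction <= 1.0:
            raise ConfigError(f"enriched_set_fraction must be in [0,1], got {self.enriched_set_fraction}")
        for name in ("effect_size", "batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_compound_clusters > self.n_steatotic_compounds:
            raise ConfigError(
                "n_compound_clusters cannot exceed n_steatotic_compounds "
                f"({self.n_compound_clusters} > {self.n_steatotic_compounds})"
            )
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["times"] = list(self.times)
        d["dose_levels"] = list(self.dose_levels)
        d["set_size_range"] = list(self.set_size_range)
        return d


@dataclass
class SimTruth:
    """Ground truth of a generated study.

    ``response_genes`` maps gene id -> {degree, amplitude, coherent,
    direction: {cluster index (str) -> +-1}}; ``confounder_genes`` maps gene
    id -> {degree, amplitude, direction}; ``enriched_sets`` lists set names
    with a planted coherent effect; ``compound_clusters`` maps steatotic
    compound -> planted class index.
    """

    response_genes: dict = field(default_factory=dict)
    confounder_genes: dict = field(default_factory=dict)
    enriched_sets: list = field(default_factory=list)
    compound_clusters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def _substreams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_SUBSTREAMS, children)}


def generate_study(config: SimConfig):
    """Generate a study with planted structure.

    Returns
    -------
    (ExpressionStudy, SimTruth, GeneSetCollection)
        The expression study (validated), its ground truth, and the gene-set
        collection whose enriched members carry the planted coherent effect.
    """
    cfg = config.validate()
    rng = _substreams(cfg.seed)

    width = max(5, len(str(cfg.n_genes)))
    genes = np.array([f"G{i:0{width}d}" for i in range(cfg.n_genes)])
    steatotic = [f"ST{i + 1:02d}" for i in range(cfg.n_steatotic_compounds)]
    negatives = [f"NC{i + 1:02d}" for i in range(cfg.n_negative_controls)]
    clusters = {c: i % cfg.n_compound_clusters for i, c in enumerate(steatotic)}

    # --- membership: disjoint response / confounder index sets -------------
    perm = rng["membership"].permutation(cfg.n_genes)
    resp_idx = np.sort(perm[: cfg.n_response_genes])
    conf_idx = np.sort(perm[cfg.n_response_genes: cfg.n_response_genes + cfg.n_confounder_genes])
    background_idx = np.setdiff1d(np.arange(cfg.n_genes), np.union1d(resp_idx, conf_idx))

    # coherent pool: response genes whose direction is +1 for every compound
    # class; enriched gene sets are drawn from it so their mean fold change
    # is positive and grows with dose and time
    n_coherent = cfg.n_response_genes // 2
    coherent_idx = resp_idx[:n_coherent]
    coherent = set(coherent_idx.tolist())

    # --- per-gene response shapes ------------------------------------------
    eff = rng["effects"]
    degrees = eff.integers(1, 3, size=cfg.n_response_genes)  # 1 or 2
    directions = np.where(
        eff.random((cfg.n_compound_clusters, cfg.n_response_genes)) < 0.5, -1, 1
    )
    for j, gidx in enumerate(resp_idx):
        if gidx in coherent:
            directions[:, j] = 1
    conf_degrees = eff.integers(1, 3, size=cfg.n_confounder_genes)
    conf_directions = np.where(eff.random(cfg.n_confounder_genes) < 0.5, -1, 1)

    truth = SimTruth(compound_clusters=dict(clusters))
    for j, gidx in enumerate(resp_idx):
        truth.response_genes[genes[gidx]] = {
            "degree": int(degrees[j]),
            "amplitude": float(cfg.effect_size),
            "coherent": bool(gidx in coherent),
            "direction": {str(c): int(directions[c, j]) for c in range(cfg.n_compound_clusters)},
        }
    for j, gidx in enumerate(conf_idx):
        truth.confounder_genes[genes[gidx]] = {
            "degree": int(conf_degrees[j]),
            "amplitude": float(cfg.effect_size),
            "direction": int(conf_directions[j]),
        }

    # --- gene sets ----------------------------------------------------------
    collection = GeneSetCollection()
    n_enriched = int(round(cfg.enriched_set_fraction * cfg.n_gene_sets))
    lo, hi = cfg.set_size_range
    if n_enriched > 0 and len(coherent_idx) < hi:
        raise ConfigError(
            "n_response_genes too small for the requested enriched sets: the "
            f"coherent pool has {len(coherent_idx)} genes but set_size_range "
            f"max is {hi}"
        )
    mem = rng["membership"]
    set_width = max(3, len(str(cfg.n_gene_sets)))
    for k in range(cfg.n_gene_sets):
        name = f"SET{k + 1:0{set_width}d}"
        size = int(mem.integers(lo, hi + 1))
        if k < n_enriched:
            n_core = max(1, math.ceil(0.8 * size))
            core = mem.choice(coherent_idx, size=min(n_core, len(coherent_idx)), replace=False)
            n_pad = size - len(core)
            pad = mem.choice(background_idx, size=n_pad, replace=False) if n_pad else np.array([], dtype=int)
            members = np.concatenate([core, pad])
            truth.enriched_sets.append(name)
            desc = "planted_enriched"
        else:
            members = mem.choice(cfg.n_genes, size=size, replace=False)
            desc = "background"
        collection.add(name, sorted(genes[np.sort(members)].tolist()), desc)

    # --- sample table -------------------------------------------------------
    dfrac = dose_fraction(cfg.dose_levels)
    times = [float(t) for t in cfg.times]
    u = {t: (t - times[0]) / (times[-1] - times[0]) for t in times}
    rows = []
    for compound in steatotic + negatives:
        for t in times:
            batch = f"{compound}_{t:g}h"
            for dose in cfg.dose_levels:
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{compound}_{dose}_{t:g}h_r{rep}",
                            "compound": compound,
                            "dose_level": dose,
                            "time_h": t,
                            "replicate": rep,
                            "batch": batch,
                            "is_negative_control": compound in set(negatives),
                        }
                    )
    samples = pd.DataFrame(rows)
    n_samples = len(samples)

    # --- assemble the matrix -------------------------------------------------
    baseline = rng["baseline"].normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    batches = list(dict.fromkeys(samples["batch"]))
    batch_shift = dict(zip(batches, rng["batch"].normal(0.0, cfg.batch_sd, size=len(batches))))
    noise = rng["noise"].normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples)) if cfg.noise_sd > 0 else 0.0

    values = np.tile(baseline[:, None], (1, n_samples))
    # per-compound effect profile over (time, dose); vectorised over genes
    resp_f = {t: u[t] ** degrees for t in times}      # (n_response,)
    conf_f = {t: u[t] ** conf_degrees for t in times}
    for s_i, row in enumerate(samples.itertuples()):
        values[:, s_i] += batch_shift[row.batch]
        g_dose = dfrac[row.dose_level]
        if g_dose == 0.0:
            continue
        if row.compound in clusters:  # steatotic
            cl = clusters[row.compound]
            values[resp_idx, s_i] += cfg.effect_size * directions[cl] * resp_f[row.time_h] * g_dose
        values[conf_idx, s_i] += cfg.effect_size * conf_directions * conf_f[row.time_h] * g_dose
    values = values + noise

    study = ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples["sample_id"].tolist()),
        samples=samples,
        dose_levels=cfg.dose_levels,
    ).validate()
    return study, truth, collection


def write_simulation(study, truth, collection, dir_path) -> Path:
    """Write the full simulated bundle: study files plus truth.json and sets.gmt."""
    d = write_study(study, dir_path)
    (d / "truth.json").write_text(truth.to_json() + "\n")
    write_gmt(collection, d / "sets.gmt")
    return d


def read_truth(dir_path) -> SimTruth:
    return SimTruth.from_json((Path(dir_path) / "truth.json").read_text())
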