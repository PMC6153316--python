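"""End-to-end orchestration with a YAML-configurable, reproducible run layout.

A run takes (or simulates) a study directory, then executes normalization,
differential expression, temporal selection, pathway scoring and compound
clustering, writing each stage's tables under the output directory together
with a manifest (config hash, seed, package versions) sufficient to
reproduce the run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import build_features, cluster_compounds, to_newick
from .deg import DegConfig, run_deg
from .errors import ConfigError
from .genesets import read_gmt, write_gmt
from .pathway import gfe_trajectories, page_table, rank_pathways
from .preprocess import average_replicates, compute_fold_changes, quantile_normalize
from .simulate import SimConfig, generate_study, read_truth, write_simulation
from .study import read_study
from .timeseries import exclude_genes, read_exclusion_list, run_timeseries, select_time_genes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full-run configuration with working defaults for a simulated study."""

    seed: int = 0
    study_dir: str | None = None       # None -> simulate
    gmt: str | None = None             # None -> the simulated sets.gmt
    exclusion_list: str | None = None
    simulate: dict = field(default_factory=dict)
    deg: dict = field(default_factory=dict)
    timeseries: dict = field(default_factory=lambda: {
        "degree": 2, "q_cutoff": 0.05, "r2_cutoff": 0.6, "alpha_stepwise": 0.05,
    })
    pathway: dict = field(default_factory=lambda: {
        "stat": "mean_fc", "p_threshold": 0.05,
    })
    clustering: dict = field(default_factory=lambda: {
        "time_filter": [24], "k_range": [1, 10], "min_timepoints": 2,
        "genes": "deg_union", "k_override": None,
    })

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        known = set(asdict(cfg))
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _write_gene_list(genes, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def run_all(config: PipelineConfig, out_dir, plots: bool = False) -> dict:
    """Execute every stage; returns a dict of in-memory results.

    Writes, under *out_dir*: ``study/`` (when simulated), ``fold_changes.tsv``,
    ``deg/``, ``timeseries/``, ``pathway/``, ``cluster/``, and
    ``manifest.json``.  Rerunning with an identical config reproduces
    identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- study ---------------------------------------------------------------
    if config.study_dir is None:
        sim_cfg = SimConfig(**{**config.simulate, "seed": int(config.simulate.get("seed", config.seed))})
        study, truth, collection = generate_study(sim_cfg)
        write_simulation(study, truth, collection, out / "study")
        logger.info("simulated study: %d genes, %d samples", len(study.gene_ids), len(study.samples))
    else:
        study = read_study(config.study_dir)
        truth = None
        collection = None
        gmt_path = config.gmt or str(Path(config.study_dir) / "sets.gmt")
        collection = read_gmt(gmt_path)
    if config.gmt is not None:
        collection = read_gmt(config.gmt)

    # --- preprocess ----------------------------------------------------------
    normalized = quantile_normalize(study)
    averaged = average_replicates(normalized)
    fold_changes = compute_fold_changes(averaged)
    _write_table(fold_changes, out / "fold_changes.tsv")

    # --- differential expression --------------------------------------------
    deg_cfg = DegConfig(**config.deg)
    deg_res = run_deg(normalized, deg_cfg)
    _write_table(deg_res.table, out / "deg" / "deg_table.tsv")
    _write_table(deg_res.negative_table, out / "deg" / "negative_table.tsv")
    _write_gene_list(deg_res.union_genes, out / "deg" / "union_genes.txt")
    _write_gene_list(deg_res.negative_genes, out / "deg" / "negative_flagged.txt")
    _write_gene_list(deg_res.final_genes, out / "deg" / "final_genes.txt")
    logger.info("deg: %d flagged, %d after negative-control subtraction",
                len(deg_res.union_genes), len(deg_res.final_genes))

    # --- timeseries ----------------------------------------------------------
    ts_kwargs = dict(config.timeseries)
    exclusion = set()
    if config.exclusion_list:
        exclusion = read_exclusion_list(config.exclusion_list)
    fits, skipped = run_timeseries(
        normalized,
        degree=int(ts_kwargs.get("degree", 2)),
        q_cutoff=float(ts_kwargs.get("q_cutoff", 0.05)),
        r2_cutoff=float(ts_kwargs.get("r2_cutoff", 0.6)),
        alpha_stepwise=float(ts_kwargs.get("alpha_stepwise", 0.05)),
    )
    _write_table(fits, out / "timeseries" / "fits.tsv")
    selected = select_time_genes(fits, r2_cutoff=float(ts_kwargs.get("r2_cutoff", 0.6)),
                                 q_cutoff=float(ts_kwargs.get("q_cutoff", 0.05)))
    selected = {c: exclude_genes(g, exclusion) for c, g in selected.items()}
    sel_rows = [(c, g) for c in selected for g in sorted(selected[c])]
    _write_table(pd.DataFrame(sel_rows, columns=["compound", "gene"]),
                 out / "timeseries" / "selected_genes.tsv")
    if skipped:
        _write_table(pd.DataFrame(skipped, columns=["compound", "reason"]),
                     out / "timeseries" / "skipped_compounds.tsv")

    # --- clustering (before pathway so cluster trajectories can use labels) --
    cl_kwargs = dict(config.clustering)
    gene_filter = None
    if cl_kwargs.get("genes") == "deg_union" and deg_res.final_genes:
        gene_filter = deg_res.final_genes
    features = build_features(
        fold_changes[fold_changes["compound"].isin(set(study.steatotic_compounds))],
        time_filter=cl_kwargs.get("time_filter"),
        genes=gene_filter,
        min_timepoints=int(cl_kwargs.get("min_timepoints", 2)),
        dose_levels=study.dose_levels,
    )
    solution = cluster_compounds(
        features,
        k_range=tuple(cl_kwargs.get("k_range", (1, 10))),
        k_override=cl_kwargs.get("k_override"),
    )
    _write_table(
        pd.DataFrame(solution.merges, columns=["id_a", "id_b", "height", "size"]),
        out / "cluster" / "linkage.tsv",
    )
    _write_table(
        pd.DataFrame(sorted(solution.labels.items()), columns=["compound", "cluster"]),
        out / "cluster" / "labels.tsv",
    )
    _write_table(
        pd.DataFrame(sorted(solution.ser_by_k.items()), columns=["k", "ser"]),
        out / "cluster" / "ser.tsv",
    )
    (out / "cluster" / "dendrogram.nwk").write_text(
        to_newick(solution.merges, solution.compounds) + "\n"
    )
    logger.info("clustering: chose k=%d over %d compounds", solution.chosen_k, len(solution.compounds))

    # --- pathway -------------------------------------------------------------
    pw_kwargs = dict(config.pathway)
    ste_fc = fold_changes[fold_changes["compound"].isin(set(study.steatotic_compounds))]
    page = page_table(ste_fc, collection, dose_levels=study.dose_levels)
    _write_table(page, out / "pathway" / "page.tsv")
    top = rank_pathways(page, p_threshold=float(pw_kwargs.get("p_threshold", 0.05)))
    _write_table(top, out / "pathway" / "top_pathways.tsv")
    traj_c = gfe_trajectories(deg_res.table, ste_fc, collection, grouping="compound",
                              stat=pw_kwargs.get("stat", "mean_fc"),
                              dose_levels=study.dose_levels)
    _write_table(traj_c, out / "pathway" / "gfe_compound.tsv")
    traj_k = gfe_trajectories(deg_res.table, ste_fc, collection, grouping="cluster",
                              cluster_labels=solution.labels,
                              stat=pw_kwargs.get("stat", "mean_fc"),
                              dose_levels=study.dose_levels)
    _write_table(traj_k, out / "pathway" / "gfe_cluster.tsv")

    # --- figures -------------------------------------------------------------
    if plots:
        import matplotlib.pyplot as plt
        from .plots import plot_dendrogram, plot_gfe_trajectories

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        ax = plot_dendrogram(solution)
        ax.figure.savefig(figdir / "dendrogram.png", dpi=120)
        plt.close(ax.figure)
        for set_name in list(dict.fromkeys(top["set"]))[:3]:
            group = traj_c["group"].iloc[0]
            fig = plot_gfe_trajectories(traj_c, set_name, group, dose_levels=study.dose_levels)
            fig.savefig(figdir / f"gfe_{set_name}_{group}.png", dpi=120)
            plt.close(fig)

    # --- manifest ------------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": int(config.seed),
        "versions": {
            "toxtempo": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {
        "study": study,
        "truth": truth,
        "collection": collection,
        "fold_changes": fold_changes,
        "deg": deg_res,
        "timeseries": (fits, skipped, selected),
        "clustering": solution,
        "page": page,
        "gfe_compound": traj_c,
        "gfe_cluster": traj_k,
    }
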