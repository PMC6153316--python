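"""The expression-study container and its on-disk layout.

An :class:`ExpressionStudy` is the universal input of the pipeline: a genes ×
samples matrix of log2 intensities plus a per-sample design table (compound,
dose level, exposure time, replicate, batch, negative-control flag).  The
design mirrors a primary-hepatocyte toxicogenomics screen: every treated
(compound, dose, time) cell has a matched vehicle control sharing the same
compound, time and batch.

A study directory holds two tab-delimited files::

    matrix.tsv    genes × samples, header row = sample ids, index = gene ids
    samples.tsv   one row per sample with the design metadata

plus, for simulated studies, ``truth.json`` and ``sets.gmt`` (see
:mod:`toxtempo.simulate` and :mod:`toxtempo.genesets`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StudyError, StudyFormatError

CONTROL = "control"
DEFAULT_DOSE_LEVELS = ("control", "low", "middle", "high")

SAMPLE_COLUMNS = [
    "sample_id",
    "compound",
    "dose_level",
    "time_h",
    "replicate",
    "batch",
    "is_negative_control",
]


def dose_rank(dose_levels=DEFAULT_DOSE_LEVELS) -> dict:
    """Map dose labels to their 0-based rank (control first)."""
    return {d: i for i, d in enumerate(dose_levels)}


def dose_fraction(dose_levels=DEFAULT_DOSE_LEVELS) -> dict:
    """Unitless monotone dose surrogate: rank mapped onto [0, 1].

    For the canonical four levels this is {control: 0, low: 1/3,
    middle: 2/3, high: 1}; real doses are compound-specific and are not
    modelled.
    """
    top = len(dose_levels) - 1
    return {d: i / top for i, d in enumerate(dose_levels)}


@dataclass
class ExpressionStudy:
    """Log2 expression values plus per-sample design metadata.

    Parameters
    ----------
    values
        genes × samples DataFrame of log2 intensities; columns must equal
        ``samples["sample_id"]`` in order.
    samples
        Design table with :data:`SAMPLE_COLUMNS`.
    dose_levels
        Ordered dose labels, control first.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    dose_levels: tuple = DEFAULT_DOSE_LEVELS

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def compounds(self) -> list:
        """Compounds in order of first appearance in the sample table."""
        return list(dict.fromkeys(self.samples["compound"]))

    @property
    def steatotic_compounds(self) -> list:
        s = self.samples
        return list(dict.fromkeys(s.loc[~s["is_negative_control"], "compound"]))

    @property
    def negative_control_compounds(self) -> list:
        s = self.samples
        return list(dict.fromkeys(s.loc[s["is_negative_control"], "compound"]))

    def validate(self) -> "ExpressionStudy":
        """Check structural invariants; raise :class:`StudyError` on failure."""
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise StudyError(f"sample table is missing columns: {missing}")
        ids = list(self.samples["sample_id"])
        if len(set(ids)) != len(ids):
            raise StudyError("duplicate sample_id in sample table")
        if list(self.values.columns) != ids:
            extra = set(self.values.columns) - set(ids)
            lacking = set(ids) - set(self.values.columns)
            raise StudyError(
                "matrix columns do not match sample table: "
                f"missing from matrix {sorted(lacking)}, "
                f"unknown in matrix {sorted(extra)}"
            )
        if self.values.isna().any().any():
            raise StudyError("expression matrix contains missing values")
        bad_dose = set(self.samples["dose_level"]) - set(self.dose_levels)
        if bad_dose:
            raise StudyError(f"unknown dose levels: {sorted(bad_dose)}")
        # every treated cell needs a matched vehicle control (same compound,
        # time and batch)
        s = self.samples
        controls = {
            (r.compound, r.time_h, r.batch)
            for r in s[s["dose_level"] == CONTROL].itertuples()
        }
        for r in s[s["dose_level"] != CONTROL].itertuples():
            if (r.compound, r.time_h, r.batch) not in controls:
                raise StudyError(
                    "treated condition without matched control: "
                    f"compound={r.compound} dose={r.dose_level} time={r.time_h}"
                )
        return self

    def subset_samples(self, mask) -> "ExpressionStudy":
        sub = self.samples.loc[mask].reset_index(drop=True)
        return ExpressionStudy(
            values=self.values[list(sub["sample_id"])],
            samples=sub,
            dose_levels=self.dose_levels,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.samples.reset_index(drop=True).equals(
                other.samples.reset_index(drop=True)
            )
            and tuple(self.dose_levels) == tuple(other.dose_levels)
        )


def write_study(study: ExpressionStudy, dir_path) -> Path:
    """Write ``matrix.tsv`` and ``samples.tsv`` into *dir_path* (created if
    needed).  Values round-trip at full precision."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    m = study.values.copy()
    m.index.name = "gene"
    # %.17g guarantees float64 values survive the text round trip exactly
    m.to_csv(d / "matrix.tsv", sep="\t", float_format="%.17g")
    study.samples[SAMPLE_COLUMNS].to_csv(d / "samples.tsv", sep="\t", index=False)
    return d


def read_study(dir_path, dose_levels=DEFAULT_DOSE_LEVELS) -> ExpressionStudy:
    """Read a study directory written by :func:`write_study`.

    Raises
    ------
    StudyFormatError
        If the directory lacks the study files or the metadata table is
        malformed (the message names the row).
    """
    d = Path(dir_path)
    matrix_path = d / "matrix.tsv"
    samples_path = d / "samples.tsv"
    if not matrix_path.is_file() or not samples_path.is_file():
        raise StudyFormatError(f"{d} is not a study directory")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    values.index.name = None
    samples = pd.read_csv(samples_path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise StudyFormatError(f"{samples_path}: missing columns {missing}")
    for col, caster in [("time_h", float), ("replicate", int)]:
        coerced = pd.to_numeric(samples[col], errors="coerce")
        bad = coerced.isna()
        if bool(bad.any()):
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is row 1
            raise StudyFormatError(
                f"{samples_path}: row {row}: cannot parse {col}="
                f"{samples[col].iloc[row - 2]!r}"
            )
        samples[col] = coerced.astype(caster)
    flag = samples["is_negative_control"]
    if flag.dtype != bool:
        mapping = {"True": True, "False": False, "true": True, "false": False,
                   "1": True, "0": False, 1: True, 0: False}
        mapped = flag.map(mapping)
        if bool(mapped.isna().any()):
            row = int(np.flatnonzero(mapped.isna().to_numpy())[0]) + 2
            raise StudyFormatError(
                f"{samples_path}: row {row}: cannot parse is_negative_control="
                f"{flag.iloc[row - 2]!r}"
            )
        samples["is_negative_control"] = mapped.astype(bool)
    study = ExpressionStudy(values=values, samples=samples, dose_levels=dose_levels)
    try:
        study.validate()
    except StudyError as exc:
        raise StudyFormatError(f"{d}: {exc}") from exc
    return study
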