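"""Domain types, readers/writers and validation for the pipeline's tables.

The pipeline moves four kinds of tabular data around: raw miRNA read-count
matrices (genes x samples), sample sheets (batch / disease-group /
timepoint labels), long-format qRT-PCR Ct tables (one row per technical
replicate), and result tables (stability rankings, statistical test
reports).  Everything is plain TSV/CSV on disk and thin dataclass wrappers
around pandas objects in memory, validated eagerly so malformed inputs
fail at the boundary with a message naming the offending rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("exoref")

#: Sentinels accepted (case-insensitively) for an undetermined Ct value.
UNDETERMINED_SENTINELS = {"undetermined", "na", "nan", ""}

DEFAULT_MAX_CYCLES = 40


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw miRNA read counts, genes in rows, samples in columns.

    ``counts`` is an integer DataFrame indexed by gene id with sample ids
    as columns.  All entries must be nonnegative integers and both axes
    must carry unique labels.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        dup_g = _duplicates(df.index)
        if dup_g:
            raise ValidationError(f"duplicate gene ids: {dup_g}")
        dup_s = _duplicates(df.columns)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            bad = np.argwhere((frac != 0) | ~np.isfinite(arr.astype(float)))
            if bad.size:
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {df.index[g]!r}, "
                    f"sample {df.columns[s]!r}"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
        if arr.size and (arr.astype(np.int64) < 0).any():
            bad = np.argwhere(arr.astype(np.int64) < 0)
            g, s = bad[0]
            raise ValidationError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_count_matrix(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample count table (first column = gene id)."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    cm.counts.to_csv(path, sep=sep, index_label="mirna")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Per-sample batch, disease-group and timepoint labels.

    ``table`` is indexed by sample_id with columns ``batch``, ``group`` and
    ``timepoint`` (``none`` when the study has no longitudinal arm).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        dup = _duplicates(df.index)
        if dup:
            raise ValidationError(f"duplicate sample ids in sheet: {dup}")
        for col in ("batch", "group"):
            if col not in df.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
            empty = df.index[df[col].astype(str).str.len() == 0]
            if len(empty):
                raise ValidationError(f"empty {col} label for samples {list(empty)}")
        if "timepoint" not in df.columns:
            df = df.assign(timepoint="none")
            object.__setattr__(self, "table", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def require_samples(self, sample_ids: Sequence[str]) -> None:
        """Strict join: every data sample must appear in the sheet."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(
                f"samples absent from sample sheet: {missing}"
            )

    def batch_of(self, sample_ids: Sequence[str]) -> pd.Series:
        self.require_samples(sample_ids)
        return self.table.loc[list(sample_ids), "batch"]

    def group_of(self, sample_ids: Sequence[str]) -> pd.Series:
        self.require_samples(sample_ids)
        return self.table.loc[list(sample_ids), "group"]


def read_sample_sheet(path: str | Path, dialect: str = "tsv") -> SampleSheet:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Abundance matrix (log2 normalized counts)
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """log2 normalized (optionally batch-corrected) abundances."""

    values: pd.DataFrame
    pseudocount: float = 1.0
    normalized: bool = True
    batch_corrected: bool = False

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if _duplicates(self.values.index) or _duplicates(self.values.columns):
            raise ValidationError("duplicate ids in abundance matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Stability table
# ---------------------------------------------------------------------------

STABILITY_COLUMNS = ["mirna", "mean_abundance", "cv_percent", "z_score", "rank"]


@dataclass
class StabilityTable:
    """Per-miRNA mean log2 abundance, CV (%), modified Z-score and rank."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in STABILITY_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"stability table missing columns {missing}")
        ranks = df["rank"].to_numpy()
        n = len(df)
        if n and sorted(ranks) != list(range(1, n + 1)):
            raise ValidationError("ranks are not a dense permutation 1..n")
        if n and not np.isfinite(df["cv_percent"].to_numpy()).all():
            raise ValidationError("non-finite CV in stability table")

    def __len__(self) -> int:
        return len(self.table)


def write_stability_table(stab: StabilityTable, path: str | Path) -> None:
    out = stab.table.loc[:, STABILITY_COLUMNS].sort_values("rank")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_stability_table(path: str | Path) -> StabilityTable:
    df = pd.read_csv(path, sep="\t")
    return StabilityTable(df)


# ---------------------------------------------------------------------------
# Ct table
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format replicate-level qRT-PCR records.

    ``records`` has columns ``sample_id``, ``target``, ``replicate`` and
    ``ct``; an undetermined reaction (no amplification within
    ``max_cycles`` cycles) is stored as NaN, never coerced to a number.
    """

    records: pd.DataFrame
    max_cycles: int = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        df = self.records
        needed = ["sample_id", "target", "replicate", "ct"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns {missing}")
        dup = df.duplicated(subset=["sample_id", "target", "replicate"])
        if dup.any():
            rows = df.loc[dup, ["sample_id", "target", "replicate"]]
            raise ValidationError(
                f"duplicate (sample, target, replicate) records:\n{rows.to_string(index=False)}"
            )
        ct = df["ct"].to_numpy(dtype=float)
        determined = ~np.isnan(ct)
        if (ct[determined] <= 0).any():
            raise ValidationError("Ct values must be positive PCR cycles")
        if (ct[determined] > self.max_cycles).any():
            bad = df.loc[determined & (df["ct"] > self.max_cycles)]
            raise ValidationError(
                f"Ct above max_cycles={self.max_cycles}:\n"
                f"{bad[['sample_id', 'target', 'ct']].to_string(index=False)}"
            )
        if (df["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample_id"]))

    @property
    def targets(self) -> list[str]:
        return list(pd.unique(self.records["target"]))

    def __len__(self) -> int:
        return len(self.records)


def _parse_ct(value: object) -> float:
    if isinstance(value, str) and value.strip().lower() in UNDETERMINED_SENTINELS:
        return math.nan
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    return float(value)


def read_ct_table(path: str | Path, max_cycles: int = DEFAULT_MAX_CYCLES,
                  dialect: str = "tsv") -> CtTable:
    """Read a long-format Ct table (columns sample, target, replicate, ct).

    ``Undetermined`` / ``NA`` / empty Ct cells become flagged-missing (NaN).
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"ct": str})
    rename = {c: c.lower() for c in df.columns}
    df = df.rename(columns=rename)
    if "sample" in df.columns and "sample_id" not in df.columns:
        df = df.rename(columns={"sample": "sample_id"})
    df["ct"] = [_parse_ct(v) for v in df["ct"]]
    df["replicate"] = df["replicate"].astype(int)
    df["sample_id"] = df["sample_id"].astype(str)
    df["target"] = df["target"].astype(str)
    return CtTable(df.reset_index(drop=True), max_cycles=max_cycles)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    df = ct.records.copy()
    out_ct = df["ct"].map(lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    df = df.assign(ct=out_ct)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Test reports
# ---------------------------------------------------------------------------

@dataclass
class TestReport:
    """Outcome of one statistical contrast."""

    __test__ = False  # keep pytest from collecting this dataclass

    contrast: str
    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    adjusted: bool = False
    significant: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        sig = bool(self.p_value <= self.alpha)
        if self.significant is None:
            self.significant = sig
        elif self.significant != sig:
            raise ValidationError("significance flag inconsistent with p and alpha")


REPORT_COLUMNS = ["contrast", "test_name", "statistic", "p_value",
                  "alpha", "adjusted", "significant"]


def reports_to_frame(reports: Sequence[TestReport]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in REPORT_COLUMNS} for r in reports]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(["contrast", "test_name"]).reset_index(drop=True)


def write_test_reports(reports: Sequence[TestReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_table(obj, path: str | Path) -> None:
    """Write a StabilityTable or a collection of TestReports as TSV."""
    if isinstance(obj, StabilityTable):
        write_stability_table(obj, path)
    else:
        write_test_reports(list(obj), path)


# ---------------------------------------------------------------------------
# Config file
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the single YAML config carrying all pipeline thresholds.

    Returns a plain dict; each pipeline stage picks the keys it knows
    (min_reads_per_sample, min_read_sum, min_detect_frac, pseudocount,
    top_n, exclude, add_external, alpha, spikein_target, spikein_window,
    min_replicates, ...).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return cfg
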