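"""Count-matrix ingestion, CPM normalization, expression pre-filtering and
per-timepoint log2 fold changes against the time-matched solvent control.

The central objects are :class:`CountMatrix` (non-negative integer gene ×
sample counts) and :class:`SampleSheet` (sample → treatment / timepoint /
replicate). Expression is normalized to counts per million mapped reads
(CPM); genes are pre-filtered on mean CPM within an experiment; treatment
effects are summarized as the log2 ratio of mean CPM between a treated arm
and its time-matched DMSO control arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("SB", "SU", "DMSO", "untreated")
#: treatments that denote an inhibitor arm (have a time-matched DMSO control)
TREATED = ("SB", "SU")


class ValidationError(ValueError):
    """Raised when input tables violate the expected layout or invariants."""


@dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Values must be non-negative integers (floats are accepted
        only when integral, as produced by some quantifiers' TSV exports).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise ValidationError("negative counts")
        if not np.all(np.mod(arr, 1) == 0):
            bad = df.columns[np.any(np.mod(arr, 1) != 0, axis=0)].tolist()
            raise ValidationError(f"counts must be integers (non-integral values in {bad[:5]})")
        self.counts = df.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample library size (column sum of counts)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.counts.shape
        return f"CountMatrix({g} genes x {s} samples)"


@dataclass
class SampleSheet:
    """Sample metadata: treatment arm, timepoint in hours, replicate index."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample", "treatment", "timepoint_h", "replicate")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        unknown = sorted(set(df["treatment"]) - set(TREATMENTS))
        if unknown:
            raise ValidationError(f"unknown treatment labels: {unknown}")
        if df["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        df = df.copy()
        df["timepoint_h"] = df["timepoint_h"].astype(int)
        self.table = df.set_index("sample", drop=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples(self, treatment: str | None = None, timepoint_h: int | None = None) -> list[str]:
        df = self.table
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        if timepoint_h is not None:
            df = df[df["timepoint_h"] == timepoint_h]
        return df.index.tolist()

    def timepoints(self, treatment: str) -> list[int]:
        return sorted(self.table.loc[self.table["treatment"] == treatment, "timepoint_h"].unique())

    def treated_arms(self) -> list[str]:
        return [t for t in TREATED if t in set(self.table["treatment"])]

    def validate_against(self, matrix: CountMatrix) -> None:
        """Require the count-matrix and sheet sample sets to coincide."""
        a, b = set(matrix.sample_ids), set(self.sample_ids)
        only_counts, only_sheet = sorted(a - b), sorted(b - a)
        if only_counts or only_sheet:
            raise ValidationError(
                f"sample sets differ: only in counts {only_counts}, only in sheet {only_sheet}"
            )

    def validate_design(self, treatment: str) -> None:
        """Check replication and control coverage for one inhibitor arm."""
        for t in self.timepoints(treatment):
            if len(self.samples(treatment, t)) < 2:
                raise ValidationError(f"<2 replicates for {treatment} at {t} h")
            if len(self.samples("DMSO", t)) < 2:
                raise ValidationError(f"missing/underreplicated DMSO control at {t} h for {treatment}")


def read_counts(path) -> CountMatrix:
    """Read a gene × sample count TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t"))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads; columns sum to 1e6 exactly."""
    libs = matrix.lib_sizes
    if (libs <= 0).any():
        zero = libs.index[libs <= 0].tolist()
        raise ValidationError(f"zero library size for samples {zero}")
    return matrix.counts / libs * 1e6


def experiment_samples(sheet: SampleSheet, treatment: str) -> list[str]:
    """All samples belonging to one inhibitor experiment: the treated arm,
    its time-matched DMSO controls, and the untreated anchors."""
    if treatment not in TREATED:
        raise ValidationError(f"treatment must be one of {TREATED}, got {treatment!r}")
    times = set(sheet.timepoints(treatment))
    out = sheet.samples(treatment)
    out += [s for s in sheet.samples("DMSO") if sheet.table.loc[s, "timepoint_h"] in times]
    out += sheet.samples("untreated")
    return out


def filter_low_expression(
    matrix: CountMatrix,
    sheet: SampleSheet | None = None,
    min_cpm: float = 1.0,
    treatment: str | None = None,
    mode: str = "mean",
) -> CountMatrix:
    """Drop genes below the expression floor.

    With ``treatment`` given, only that experiment's samples (treated arm +
    its DMSO controls + untreated anchors) enter the criterion, so the filter
    is computed per experiment. ``mode`` selects the reading of the floor:
    ``mean`` (default) keeps genes with mean CPM ≥ ``min_cpm`` across the
    selected samples; ``all`` requires every sample to reach it; ``any`` one.
    """
    if min_cpm < 0:
        raise ValidationError("min_cpm must be >= 0")
    x = cpm(matrix)
    if treatment is not None:
        if sheet is None:
            raise ValidationError("per-experiment filtering needs a sample sheet")
        x = x[experiment_samples(sheet, treatment)]
    if mode == "mean":
        keep = x.mean(axis=1) >= min_cpm
    elif mode == "all":
        keep = (x >= min_cpm).all(axis=1)
    elif mode == "any":
        keep = (x >= min_cpm).any(axis=1)
    else:
        raise ValidationError(f"unknown filter mode {mode!r}")
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return CountMatrix(matrix.counts.loc[keep])


def lfc_vs_control(
    matrix: CountMatrix,
    sheet: SampleSheet,
    treatment: str,
    pseudocount: float = 0.5,
    timepoints: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change of mean CPM, treated vs time-matched DMSO.

    lfc[g, t] = log2((mean CPM treated at t + pc) / (mean CPM DMSO at t + pc)),
    means taken over replicates. Returns a DataFrame indexed by gene with one
    integer column per timepoint (hours). Positive values mean higher
    expression under the inhibitor than under solvent.
    """
    if treatment not in TREATED:
        raise ValidationError(f"treatment must be one of {TREATED}, got {treatment!r}")
    sheet.validate_against(matrix)
    x = cpm(matrix)
    if timepoints is None:
        timepoints = [t for t in sheet.timepoints(treatment) if t != 0]
    out = {}
    for t in timepoints:
        trt = sheet.samples(treatment, t)
        ctl = sheet.samples("DMSO", t)
        if not trt:
            raise ValidationError(f"no {treatment} samples at {t} h")
        if not ctl:
            raise ValidationError(f"no DMSO control samples at {t} h")
        out[int(t)] = np.log2((x[trt].mean(axis=1) + pseudocount) / (x[ctl].mean(axis=1) + pseudocount))
    return pd.DataFrame(out, index=matrix.gene_ids)


def direction_table(lfc: pd.DataFrame, lam: float = 0.0) -> pd.DataFrame:
    """Per-timepoint direction labels: up/down where |lfc| ≥ lam, else none."""
    up = (lfc.abs() >= lam) & (lfc > 0)
    down = (lfc.abs() >= lam) & (lfc < 0)
    arr = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(arr, index=lfc.index, columns=lfc.columns)


def write_lfc(lfc: pd.DataFrame, path, lam: float = 0.0) -> None:
    """Write an LFC table as TSV with lfc_<t>h and direction_<t>h columns."""
    out = pd.DataFrame(index=lfc.index)
    dirs = direction_table(lfc, lam)
    for t in lfc.columns:
        out[f"lfc_{t}h"] = lfc[t]
        out[f"direction_{t}h"] = dirs[t]
    out.rename_axis("gene_id").to_csv(path, sep="\t")


def read_lfc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [c for c in df.columns if c.startswith("lfc_")]
    out = df[cols].copy()
    out.columns = [int(c.removeprefix("lfc_").removesuffix("h")) for c in cols]
    return out
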