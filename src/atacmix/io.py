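"""Readers and writers for the plain-text formats the pipeline exchanges.

BED (3+1 columns, 0-based half-open) for peak sets; TSV for count matrices
(peak_id + one column per sample), sample group tables, TSS tables and
result tables. Readers validate aggressively and report the offending line
or cell; writers round-trip losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, MixtureDesign, PeakSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_group_table",
    "write_group_table",
    "read_tss_table",
    "read_design",
    "write_design",
]

logger = logging.getLogger(__name__)


def read_bed(path) -> PeakSet:
    """Read a BED3+ file into a PeakSet.

    A fourth column, when present, supplies peak ids; otherwise ids
    peak_000001, ... are generated in file order. Input is sorted by
    (chrom, start) on read; unsorted input is flagged in the log.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
            records.append((chrom, start, end, name))
    if not records:
        raise ValueError(f"{path}: no BED records")
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "peak_id"])
    if df["peak_id"].isna().any():
        if df["peak_id"].notna().any():
            raise ValueError(f"{path}: mixture of named and unnamed records")
        df["peak_id"] = [f"peak_{i + 1:06d}" for i in range(len(df))]
    if df["peak_id"].duplicated().any():
        dup = df["peak_id"][df["peak_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate peak id {dup!r}")
    df = df.set_index("peak_id")
    sorted_df = df.sort_values(["chrom", "start"], kind="stable")
    if not sorted_df.index.equals(df.index):
        logger.info("%s: input not coordinate-sorted; sorting on read", path)
    return PeakSet(sorted_df)


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED4 (chrom, start, end, peak_id)."""
    df = peaks.df
    with open(path, "w") as fh:
        for pid, row in df.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{pid}\n")


def read_counts(path) -> CountMatrix:
    """Read a peak_id-indexed TSV of integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate peak_id {dup!r}")
    numeric = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            peak = df.index[converted.isna()][0]
            raise ValueError(f"{path}: non-numeric count at (peak {peak!r}, sample {col!r})")
        frac = converted % 1 != 0
        if frac.any():
            peak = df.index[frac][0]
            raise ValueError(f"{path}: non-integer count at (peak {peak!r}, sample {col!r})")
        if (converted < 0).any():
            peak = df.index[converted < 0][0]
            raise ValueError(f"{path}: negative count at (peak {peak!r}, sample {col!r})")
        numeric[col] = converted.astype(np.int64)
    return CountMatrix(pd.DataFrame(numeric, index=df.index))


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="peak_id")


def read_group_table(path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id and group")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "group"]
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id")["group"]


def write_group_table(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS table: gene_id, chrom, position, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "position", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: TSS table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    if (df["position"] < 0).any():
        raise ValueError(f"{path}: negative TSS position")
    return df.set_index("gene_id")


def read_design(path) -> MixtureDesign:
    """Read a true-proportion table (sample_id + one column per cell type)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MixtureDesign(df)


def write_design(design: MixtureDesign, path) -> None:
    design.proportions.to_csv(path, sep="\t", index_label="sample_id")
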