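"""Core data containers shared across the pipeline.

All tabular containers are thin, validated wrappers around pandas objects:
peaks index rows, samples index columns. Validation happens at construction
so downstream code can assume consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakSet",
    "CountMatrix",
    "NormalizedMatrix",
    "MixtureDesign",
    "SignatureMatrix",
    "DeconvolutionResult",
    "RecoveryStats",
]


@dataclass(frozen=True)
class PeakSet:
    """Consensus open-chromatin intervals with stable identifiers.

    ``df`` is indexed by unique peak id and has columns ``chrom``, ``start``,
    ``end`` in 0-based half-open coordinates, sorted by (chrom, start).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = {"chrom", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"PeakSet frame missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate peak ids: {dup}")
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        if (starts < 0).any():
            raise ValueError("negative peak start coordinate")
        if (starts >= ends).any():
            bad = df.index[starts >= ends][0]
            raise ValueError(f"peak {bad!r} has start >= end")
        ordered = df.sort_values(["chrom", "start"], kind="stable")
        if not ordered.index.equals(df.index):
            object.__setattr__(self, "df", ordered)

    @property
    def peak_ids(self) -> pd.Index:
        return self.df.index

    @property
    def lengths(self) -> pd.Series:
        """Peak widths in bp."""
        return self.df["end"] - self.df["start"]

    def __len__(self) -> int:
        return len(self.df)


def _check_count_frame(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if counts.index.has_duplicates:
        raise ValueError("duplicate peak ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix must be numeric")
    if (arr < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("count matrix contains non-integer entries")
    return counts.astype(np.int64)


@dataclass
class CountMatrix:
    """Peaks x samples matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = _check_count_frame(self.counts)

    @property
    def peak_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def effective_library_sizes(self) -> pd.Series:
        """Total reads in consensus peaks, per sample (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return CountMatrix(self.counts[list(sample_ids)].copy())


@dataclass
class NormalizedMatrix:
    """TMM-adjusted counts-per-million on the linear scale.

    value = 1e6 * count / (effective_library_size * tmm_factor)
    """

    values: pd.DataFrame
    tmm_factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.tmm_factors.index):
            raise ValueError("tmm_factors index does not match sample ids")
        if not self.values.columns.equals(self.library_sizes.index):
            raise ValueError("library_sizes index does not match sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be non-negative")

    @property
    def peak_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class MixtureDesign:
    """Known per-sample cell-type proportion vectors (samples x cell types)."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if (arr < 0).any():
            bad = self.proportions.index[(arr < 0).any(axis=1)][0]
            raise ValueError(f"sample {bad!r} has a negative proportion")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0.0):
            bad = self.proportions.index[np.abs(sums - 1.0) > 1e-12][0]
            raise ValueError(f"proportions of sample {bad!r} do not sum to 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.proportions.index

    @property
    def cell_types(self) -> pd.Index:
        return self.proportions.columns


@dataclass
class SignatureMatrix:
    """Signature peaks x cell types, median normalized accessibility.

    ``g`` is the per-type signature size chosen by condition-number
    minimization; ``kappa`` the 2-norm condition number of ``values``.
    """

    values: pd.DataFrame
    g: int
    kappa: float
    peak_cell_type: pd.Series = None  # signature peak -> favored cell type

    @property
    def peak_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    def peaks_for(self, cell_type: str) -> pd.Index:
        """Signature peaks whose accessibility favors ``cell_type``."""
        if self.peak_cell_type is None:
            raise ValueError("signature has no per-type peak assignment")
        return self.peak_cell_type.index[self.peak_cell_type == cell_type]


@dataclass
class DeconvolutionResult:
    """Estimated proportions per sample, with fit diagnostics."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    residuals: pd.Series  # 2-norm of S f - m at the NNLS solution
    truth: pd.DataFrame | None = None
    abs_error: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("negative estimated proportion")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9, rtol=0.0):
            raise ValueError("estimated proportions do not sum to 1")


@dataclass(frozen=True)
class RecoveryStats:
    """Agreement between estimated and true proportions, pooled over samples."""

    r: float
    rmse: float
    max_abs_error: pd.Series
    n: int
    degenerate: bool = False
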