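"""Effective-library-size + TMM normalization of peak count matrices.

Counts are scaled to counts-per-million of the TMM-effective library:
value = 1e6 * count / (library_size * tmm_factor), where library_size is the
total number of reads in consensus peaks and the TMM factor is the
trimmed-mean-of-M-values scaling factor of Robinson & Oshlack, computed with
the canonical parameters (30% two-sided trim on M, 5% on A, precision
weights, upper-quartile reference selection) and re-centered so the factors
have geometric mean 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, NormalizedMatrix

__all__ = ["effective_library_sizes", "tmm_factors", "normalize_cpm", "tmm_normalize"]

logger = logging.getLogger(__name__)


def effective_library_sizes(counts: CountMatrix) -> pd.Series:
    """Per-sample total reads in consensus peaks (column sums)."""
    return counts.effective_library_sizes()


def _upper_quartile_fraction(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    return np.quantile(counts, 0.75, axis=0) / lib


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    a_cutoff: float,
) -> float:
    """TMM factor of one sample against the reference, on the log2 scale 2^f."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return np.nan  # caller logs and substitutes 1
    po = obs[both] / lib_obs
    pr = ref[both] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M; weights are its reciprocal
    v = (lib_obs - obs[both]) / (lib_obs * obs[both]) + (lib_ref - ref[both]) / (
        lib_ref * ref[both]
    )
    keep_a = a > a_cutoff
    m, a, v = m[keep_a], a[keep_a], v[keep_a]
    if m.size == 0:
        return np.nan
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction across samples. M- and
    A-values are computed over peaks nonzero in both sample and reference,
    doubly trimmed, and combined by a precision-weighted mean.
    """
    lib = counts.effective_library_sizes().to_numpy(dtype=float)
    if (lib <= 0).all():
        raise ValueError("no sample with nonzero library size")
    arr = counts.counts.to_numpy(dtype=float)
    samples = counts.sample_ids

    with np.errstate(divide="ignore", invalid="ignore"):
        f75 = _upper_quartile_fraction(arr, lib)
    finite = np.isfinite(f75)
    ref_idx = int(np.nanargmin(np.abs(f75 - np.nanmean(f75[finite]))))
    ref = arr[:, ref_idx]
    lib_ref = lib[ref_idx]

    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if lib[j] <= 0:
            logger.warning("sample %s has zero library size; TMM factor set to 1", samples[j])
            continue
        f = _tmm_pair(arr[:, j], ref, lib[j], lib_ref, logratio_trim, sum_trim, a_cutoff)
        if np.isnan(f):
            logger.warning(
                "sample %s shares no nonzero peaks with the reference; factor set to 1",
                samples[j],
            )
            f = 1.0
        factors[j] = f

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def normalize_cpm(counts: CountMatrix, factors: pd.Series) -> NormalizedMatrix:
    """Counts-per-million of the TMM-effective library, linear scale."""
    if not counts.sample_ids.equals(factors.index):
        factors = factors.reindex(counts.sample_ids)
        if factors.isna().any():
            raise ValueError("factors missing for some samples")
    if (factors <= 0).any():
        bad = factors.index[factors <= 0][0]
        raise ValueError(f"non-positive TMM factor for sample {bad!r}")
    lib = counts.effective_library_sizes()
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero effective library size")
    values = 1e6 * counts.counts / (lib * factors)
    return NormalizedMatrix(
        values=values, tmm_factors=factors, library_sizes=lib.astype(float)
    )


def tmm_normalize(counts: CountMatrix, **kwargs) -> NormalizedMatrix:
    """Convenience: estimate TMM factors and return the normalized matrix."""
    return normalize_cpm(counts, tmm_factors(counts, **kwargs))
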