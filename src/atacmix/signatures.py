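"""Differential accessibility testing and signature-matrix construction.

Signature peaks discriminate one cell type from the rest of the pure
populations. Candidates are screened by a two-sided unequal-variance
(Welch) t-test on log2 normalized accessibility with Benjamini-Hochberg FDR
control; the signature size g is chosen by minimizing the 2-norm condition
number of the median signature matrix over a grid of candidate sizes, the
CIBERSORT-style recipe.

Differential accessibility calling uses the conventional thresholds
FDR < 5% and |log2 fold change| > 2 on normalized read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix, SignatureMatrix

__all__ = [
    "welch_t_test",
    "bh_fdr",
    "one_vs_rest_tests",
    "call_differential_peaks",
    "select_signature_matrix",
    "condition_number",
    "LOG2_PSEUDOCOUNT",
]

logger = logging.getLogger(__name__)

LOG2_PSEUDOCOUNT = 0.5  # added before any log2 of normalized accessibility
_VAR_FLOOR = 1e-12


def _welch_arrays(
    a: np.ndarray, b: np.ndarray, axis: int = -1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch statistic, Satterthwaite df and two-sided p."""
    na = a.shape[axis]
    nb = b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    ma = a.mean(axis=axis)
    mb = b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    floored = (va < _VAR_FLOOR) | (vb < _VAR_FLOOR)
    if np.any(floored):
        logger.warning(
            "%d peak(s) with near-zero group variance; variance floored at %g",
            int(np.sum(floored)),
            _VAR_FLOOR,
        )
    va = np.maximum(va, _VAR_FLOOR)
    vb = np.maximum(vb, _VAR_FLOOR)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided unequal-variance t-test for one peak.

    Returns (t, Satterthwaite df, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("groups must be 1-dimensional")
    t, df, p = _welch_arrays(a[None, :], b[None, :], axis=1)
    return float(t[0]), float(df[0]), float(p[0])


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_values(values: pd.DataFrame) -> pd.DataFrame:
    return np.log2(values + LOG2_PSEUDOCOUNT)


def _group_columns(norm: NormalizedMatrix, groups: pd.Series) -> dict[str, list]:
    missing = groups.index.difference(norm.sample_ids)
    if len(missing):
        raise KeyError(f"group samples missing from matrix: {list(missing)}")
    out: dict[str, list] = {}
    for sample, g in groups.items():
        out.setdefault(g, []).append(sample)
    for g, cols in out.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    return out


def one_vs_rest_tests(
    norm: NormalizedMatrix, groups: pd.Series
) -> dict[str, pd.DataFrame]:
    """Per-cell-type one-vs-rest Welch tests over all peaks.

    The statistic is computed on log2(value + 0.5); the reported log2 fold
    change is between pseudocounted group means of linear normalized values,
    positive when the peak favors the target type. Returns, per cell type, a
    frame with columns t, df, p, q, log2fc.
    """
    by_group = _group_columns(norm, groups)
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    logv = _log2_values(norm.values)
    results = {}
    for ct, cols in by_group.items():
        rest = [s for g, cs in by_group.items() if g != ct for s in cs]
        a = logv[cols].to_numpy()
        b = logv[rest].to_numpy()
        t, df, p = _welch_arrays(a, b, axis=1)
        q = bh_fdr(p)
        mean_a = norm.values[cols].to_numpy().mean(axis=1)
        mean_b = norm.values[rest].to_numpy().mean(axis=1)
        lfc = np.log2(mean_a + LOG2_PSEUDOCOUNT) - np.log2(mean_b + LOG2_PSEUDOCOUNT)
        results[ct] = pd.DataFrame(
            {"t": t, "df": df, "p": p, "q": q, "log2fc": lfc}, index=norm.peak_ids
        )
    return results


def call_differential_peaks(
    norm: NormalizedMatrix,
    groups: pd.Series,
    q_max: float = 0.05,
    min_abs_log2fc: float = 2.0,
) -> pd.Series:
    """Label each peak by the two-group differential accessibility rule.

    Requires exactly two groups of pure replicates; a peak is
    ``<type>-specific`` when q < q_max and its log2 fold change toward that
    type exceeds min_abs_log2fc, else ``shared/ns``.
    """
    by_group = _group_columns(norm, groups)
    if len(by_group) != 2:
        raise ValueError("differential calling requires exactly two groups")
    ct_a, ct_b = sorted(by_group)
    res = one_vs_rest_tests(norm, groups)[ct_a]
    labels = np.full(len(res), "shared/ns", dtype=object)
    sig = res["q"].to_numpy() < q_max
    lfc = res["log2fc"].to_numpy()
    labels[sig & (lfc > min_abs_log2fc)] = f"{ct_a}-specific"
    labels[sig & (lfc < -min_abs_log2fc)] = f"{ct_b}-specific"
    return pd.Series(labels, index=norm.peak_ids, name="da_label")


def condition_number(matrix) -> float:
    """2-norm condition number; +inf for rank-deficient matrices."""
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < arr.shape[1]:
        raise ValueError("matrix must have at least as many rows as columns")
    s = np.linalg.svd(arr, compute_uv=False)
    smax = s[0]
    smin = s[-1]
    if smin <= smax * np.finfo(float).eps * max(arr.shape) or smin == 0:
        return float("inf")
    return float(smax / smin)


def _median_matrix(
    norm: NormalizedMatrix, by_group: dict[str, list], peak_ids: pd.Index
) -> pd.DataFrame:
    cols = {
        ct: norm.values.loc[peak_ids, cs].median(axis=1) for ct, cs in by_group.items()
    }
    return pd.DataFrame(cols, index=peak_ids)


def select_signature_matrix(
    norm: NormalizedMatrix,
    groups: pd.Series,
    q_sig: float = 0.30,
    g_grid=range(50, 201),
) -> SignatureMatrix:
    """Build the signature matrix minimizing condition number over g.

    For each candidate per-type signature size g, the top g peaks per cell
    type (among those with q < q_sig, ranked by descending fold change
    favoring that type) are pooled, their median normalized accessibility in
    each type's pure replicates forms the candidate matrix, and the matrix
    with the smallest 2-norm condition number is returned (ties break toward
    smaller g).
    """
    by_group = _group_columns(norm, groups)
    tests = one_vs_rest_tests(norm, groups)
    g_grid = sorted(set(int(g) for g in g_grid))
    if not g_grid or g_grid[0] < 1:
        raise ValueError("g_grid must contain positive sizes")

    ranked: dict[str, pd.Index] = {}
    for ct, res in tests.items():
        cand = res[(res["q"] < q_sig) & (res["log2fc"] > 0)]
        cand = cand.sort_values(
            ["log2fc"], ascending=False, kind="stable"
        )
        ranked[ct] = cand.index
    available = {ct: len(idx) for ct, idx in ranked.items()}
    if min(available.values()) < g_grid[0]:
        raise ValueError(
            f"too few qualifying peaks for signature selection "
            f"(need >= {g_grid[0]} per type, have {available})"
        )

    best: tuple[float, int, pd.Index] | None = None
    g_max = min(available.values())
    for g in g_grid:
        if g > g_max:
            break
        peak_ids = pd.Index([])
        for ct in by_group:
            peak_ids = peak_ids.union(ranked[ct][:g], sort=False)
        med = _median_matrix(norm, by_group, peak_ids)
        kappa = condition_number(med.to_numpy())
        if best is None or kappa < best[0]:
            best = (kappa, g, peak_ids)
    assert best is not None
    kappa, g, peak_ids = best

    med = _median_matrix(norm, by_group, peak_ids)
    # favored type of each signature peak; a peak selected by several
    # one-vs-rest contrasts (possible for K > 2) goes to its largest fold change
    lfc = pd.DataFrame({ct: tests[ct].loc[peak_ids, "log2fc"] for ct in by_group})
    membership = pd.DataFrame(
        {ct: peak_ids.isin(ranked[ct][:g]) for ct in by_group}, index=peak_ids
    )
    peak_ct = lfc.where(membership).idxmax(axis=1)
    return SignatureMatrix(
        values=med, g=g, kappa=kappa, peak_cell_type=peak_ct.rename("cell_type")
    )
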