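"""Cell-type proportion estimation by constrained linear deconvolution.

The mixing model: the normalized accessibility of a signature peak in a
mixed sample is the proportion-weighted sum of its accessibility in the
pure cell types, m ~ S f with f >= 0, sum(f) = 1. The default solver is
non-negative least squares with post-hoc sum-to-one renormalization; a
linear nu-SVR backend is available for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from .containers import (
    DeconvolutionResult,
    MixtureDesign,
    NormalizedMatrix,
    RecoveryStats,
    SignatureMatrix,
)

__all__ = ["estimate_proportions", "deconvolve_samples", "evaluate_recovery"]

logger = logging.getLogger(__name__)


def _nusvr_fit(s: np.ndarray, m: np.ndarray) -> np.ndarray:
    from sklearn.svm import NuSVR

    best = None
    for nu in (0.25, 0.5, 0.75):
        model = NuSVR(nu=nu, C=1.0, kernel="linear")
        model.fit(s, m)
        rmse = float(np.sqrt(np.mean((model.predict(s) - m) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, model.coef_.ravel())
    coef = np.maximum(best[1], 0.0)
    return coef


def estimate_proportions(
    signature: SignatureMatrix,
    mixture_vector,
    method: str = "nnls",
) -> tuple[np.ndarray, float]:
    """Estimate one sample's cell-type proportions from signature peaks.

    ``mixture_vector`` must be aligned to the signature's peak order (a
    pandas Series is realigned by id). Returns (f_hat, residual) where
    residual is ||S f - m||_2 before sum-to-one renormalization.
    """
    s = signature.values.to_numpy(dtype=float)
    if not np.isfinite(signature.kappa):
        raise ValueError("signature matrix is rank deficient (infinite kappa)")
    if isinstance(mixture_vector, pd.Series):
        missing = signature.peak_ids.difference(mixture_vector.index)
        if len(missing):
            raise KeyError(f"mixture vector missing signature peaks: {list(missing)[:5]}")
        m = mixture_vector.reindex(signature.peak_ids).to_numpy(dtype=float)
    else:
        m = np.asarray(mixture_vector, dtype=float)
        if m.shape != (s.shape[0],):
            raise ValueError(
                f"mixture vector length {m.shape} does not match "
                f"{s.shape[0]} signature peaks"
            )
    if not np.any(m > 0):
        raise ValueError("all-zero mixture profile cannot be deconvolved")

    if method == "nnls":
        f, residual = nnls(s, m)
    elif method == "nusvr":
        f = _nusvr_fit(s, m)
        residual = float(np.linalg.norm(s @ f - m))
    else:
        raise ValueError(f"unknown deconvolution method {method!r}")
    total = f.sum()
    if total <= 0:
        raise ValueError("solver returned an all-zero proportion vector")
    return f / total, float(residual)


def deconvolve_samples(
    signature: SignatureMatrix,
    norm: NormalizedMatrix,
    sample_ids=None,
    method: str = "nnls",
    truth: MixtureDesign | None = None,
) -> DeconvolutionResult:
    """Deconvolve a set of samples against one signature matrix."""
    if sample_ids is None:
        sample_ids = list(norm.sample_ids)
    missing = [s for s in sample_ids if s not in norm.sample_ids]
    if missing:
        raise KeyError(f"samples absent from matrix: {missing}")
    absent = signature.peak_ids.difference(norm.peak_ids)
    if len(absent):
        raise KeyError(f"signature peaks absent from matrix: {list(absent)[:5]}")

    rows = []
    residuals = []
    sub = norm.values.loc[signature.peak_ids, sample_ids]
    for i, sample in enumerate(sample_ids):
        f, r = estimate_proportions(signature, sub.iloc[:, i].to_numpy(), method=method)
        rows.append(f)
        residuals.append(r)
    index = pd.Index(sample_ids, name="sample_id")
    props = pd.DataFrame(rows, index=index, columns=signature.cell_types)
    residuals = pd.Series(residuals, index=index, name="residual")
    result = DeconvolutionResult(proportions=props, residuals=residuals)
    if truth is not None:
        t = truth.proportions.reindex(index=props.index, columns=props.columns)
        if t.isna().any().any():
            raise ValueError("truth does not cover all deconvolved samples")
        result.truth = t
        result.abs_error = (props - t).abs()
    return result


def evaluate_recovery(
    result: DeconvolutionResult, truth: MixtureDesign
) -> RecoveryStats:
    """Pooled agreement between estimated and true proportions.

    Pearson R and RMSE are computed over all (sample, cell type) pairs;
    a degenerate (zero-variance) input yields R = 0 with a warning flag.
    """
    est = result.proportions
    t = truth.proportions.reindex(index=est.index, columns=est.columns)
    if t.isna().any().any():
        missing = t.index[t.isna().any(axis=1)].tolist()
        raise ValueError(f"truth missing for samples: {missing[:5]}")
    x = est.to_numpy(dtype=float).ravel()
    y = t.to_numpy(dtype=float).ravel()
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    degenerate = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    if degenerate:
        logger.warning("degenerate proportions (zero variance); reporting R = 0")
        r = 0.0
    else:
        r = float(pearsonr(x, y)[0])
    max_abs = (est - t).abs().max(axis=1)
    return RecoveryStats(
        r=r, rmse=rmse, max_abs_error=max_abs, n=x.size, degenerate=degenerate
    )
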