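"""Detection of cell-specific peaks in mixtures versus proportion and depth.

Per-sample peak detection is defined at the count level by a Poisson
enrichment test against a uniform genomic background: with library size L,
peak length w and effective genome size G, the background rate is
lambda = L * w / G and a peak is detected when the upper-tail p-value
P(X >= count | lambda), BH-adjusted across the evaluated peak set, falls
below a q threshold (default 0.01). This mirrors per-sample peak calling at
q < 0.01 without re-processing reads.

Detection rates of a cell type's signature (or differential) peaks are then
tracked across mixture proportions and binomially thinned sequencing depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .containers import CountMatrix, PeakSet
from .signatures import bh_fdr
from .simulate import downsample_matrix

__all__ = [
    "DetectionReport",
    "detect_peak",
    "detection_pvalues",
    "detect_peaks",
    "detection_rates",
    "depth_titration",
    "synthetic_effective_genome",
    "MOUSE_EFFECTIVE_GENOME",
]

MOUSE_EFFECTIVE_GENOME = 1.87e9  # bp, mouse mappable genome scale
DEFAULT_IN_PEAK_FRACTION = 0.1


def synthetic_effective_genome(
    peaks: PeakSet, in_peak_fraction: float = DEFAULT_IN_PEAK_FRACTION
) -> float:
    """Background genome size for simulated data.

    The simulator only places reads in peaks; the uniform background is
    defined by spreading the library over total peak length divided by the
    assumed in-peak read fraction.
    """
    if not 0 < in_peak_fraction <= 1:
        raise ValueError("in_peak_fraction must lie in (0, 1]")
    return float(peaks.lengths.sum()) / in_peak_fraction


@dataclass(frozen=True)
class DetectionReport:
    """Detection flags and per-cell-type detection rates.

    ``detected`` is peaks x samples (bool, over the evaluated peak set);
    ``rates``   is samples x cell types: the detected fraction of each
    type's peak set; ``library_sizes`` are per-sample in-peak totals.
    """

    detected: pd.DataFrame
    rates: pd.DataFrame
    library_sizes: pd.Series

    def rate(self, sample_id: str, cell_type: str) -> float:
        return float(self.rates.loc[sample_id, cell_type])


def detect_peak(
    count: int,
    peak_length: float,
    library_size: float,
    effective_genome: float,
    q_threshold: float = 0.01,
) -> bool:
    """Single-peak detection (no multiplicity adjustment).

    Evaluates the raw upper-tail Poisson p-value against the background
    rate lambda = library_size * peak_length / effective_genome.
    """
    if effective_genome <= 0:
        raise ValueError("effective_genome must be positive")
    if peak_length <= 0 or library_size <= 0:
        raise ValueError("peak_length and library_size must be positive")
    if count <= 0:
        return False
    lam = library_size * peak_length / effective_genome
    p = poisson.sf(count - 1, lam)
    return bool(p < q_threshold)


def detection_pvalues(
    counts: CountMatrix, peak_lengths: pd.Series, effective_genome: float
) -> pd.DataFrame:
    """Raw upper-tail Poisson p-values, peaks x samples."""
    if effective_genome <= 0:
        raise ValueError("effective_genome must be positive")
    w = peak_lengths.reindex(counts.peak_ids)
    if w.isna().any():
        raise KeyError("peak_lengths missing for some peaks in the matrix")
    lib = counts.effective_library_sizes().to_numpy(dtype=float)
    lam = np.outer(w.to_numpy(dtype=float), lib) / effective_genome
    c = counts.counts.to_numpy()
    p = poisson.sf(c - 1, lam)
    p[c == 0] = 1.0
    return pd.DataFrame(p, index=counts.peak_ids, columns=counts.sample_ids)


def detect_peaks(
    counts: CountMatrix,
    peak_lengths: pd.Series,
    effective_genome: float,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Detection flags with BH adjustment per sample across all peaks."""
    p = detection_pvalues(counts, peak_lengths, effective_genome)
    q = p.apply(lambda col: bh_fdr(col.to_numpy()), axis=0, result_type="broadcast")
    return (q < q_threshold) & (counts.counts > 0)


def detection_rates(
    counts: CountMatrix,
    peak_sets: Mapping[str, pd.Index],
    peak_lengths: pd.Series,
    effective_genome: float,
    q_threshold: float = 0.01,
) -> DetectionReport:
    """Detection rates of named peak sets (signature or DA) per sample.

    The BH adjustment runs per sample across every peak in the matrix (the
    analogue of genome-wide calling); rates aggregate the resulting flags
    over each requested peak set.
    """
    if not peak_sets:
        raise ValueError("no peak sets supplied")
    for name, ids in peak_sets.items():
        ids = pd.Index(ids)
        if len(ids) == 0:
            raise ValueError(f"peak set {name!r} is empty")
        missing = ids.difference(counts.peak_ids)
        if len(missing):
            raise KeyError(f"peak set {name!r} has ids absent from matrix: {list(missing)[:5]}")
    detected = detect_peaks(counts, peak_lengths, effective_genome, q_threshold)
    rates = pd.DataFrame(
        {name: detected.loc[pd.Index(ids)].mean(axis=0) for name, ids in peak_sets.items()}
    )
    rates.index.name = "sample_id"
    return DetectionReport(
        detected=detected,
        rates=rates,
        library_sizes=counts.effective_library_sizes().astype(float),
    )


def depth_titration(
    counts: CountMatrix,
    depth_fractions,
    analysis: Callable[[CountMatrix], Mapping[str, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Re-run an analysis after thinning all samples to each depth fraction.

    ``analysis`` maps a (thinned) count matrix to a flat mapping of summary
    statistics; the result has one row per depth fraction. Fraction 1.0
    reproduces the un-thinned analysis exactly.
    """
    fractions = [float(f) for f in depth_fractions]
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("depth fractions must lie in (0, 1]")
    rows = []
    for frac in fractions:
        thinned = counts if frac == 1.0 else downsample_matrix(counts, frac, rng)
        stats = dict(analysis(thinned))
        stats["depth_fraction"] = frac
        stats["mean_depth"] = float(thinned.effective_library_sizes().mean())
        rows.append(stats)
    out = pd.DataFrame(rows).set_index("depth_fraction")
    return out
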