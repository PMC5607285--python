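"""End-to-end mixture benchmark: simulate, normalize, sign, deconvolve, detect.

This is the programmatic equivalent of the `atacmix run-all` command and the
workhorse behind the bundled benchmark numbers: a two-cell-type titration is
simulated, TMM-normalized, signature peaks are selected from the pure
replicates, every mixture is deconvolved, and signature-peak detection rates
are tabulated across the titration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    DeconvolutionResult,
    MixtureDesign,
    NormalizedMatrix,
    RecoveryStats,
    SignatureMatrix,
)
from .deconvolve import deconvolve_samples, evaluate_recovery
from .normalize import tmm_normalize
from .sensitivity import (
    DEFAULT_IN_PEAK_FRACTION,
    DetectionReport,
    detection_rates,
    synthetic_effective_genome,
)
from .signatures import call_differential_peaks, select_signature_matrix
from .simulate import MixtureExperiment, SimulationParams, simulate_mixture_experiment

__all__ = ["BenchmarkResult", "run_mixture_benchmark"]


@dataclass
class BenchmarkResult:
    experiment: MixtureExperiment
    normalized: NormalizedMatrix
    signature: SignatureMatrix
    da_labels: pd.Series
    deconvolution: DeconvolutionResult
    recovery: RecoveryStats
    detection: DetectionReport

    def detection_rate_at(self, cell_type: str, proportion: float) -> float:
        """Signature-peak detection rate in the mixture with the given
        proportion of ``cell_type``."""
        design = self.experiment.design.proportions
        match = design.index[np.isclose(design[cell_type], proportion)]
        if len(match) == 0:
            raise KeyError(f"no mixture with {cell_type} proportion {proportion}")
        return self.detection.rate(match[0], cell_type)


def run_mixture_benchmark(
    params: SimulationParams | None = None,
    g_grid=range(50, 201),
    q_sig: float = 0.30,
    detection_q: float = 0.01,
    in_peak_fraction: float = DEFAULT_IN_PEAK_FRACTION,
    method: str = "nnls",
) -> BenchmarkResult:
    """Run the full simulated-mixture analysis under one parameter set."""
    params = SimulationParams() if params is None else params
    exp = simulate_mixture_experiment(params)

    norm = tmm_normalize(exp.counts)
    pure_norm = NormalizedMatrix(
        values=norm.values[list(exp.pure_samples)],
        tmm_factors=norm.tmm_factors[list(exp.pure_samples)],
        library_sizes=norm.library_sizes[list(exp.pure_samples)],
    )
    signature = select_signature_matrix(pure_norm, exp.groups, q_sig=q_sig, g_grid=g_grid)
    da_labels = (
        call_differential_peaks(pure_norm, exp.groups)
        if params.n_cell_types == 2
        else pd.Series(dtype=object)
    )

    deconv = deconvolve_samples(
        signature,
        norm,
        sample_ids=list(exp.mixture_samples),
        method=method,
        truth=exp.design,
    )
    recovery = evaluate_recovery(deconv, exp.design)

    mixture_counts = CountMatrix(exp.counts.counts[list(exp.mixture_samples)].copy())
    peak_sets = {
        ct: signature.peaks_for(ct) for ct in signature.cell_types
    }
    detection = detection_rates(
        mixture_counts,
        peak_sets,
        peak_lengths=exp.peaks.lengths,
        effective_genome=synthetic_effective_genome(exp.peaks, in_peak_fraction),
        q_threshold=detection_q,
    )
    return BenchmarkResult(
        experiment=exp,
        normalized=norm,
        signature=signature,
        da_labels=da_labels,
        deconvolution=deconv,
        recovery=recovery,
        detection=detection,
    )
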