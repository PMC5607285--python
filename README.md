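# atacmix

Cell-type deconvolution and sensitivity analysis of ATAC-seq cell mixtures.

Bulk chromatin-accessibility profiles of heterogeneous tissues (pancreatic
islets being the motivating case: mixtures of alpha-, beta- and other
endocrine cells) blend the regulatory landscapes of their constituent cell
types. Given ATAC-seq peak count profiles of the *pure* populations,
`atacmix` answers two questions a genomics analyst has about a mixed
sample:

1. **What fraction of each cell type is in it?** Signature peaks — the
   open-chromatin regions that best discriminate one cell type from the
   rest — are selected from pure replicates, and the mixture profile is
   modeled as a proportion-weighted sum of pure profiles:

   *m = S f*,  *f ≥ 0*, *Σ f = 1*

   where *S* is the signature matrix (median normalized accessibility of
   each signature peak in each pure population) and *f* the unknown
   proportion vector, estimated by non-negative least squares and
   renormalized to the simplex.

2. **How small a population can still be seen?** A count-level Poisson
   enrichment test (background rate λ = library · peak-width / effective
   genome, BH-adjusted, q < 0.01 — a stand-in for per-sample peak calling)
   tracks the fraction of a cell type's signature peaks detected as that
   type's proportion and the sequencing depth shrink.

The package bundles a negative-binomial simulator that reproduces the
benchmark study design — pure replicates of two archetype islet cell lines
plus mixtures titrated 0–100% in 10% steps — so the entire pipeline runs
and is tested without any external data. Real data enter as a BED peak set
plus a peaks × samples TSV count matrix and a sample-group table.

## Pipeline

| stage | module | method |
| --- | --- | --- |
| simulate | `atacmix.simulate` | per-peak lognormal accessibility, NB counts (var = μ + φμ²), binomial depth thinning |
| normalize | `atacmix.normalize` | effective library size (reads in peaks) + TMM scaling factors, linear CPM |
| signatures | `atacmix.signatures` | Welch t-tests on log2 CPM, BH FDR; DA call at q < 0.05 and \|log2 FC\| > 2; signature size chosen by condition-number minimization |
| deconvolve | `atacmix.deconvolve` | NNLS on linear CPM over signature peaks (ν-SVR backend optional), recovery statistics vs truth |
| sensitivity | `atacmix.sensitivity` | Poisson-background detection, rates per cell type across titration and depth |
| I/O + annotation | `atacmix.io`, `atacmix.annotate` | BED/TSV round-trips, promoter (≤ 2 kb to TSS) vs distal classes, max-\|FC\| peak→gene assignment, accessibility/expression fold-change concordance |

## Worked example

```python
from atacmix import SimulationParams
from atacmix.pipeline import run_mixture_benchmark

bench = run_mixture_benchmark(SimulationParams(seed=42))
sig = bench.signature
print(f"signature size g = {sig.g} per cell type ({len(sig.peak_ids)} peaks), kappa = {sig.kappa:.3f}")
print(f"pooled Pearson R = {bench.recovery.r:.4f}, RMSE = {bench.recovery.rmse:.4f}")
print(bench.deconvolution.proportions.round(3).to_string())
```

prints

```
signature size g = 56 per cell type (112 peaks), kappa = 1.042
pooled Pearson R = 0.9986, RMSE = 0.0173
           alpha   beta
sample_id
mix_p000   0.008  0.992
mix_p010   0.108  0.892
mix_p020   0.208  0.792
mix_p030   0.294  0.706
mix_p040   0.400  0.600
mix_p050   0.493  0.507
mix_p060   0.623  0.377
mix_p070   0.743  0.257
mix_p080   0.819  0.181
mix_p090   0.914  0.086
mix_p100   0.989  0.011
```

The 11 rows are the titration mixtures (`mix_p020` contains 20% alpha-like
cells); the estimated proportions track the truth with pooled Pearson
R = 0.9986, and 98% of alpha signature peaks are still detected in the
20%-alpha mixture (`bench.detection_rate_at("alpha", 0.2)`).

The same analysis is available from the shell:

```sh
atacmix --seed 42 --outdir out run-all      # BED, counts, signature, proportions, detection, depth titration
atacmix --outdir out simulate               # or run the stages separately
atacmix --outdir out deconvolve --counts out/counts.tsv --groups out/groups.tsv --truth out/truth.tsv
```

Every command writes a `provenance_<command>.json` with the resolved
parameters, seed and version; a YAML `--config` mirrors
`SimulationParams` plus the analysis thresholds.

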