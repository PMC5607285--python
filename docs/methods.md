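# Methods

## The mixing model

A bulk ATAC-seq profile of a cell mixture is modeled as a linear blend of
the profiles of its constituent cell types. For a set of signature peaks
and K cell types, let S be the signature matrix (peaks × K, median
normalized accessibility of each peak in each type's pure replicates) and
m the normalized profile of a mixed sample over the same peaks. The model
is

    m = S f + e,   f ≥ 0,  Σ_c f_c = 1,

and f is estimated by non-negative least squares followed by sum-to-one
renormalization. NNLS implements the weighted-sum assumption directly;
renormalization rather than a simplex-constrained solver keeps the fit a
single convex problem and is equivalent in the noiseless limit. A linear
ν-SVR backend (ν ∈ {0.25, 0.5, 0.75}, best in-sample RMSE, negative
coefficients clipped) is available as `method="nusvr"` for comparison with
support-vector deconvolution tools, but is not the default.

Deconvolution operates on **linear-scale** normalized values, not log
values: additivity of read counts across cell types holds on the linear
scale only.

An identifiability caveat follows from normalization: if cell types differ
in their total per-cell accessibility, the coefficients recovered from
depth-normalized profiles are *read* fractions, `f_c · T_c / Σ T` with
T_c the total accessibility of type c, not cell fractions. Exact recovery
of cell proportions therefore holds when profiles mix exactly as m = S f
(the invariant the noiseless tests check, to 1e-6); on simulated counts
the residual type-total asymmetry plus counting noise leaves a pooled
correlation of ~0.998 and RMSE ~0.02 rather than exactly 1 and 0.

## Normalization

Counts are divided by the effective library size (total reads in consensus
peaks) and a trimmed-mean-of-M-values (TMM) scaling factor, then scaled to
counts per million: value = 1e6 · count / (L · f_TMM). The TMM factor uses
the canonical recipe: reference sample = the one whose upper-quartile
count fraction is closest to the mean; M and A values over peaks nonzero
in both sample and reference; 30% two-sided trim on M and 5% on A;
precision-weighted (delta-method variance) mean of the surviving M values;
factors re-centered to geometric mean 1. Trim parameters are exposed as
arguments. Zero counts normalize to 0 with no pseudocount; any log2
transform downstream adds a pseudocount of 0.5.

## Signature selection and differential accessibility

Per cell type, a one-vs-rest Welch (unequal-variance) t-test is computed
on log2(CPM + 0.5) across pure replicates, with Benjamini–Hochberg FDR
control across peaks. Groups need ≥ 2 replicates; group variances are
floored at 1e-12 (with a logged warning) so constant groups yield t = 0
rather than an undefined statistic.

Differential accessibility uses the conventional thresholds FDR < 5% and
|log2 FC| > 2, the fold change being the ratio of pseudocounted group
means of linear CPM.

Signature peaks: among peaks with q < 0.30 favoring a type, the top g by
fold change are taken per type for each g in a grid (default 50–200); the
g whose pooled median matrix has the smallest 2-norm condition number κ is
kept (ties toward smaller g). Minimizing κ favors signature matrices whose
columns are well separated, which stabilizes the downstream least-squares
fit. The published analysis this mirrors delegated selection to a
deconvolution tool whose exact settings are not recoverable; the
q < 0.30 screen and condition-number grid are the standard recipe for such
tools and are exposed as configuration.

The Welch-test route is a deliberate substitution for negative-binomial
GLM testing (edgeR-style) used in some pipelines; thresholds are kept
identical, and the bundled simulation shows the two-group labels recover
the generator's peak classes exactly in the low-noise limit.

## Synthetic data

The generator emulates the benchmark study design: two archetype islet
cell lines profiled pure in triplicate, plus 11 mixtures at 0–100% in 10%
steps, all sequenced to 5e6 in-peak reads.

* Peaks: 20,000 intervals of 500 bp on one synthetic chromosome, 1 kb
  apart (coordinates exist only so BED round-trips are meaningful).
* Base accessibility b_i ~ lognormal(0, 1) per peak — a heavy-tailed
  intensity distribution typical of accessibility data.
* 10% of peaks per type are cell-specific: accessibility 16·b in their own
  type and 0.5·b elsewhere (expected log2 contrast 5, comfortably past the
  DA threshold of 2); the rest are shared (b everywhere).
* Counts: a sample with depth D and per-peak intensities μ gets
  NB(mean = D·μ/Σμ, var = μ + φμ²) counts with φ = 0.05, a mild
  overdispersion chosen as realistic for technical + biological replicate
  variation of count data; φ = 0 gives exact Poisson.
* Mixtures: intensities combine as Σ_c f_c μ_c before depth scaling —
  reads from a mixture come from its cells in proportion.
* Depth: binomial thinning with p = target/current models uniform read
  subsampling; the depth grid default (1, 0.25, 0.15, 0.05, 0.01 of full
  depth) rescales the 25/15/5/1-million down-sampling design of a ~100M
  read experiment.

What the simulation does **not** emulate: GC/fragment-length biases,
spatially correlated background, peak-width variation, chromosome
structure, composition-induced normalization stress beyond what random
intensities produce, and partial peak overlap between cell types beyond
the single background factor. Passing benchmarks here demonstrate the
statistical machinery is correct and calibrated under the stated count
model, not that real mixed-tissue libraries will reach the same accuracy.

## Peak detection proxy

Real pipelines decide "is this peak present in this sample" by per-sample
peak calling from reads at q < 0.01. Re-calling peaks is out of scope at
the count level, so detection is defined by a Poisson enrichment test
against a uniform background: λ = L·w/G for library size L, peak width w,
effective genome G; upper-tail p-values are BH-adjusted per sample across
all peaks in the matrix (the analogue of genome-wide calling) and compared
to q < 0.01. G defaults to 1.87e9 bp (mouse mappable genome) for real
data; for synthetic data G = total peak length / 0.1, i.e. the background
assumes 10% of reads fall in peaks.

Two consequences worth knowing:

* Signature-peak detection **saturates**: above ~30% cognate proportion
  essentially every signature peak is detected, so rank correlations of
  signature rates against proportion are truncated by ties. Monotonicity
  is therefore quantified on the differential-peak rates, which span the
  dynamic range (Spearman ≥ 0.99 on the default simulation), while
  signature rates are checked to dominate DA rates at every titration
  point.
* At 0% cognate proportion the signature-peak rate is ~0.5–0.6, not ~0:
  with a background factor of 0.5, specific peaks are genuinely half-open
  in the other cell type, and a deeply sequenced sample correctly detects
  many of them as enriched over genomic background. The 0% point is the
  titration minimum, not a false-positive floor.

## Numerical and interface choices

* Tie-breaks: signature grid ties → smallest g; peak→gene assignment ties
  on |FC| → larger raw mean accessibility, then lexicographic peak id.
* Degenerate inputs: rank-deficient signature matrices get κ = ∞ and are
  refused by the solver; all-zero mixture profiles, zero library sizes and
  empty peak sets raise errors naming the offender; constant estimated or
  true proportions make Pearson R undefined — reported as 0 with a
  degeneracy flag.
* TSS distance is measured from the TSS to the nearest covered base of the
  peak (0 if inside); class promoter iff distance ≤ 2000 bp, else distal.
* All randomness flows through a single `numpy` Generator seeded from
  `SimulationParams.seed`; identical parameters and seed give bit-identical
  outputs.
* Benchmark problem sizes (20,000 peaks, 3 replicates/type, 11 mixtures,
  5e6 reads) are the simulated study conditions; unit tests use smaller
  universes (300–5,000 peaks) chosen to keep each statistical check
  well-powered.

## Known limitations

* K > 2 cell types are supported throughout (one-vs-rest testing,
  NNLS), but the bundled titration design and DA caller are two-type;
  multi-type mixtures require a user-supplied design.
* Welch tests on 3 vs 3 replicates have limited power compared to
  count-model tests; the 16-fold simulated contrast makes this moot in the
  benchmark but real marginal peaks will be missed.
* The detection proxy shares none of a peak caller's read-level evidence
  (fragment placement, local background), so absolute detection rates are
  comparable across conditions, not across tools.
* Proportion estimates inherit the read-fraction bias described above
  whenever cell types differ in total accessibility per cell.
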