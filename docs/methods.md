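# Methods

## Statistical model

For each selected pair of a gene *k* and a CpG *j*, expression is
modelled as a linear function of methylation with shared nuisance
covariates:

    y_k = a_jk M_j + X b_jk + c_jk 1 + e,   e ~ (0, sigma_jk^2 I)

* `y_k` — length-n vector of log expression levels for gene k;
* `M_j` — length-n vector of methylation Beta scores in [0, 1] for CpG j;
* `X` — n x m covariate matrix, identical for every pair;
* `a_jk` — the quantity of interest: expression units per Beta unit.

An intercept is always included and may not be supplied by the user;
covariate columns that are constant after sample alignment are rejected
because they would duplicate it. The estimate, its standard error with
residual degrees of freedom `df = n − m − 2` (intercept + m covariates +
methylation term), the t-statistic and a two-sided tail probability are
reported per pair.

### Gaussian p-values

The tail probability is `p = 2(1 − Φ(|t|))` with Φ the standard normal
CDF, evaluated as `erfc(|t|/√2)` so the far tail retains full relative
accuracy. Using the normal rather than the Student-t reference is a
deliberate approximation that makes the tail computation a single
vectorized primitive over an entire block. The error of the
approximation is bounded by the t-vs-normal discrepancy at `df`: measured
on t ∈ [−5, 5], the maximum absolute gap is ≈ 3.2e-4 at df = 996 and
≈ 5.1e-2 at df = 6, so p-values are trustworthy for large cohorts and
anti-conservative for very small ones (roughly n < 20). Tail
probabilities for finite statistics are floored at the smallest positive
double (≈ 4.9e-324) instead of underflowing to zero; an exact fit
(zero residual variance, |r| = 1) reports a saturated t of ±1e9 and
p = 0 exactly.

### Mass computation

All pairs in a gene-block x CpG-block tile are fitted simultaneously via
Frisch–Waugh–Lovell residualization: with `Q` an orthonormal basis of
`[1 | X]` (thin QR), both blocks are projected once per block
(`R = Y − (YQ)Qᵀ`), and then

    a_jk   = <r_yk, r_mj> / ||r_mj||²
    RSS_jk = ||r_yk||² − a_jk <r_yk, r_mj>
    se_jk  = sqrt(RSS_jk / df) / ||r_mj||

which requires one cross-product matrix per tile instead of one matrix
factorization per pair. The test suite verifies numerical equivalence to
per-pair full-design least squares (statsmodels OLS and a plain lstsq
oracle) at relative 1e-8 over 1000+ random instances; observed agreement
is ~1e-13. Optional per-covariate statistics are recovered algebraically
from the same quantities: the full-model covariate coefficients are
`pinv(D)y − (pinv(D)m) a_jk` and their variances
`sigma² (diag((DᵀD)⁻¹) + (pinv(D)m)² / ||r_m||²)`, with `D = [1 | X]`.

### Degenerate loci

A locus whose residual vector has (numerically) zero norm — e.g. a
constant methylation probe, or one that is an exact linear combination of
the covariates — cannot be tested. Such loci yield NaN est/se/t/p for all
their pairs, a warning log line, and are counted in the run summary;
they never abort a run and never pass a p-value filter. The zero-norm
cutoff is relative: `||r||² ≤ 1e-12 · max(||raw||², 1)`.

## Pair selection

Windows are anchored on the transcript start site: BED strand `+` or
unknown anchors at `start`, strand `−` at `end − 1` (the last base of the
half-open interval). CpG probes anchor at their interval start (single
base by convention; wider intervals warn). Distances are absolute
TSS-to-CpG offsets in 0-based coordinates; windows are symmetric
("within" means `d ≤ W`, "outside" means `d > W`), so the boundary
distance belongs to cis, not distal. With the default windows — cis 1 Mb,
distal 50 kb — the two same-chromosome modalities deliberately overlap
for 50 kb < d ≤ 1 Mb; the overlap follows the window definitions
literally and is asserted, not hidden, in the tests. Chromosome names are
compared as exact strings; a preflight warning fires when the gene and
CpG annotations share no chromosome name. Loci absent from an annotation
are excluded from cis/distal/trans (logged once each); `all` mode ignores
annotations entirely. Trans/all runs default to storing only p < 1e-5 to
bound output size; cis/distal default to no filter. The filter is strict
(`p < threshold`).

## Chunked execution and determinism

The gene x CpG grid is tiled by explicit chunk sizes or by inverting a
closed-form working-set model,

    bytes(G, C) = 1.5 · bpv · (2Gn + 2Cn + (m+1)n + 6GC)

(raw + residualized input blocks, the design, and six result-sized G x C
temporaries; 1.5 is a safety factor for allocator overhead). `auto` gene
sizing returns the largest G for which this fits the configured budget
(default 2 GiB); the formula is exposed so the estimate can be reproduced
independently.

Outputs are bit-identical across tilings and thread counts. Two
implementation choices make this hold exactly rather than approximately:
every per-pair reduction (residualization products, cross-products, row
norms) runs through a fixed-order einsum kernel whose summation order
depends only on the sample axis, never on the block shape — BLAS gemm
kernels, by contrast, change accumulation order with operand shape and
thread count, which costs the last ulp; and rows are emitted gene-major,
CpG-minor regardless of tiling, buffered per gene block. Numeric cells
are serialized with `%.17g`, the shortest format that round-trips an
IEEE double, so file comparison is exact and write→read is an identity.
Thread counts are applied through threadpoolctl around the compute loop.
A failing block aborts the whole run and removes the partial output
file.

Computation is double precision on CPU. The regression core also accepts
float32 (the precision an accelerator path would use); the cross-precision
contract — estimates within relative 1e-4 of double — is verified in the
tests. Device selection probes for a CUDA-capable torch installation at
run time: `auto` falls back to CPU when none is found, and an explicit
accelerator request without a device is an error.

## Synthetic data

`generate_dummy` produces unstructured inputs: expression i.i.d. standard
normal (log expression is roughly symmetric and unbounded), methylation
i.i.d. uniform on [0, 1] (spans the full Beta range with no further
structure), covariates standard normal, and loci placed uniformly over a
configurable layout (default 2 chromosomes of 3 Mb, so the default cis
and distal windows are both exercised at test scale). `generate_with_effects`
adds planted effects `y_k = Σ a·M_j + Xb + N(0, sd²)` and emits a truth
table for scoring. All draws come from a single seeded PCG64 stream, so
equal seeds give byte-identical files across platforms.

What the generator does *not* emulate: the correlation structure of real
cohorts (probe-probe LD, cell-type mixtures, batch structure), non-null
genome-wide effect distributions, or array-specific missingness. Passing
tests therefore demonstrate the correctness and calibration of the
computation under the stated generative model, not robustness to real-data
artifacts — inputs are assumed preprocessed and QC'd upstream.

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen to exercise every code path
while keeping the whole suite in tens of seconds: oracle agreement on
1000+ random instances with n ∈ [10, 200], m ∈ [0, 5]; chunk invariance
on a 50-gene x 200-CpG x n = 100 run across tilings (1,1), (7,13), (all,all)
and 1 or 4 threads; modality membership against an exhaustive double loop
on a 1000 x 1000 annotation grid including exact-boundary distances; null
calibration on 10⁴ independent null pairs at n = 200 (fraction of
p < 0.05 expected in [0.03, 0.07] under the Gaussian approximation);
recovery of a planted a = 0.5 (noise sd 1, n = 500, 200 replicates:
mean within ±0.02, 95% CI coverage ≥ 93%); and runtime over CpG counts
{1, 2, 4, 8}·10³ fitted to a line (R² ≥ 0.95), a qualitative scaling
check, not a benchmark.

## Design choices and limitations

* **Missing values** are a hard error by default; an opt-in flag drops
  affected loci with a log line each. Per-pair complete-case analysis
  would break the batched computation and silently vary n across pairs.
* **Categorical covariates** must be pre-encoded numerically by the user;
  no automatic coding is attempted.
* **Duplicate sample or locus ids** are errors, never deduplicated.
* **Pearson mode** p-values use the r → t transform
  `t = r·sqrt((n−2)/(1−r²))` with the same Gaussian tail; with m = 0 this
  t equals the regression t exactly (asserted in tests).
* **Two-sided tests only**; no one-sided option.
* **No multiple-testing correction**: the tool filters on raw p; FDR/FWER
  control is the analyst's responsibility downstream.
* The fixed-order einsum kernels trade peak BLAS throughput for exact
  reproducibility; at the block sizes the memory model produces, the
  cross-product remains far from the bottleneck of an end-to-end run
  (output writing dominates).
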