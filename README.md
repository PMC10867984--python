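# ecpg — scalable eQTM/eCpG mapping

`ecpg` tests for associations between DNA methylation and gene expression
measured in the same samples. A CpG locus whose methylation level predicts
the expression of a gene is an *expression quantitative trait methylation*
locus (eQTM, also called an eCpG); such loci are candidate regulatory
elements, locally (promoter methylation) or remotely (distal enhancers,
other chromosomes). The package is aimed at epigenomics analysts who have
preprocessed methylation Beta-value and log-expression matrices (e.g.
Illumina 450K/EPIC plus an expression array or RNA-seq) and need to scan
millions to billions of (gene, CpG) pairs quickly and reproducibly.

## The model

For gene *k* and CpG *j* over *n* shared samples, `ecpg` fits

```
y_k = a_jk * M_j + X b_jk + intercept + e,    e ~ (0, sigma^2)
```

where `y_k` is the gene's log expression vector, `M_j` the CpG's Beta
scores in [0, 1], and `X` an n x m matrix of user covariates (age, batch,
cell composition, ...). The reported statistics for each pair are the
methylation coefficient `a_jk` (column `est`), its standard error `se`
(residual degrees of freedom n − m − 2), `t = est/se`, and the two-sided
Gaussian-tail p-value `p = 2(1 − Φ(|t|))`. The Gaussian CDF deliberately
stands in for Student's t: the two coincide as n grows, and the normal
tail vectorizes cheaply over huge blocks (below roughly 20 samples the
difference is noticeable; see `docs/methods.md`). A covariate-free
Pearson-correlation mode is also available (`est` is then r).

Rather than fitting each pair separately, the whole gene x CpG grid is
fitted in a handful of matrix products: expression and methylation rows
are residualized once against the shared design `[1 | X]`
(Frisch–Waugh–Lovell), after which every `a_jk` is a simple-regression
slope. The grid is tiled into memory-budgeted chunks; results are
bit-identical for every tiling and thread count.

Four modalities select which pairs are tested, anchored on the gene's
transcript start site (TSS): **cis** (within a window, default ±1 Mb, same
chromosome), **distal** (outside a window, default 50 kb, same
chromosome), **trans** (different chromosome), and **all** (every pair).
Trans and all filter output to p < 1e-5 by default to bound file sizes.

## Worked example

Plant one true effect (gene7 ~ cg0000042, a = 1.2) among 2000 null pairs
and map them:

```python
from ecpg import EQTMModel, EffectSpec, generate_with_effects, align_samples

spec = EffectSpec(n_samples=300, n_genes=20, n_cpgs=100, n_covariates=2,
                  covariate_effects=(0.8, -0.5),
                  effects=(("gene7", "cg0000042", 1.2),),
                  noise_sd=1.0, seed=11)
ds = generate_with_effects(spec)
model = EQTMModel(align_samples(ds.expression, ds.methylation, ds.covariates),
                  ds.gene_annotation, ds.cpg_annotation)
res = model.fit("all", keep_all_pairs=True)
print(res.summary())
```

```
eQTM mapping results
========================================================
method                  mlr
modality                all
window (bp)             -
p-value threshold       -
samples (n)             300
covariates (m)          2
genes                   20
CpG loci                100
pairs tested            2000
pairs reported          2000
degenerate loci         0
device                  cpu(1 threads)
--------------------------------------------------------
gene_id    cpg_id     est     se      t         p
  gene7 cg0000042  0.7725 0.1902  4.062 4.858e-05
 gene19 cg0000065 -0.7396 0.2071 -3.571 0.0003557
  gene8 cg0000069  -0.714 0.2072 -3.445 0.0005704
  ...
```

The planted pair is the top hit: its estimated coefficient 0.77 ± 0.19
(expression units per Beta unit) is within two standard errors of the
planted 1.2, and its p-value is three orders of magnitude smaller than
the best null pair. `res.frame` holds the full table; `res.significant(1e-5)`
and `res.plot_volcano()` work from there.

The same run from a shell:

```sh
ecpg data dummy --samples 300 --genes 20 --cpgs 100 --covariates 2 \
    --seed 11 --out data/
ecpg run cis --expression data/expression.csv --methylation data/methylation.csv \
    --covariates data/covariates.csv --gene-bed data/genes.bed \
    --cpg-bed data/cpgs.bed --window 1000000 --out cis_results.csv
```

Chunking (`--gene-chunk/--cpg-chunk`, or `auto` with `--memory-budget`)
bounds peak memory; `--threads` sets the CPU thread pool; a CUDA-capable
accelerator is used automatically when one is detected, and
`--device cpu` forces CPU execution.

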