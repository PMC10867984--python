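"""Reproducible synthetic expression/methylation/covariate/annotation data.

Two generators are provided. ``generate_dummy`` emulates unstructured
random inputs for smoke testing and benchmarking: expression values are
standard Gaussian (log-scale expression is roughly symmetric and
unbounded), methylation Beta scores are uniform on [0, 1], and loci are
placed uniformly at random over a configurable chromosome layout.
``generate_with_effects`` additionally plants known methylation effects
into selected expression rows, emitting a truth table so recovery and
power can be scored. Both are deterministic for a fixed seed: all draws
come from one ``numpy.random.default_rng`` (PCG64) stream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (BedRecord, CovariateTable, LociAnnotation, LocusMatrix,
                 write_bed, write_covariates, write_locus_matrix)


@dataclass(frozen=True)
class ChromosomeLayout:
    """How simulated loci are placed on a genome."""

    n_chromosomes: int = 2
    chromosome_length: int = 3_000_000  # spans the default cis window

    def names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))


@dataclass(frozen=True)
class EffectSpec:
    """Specification of an effect-planted synthetic dataset."""

    n_samples: int
    n_genes: int
    n_cpgs: int
    n_covariates: int = 0
    #: (gene_id, cpg_id, effect size a) in expression units per Beta unit.
    effects: tuple[tuple[str, str, float], ...] = ()
    #: Covariate coefficients shared by all genes; length n_covariates.
    covariate_effects: tuple[float, ...] = ()
    noise_sd: float = 1.0
    layout: ChromosomeLayout = field(default_factory=ChromosomeLayout)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if min(self.n_samples, self.n_genes, self.n_cpgs) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.covariate_effects and len(self.covariate_effects) != self.n_covariates:
            raise ConfigurationError("covariate_effects length must equal n_covariates")


@dataclass(frozen=True)
class SyntheticDataset:
    """In-memory synthetic dataset plus its annotations and truth table."""

    expression: LocusMatrix
    methylation: LocusMatrix
    covariates: CovariateTable
    gene_annotation: LociAnnotation
    cpg_annotation: LociAnnotation
    truth: pd.DataFrame  # columns gene_id, cpg_id, effect (empty when unplanted)

    def write(self, out_dir) -> dict[str, Path]:
        """Write all components as CSV/BED under ``out_dir``; returns paths."""
        out = Path(out_dir)
        os.makedirs(out, exist_ok=True)
        paths = {
            "expression": out / "expression.csv",
            "methylation": out / "methylation.csv",
            "covariates": out / "covariates.csv",
            "gene_bed": out / "genes.bed",
            "cpg_bed": out / "cpgs.bed",
        }
        write_locus_matrix(self.expression, paths["expression"])
        write_locus_matrix(self.methylation, paths["methylation"])
        write_covariates(self.covariates, paths["covariates"])
        write_bed(self.gene_annotation, paths["gene_bed"])
        write_bed(self.cpg_annotation, paths["cpg_bed"])
        if len(self.truth):
            paths["truth"] = out / "truth.csv"
            self.truth.to_csv(paths["truth"], index=False)
        return paths


def _place_loci(rng: np.random.Generator, ids, layout: ChromosomeLayout,
                widths) -> LociAnnotation:
    chroms = layout.names()
    records: dict[str, BedRecord] = {}
    chrom_idx = rng.integers(0, len(chroms), size=len(ids))
    for i, locus in enumerate(ids):
        width = widths[i]
        start = int(rng.integers(0, max(layout.chromosome_length - width, 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        records[locus] = BedRecord(chroms[chrom_idx[i]], start, start + width, strand)
    return LociAnnotation(records)


def _annotations(rng: np.random.Generator, gene_ids, cpg_ids,
                 layout: ChromosomeLayout) -> tuple[LociAnnotation, LociAnnotation]:
    gene_widths = rng.integers(1_000, 100_000, size=len(gene_ids))
    genes = _place_loci(rng, gene_ids, layout, gene_widths)
    cpgs = _place_loci(rng, cpg_ids, layout, np.ones(len(cpg_ids), dtype=int))
    return genes, cpgs


def generate_dummy(n_samples: int, n_genes: int, n_cpgs: int,
                   n_covariates: int = 0, seed: int = 0,
                   layout: ChromosomeLayout = ChromosomeLayout()) -> SyntheticDataset:
    """Unstructured random dataset: no true methylation-expression effects.

    Expression ~ N(0, 1) i.i.d.; methylation ~ U(0, 1) i.i.d.; covariates
    ~ N(0, 1); loci placed uniformly over the layout. Because expression
    is independent of methylation, p-values from mapping this data are
    null-calibrated (approximately uniform at large n).
    """
    if min(n_samples, n_genes, n_cpgs) < 1:
        raise ConfigurationError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    sample_ids = tuple(f"s{i + 1}" for i in range(n_samples))
    gene_ids = tuple(f"gene{i + 1}" for i in range(n_genes))
    cpg_ids = tuple(f"cg{i + 1:07d}" for i in range(n_cpgs))
    cov_names = tuple(f"cov{i + 1}" for i in range(n_covariates))
    expression = LocusMatrix(gene_ids, sample_ids,
                             rng.standard_normal((n_genes, n_samples)))
    methylation = LocusMatrix(cpg_ids, sample_ids,
                              rng.random((n_cpgs, n_samples)))
    covariates = CovariateTable(sample_ids, cov_names,
                                rng.standard_normal((n_samples, n_covariates)))
    genes, cpgs = _annotations(rng, gene_ids, cpg_ids, layout)
    truth = pd.DataFrame(columns=["gene_id", "cpg_id", "effect"])
    return SyntheticDataset(expression, methylation, covariates, genes, cpgs, truth)


def generate_with_effects(spec: EffectSpec) -> SyntheticDataset:
    """Dataset with planted linear effects of methylation on expression.

    Each expression row is built as

        y_k = sum_j a_jk * M_j + X @ b + N(0, noise_sd^2)

    where the sum runs over the planted (gene k, CpG j, a) triples.
    Methylation is U(0, 1); covariates are N(0, 1). The returned truth
    table lists the planted pairs for downstream scoring.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = tuple(f"s{i + 1}" for i in range(spec.n_samples))
    gene_ids = tuple(f"gene{i + 1}" for i in range(spec.n_genes))
    cpg_ids = tuple(f"cg{i + 1:07d}" for i in range(spec.n_cpgs))
    cov_names = tuple(f"cov{i + 1}" for i in range(spec.n_covariates))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    cpg_index = {c: i for i, c in enumerate(cpg_ids)}
    for gene, cpg, _ in spec.effects:
        if gene not in gene_index:
            raise ConfigurationError(f"planted gene {gene!r} does not exist")
        if cpg not in cpg_index:
            raise ConfigurationError(f"planted CpG {cpg!r} does not exist")

    meth = rng.random((spec.n_cpgs, spec.n_samples))
    cov = rng.standard_normal((spec.n_samples, spec.n_covariates))
    b = np.asarray(spec.covariate_effects if spec.covariate_effects
                   else np.zeros(spec.n_covariates), dtype=np.float64)
    expr = rng.standard_normal((spec.n_genes, spec.n_samples)) * spec.noise_sd
    if spec.n_covariates:
        expr += (cov @ b)[None, :]
    for gene, cpg, a in spec.effects:
        expr[gene_index[gene]] += a * meth[cpg_index[cpg]]

    expression = LocusMatrix(gene_ids, sample_ids, expr)
    methylation = LocusMatrix(cpg_ids, sample_ids, meth)
    covariates = CovariateTable(sample_ids, cov_names, cov)
    genes, cpgs = _annotations(rng, gene_ids, cpg_ids, spec.layout)
    truth = pd.DataFrame([(g, c, a) for g, c, a in spec.effects],
                         columns=["gene_id", "cpg_id", "effect"])
    return SyntheticDataset(expression, methylation, covariates, genes, cpgs, truth)
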