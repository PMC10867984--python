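"""High-level modelling interface: ``EQTMModel.fit() -> EQTMResults``.

This is the programmatic face of the package, shaped like a statistical
modelling library: a model object is constructed from the aligned data
(and optional genomic annotations), ``fit`` executes the mapping for a
chosen modality and method, and the returned results object carries the
per-pair estimates with their uncertainties plus run diagnostics and a
``summary()`` table. The command-line interface is a thin wrapper over
the same machinery.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import RunConfig, RunSummary, run_mapping, _available_fields
from .errors import ConfigurationError
from .io import (AlignedDataset, CovariateTable, LociAnnotation, LocusMatrix,
                 align_samples, read_bed, read_covariates, read_locus_matrix)
from .mapping import MappingMode, Modality


class EQTMModel:
    """Covariate-adjusted association model between methylation and expression.

    For each selected (gene k, CpG j) pair the model is

        y_k = a_jk * M_j + X b_jk + intercept + error

    with y_k the gene's log expression over samples, M_j the CpG's Beta
    scores, and X the shared covariates. ``fit`` reports the methylation
    coefficient a_jk, its standard error, the t-statistic and a two-sided
    Gaussian-tail p-value for every pair of the chosen modality.

    Parameters
    ----------
    dataset
        Sample-aligned expression/methylation/covariate data.
    gene_annotation, cpg_annotation
        BED-derived genomic positions; required for cis/distal/trans.
    """

    def __init__(self, dataset: AlignedDataset,
                 gene_annotation: LociAnnotation | None = None,
                 cpg_annotation: LociAnnotation | None = None) -> None:
        self.dataset = dataset
        self.gene_annotation = gene_annotation
        self.cpg_annotation = cpg_annotation

    @classmethod
    def from_files(cls, expression, methylation, covariates,
                   gene_bed=None, cpg_bed=None, *,
                   drop_missing: bool = False) -> "EQTMModel":
        """Build a model from the CSV/BED files the tool reads."""
        dataset = align_samples(
            read_locus_matrix(expression, drop_missing=drop_missing),
            read_locus_matrix(methylation, drop_missing=drop_missing),
            read_covariates(covariates),
        )
        return cls(dataset,
                   read_bed(gene_bed) if gene_bed else None,
                   read_bed(cpg_bed) if cpg_bed else None)

    @classmethod
    def from_dataframes(cls, expression: pd.DataFrame, methylation: pd.DataFrame,
                        covariates: pd.DataFrame,
                        gene_annotation: LociAnnotation | None = None,
                        cpg_annotation: LociAnnotation | None = None) -> "EQTMModel":
        """Build a model from loci-by-samples / samples-by-covariates frames."""
        dataset = align_samples(
            LocusMatrix(tuple(map(str, expression.index)),
                        tuple(map(str, expression.columns)),
                        expression.to_numpy(dtype=np.float64)),
            LocusMatrix(tuple(map(str, methylation.index)),
                        tuple(map(str, methylation.columns)),
                        methylation.to_numpy(dtype=np.float64)),
            CovariateTable(tuple(map(str, covariates.index)),
                           tuple(map(str, covariates.columns)),
                           covariates.to_numpy(dtype=np.float64)),
        )
        return cls(dataset, gene_annotation, cpg_annotation)

    def fit(self, mode: MappingMode | str = "all", *, method: str = "mlr",
            p_max: float | None = None, window: int | None = None,
            with_covariate_stats: bool = False,
            gene_chunk=None, cpg_chunk=None,
            cpu_threads: int = 1, keep_all_pairs: bool = False,
            output_path=None) -> "EQTMResults":
        """Run the mapping and return the fitted results.

        Parameters
        ----------
        mode
            A MappingMode or one of 'cis', 'distal', 'trans', 'all'.
        p_max
            Keep only pairs with p strictly below this; trans/all default
            to 1e-5 unless ``keep_all_pairs`` is set.
        keep_all_pairs
            Disable the modality's default p-value threshold.
        output_path
            Also leave the streamed CSV at this path.
        """
        if isinstance(mode, str):
            mode = MappingMode(Modality(mode), window=window)
        if keep_all_pairs and p_max is not None:
            raise ConfigurationError("keep_all_pairs excludes p_max")
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(output_path) if output_path else Path(tmp) / "results.csv"
            base = RunConfig(mode=mode, method=method, p_max=p_max,
                             no_filter=keep_all_pairs,
                             with_covariate_stats=with_covariate_stats,
                             gene_chunk=gene_chunk, cpg_chunk=cpg_chunk,
                             cpu_threads=cpu_threads, output_path=path)
            columns = _available_fields(base,
                                        self.dataset.covariates.covariate_names)
            config = replace(base, columns=columns)
            summary = run_mapping(self.dataset, self.gene_annotation,
                                  self.cpg_annotation, config)
            frame = pd.read_csv(path, dtype={"gene_id": str, "cpg_id": str})
        return EQTMResults(model=self, frame=frame, run_summary=summary,
                           config=config)


@dataclass
class EQTMResults:
    """Fitted (gene, CpG) associations with uncertainties and diagnostics.

    Attributes
    ----------
    frame
        One row per reported pair: gene_id, cpg_id, est (methylation
        coefficient, expression units per Beta unit; Pearson mode: r),
        se, t, p, plus per-covariate columns when requested.
    run_summary
        Pairs tested, rows written, degenerate loci, chunk/block counts.
    """

    model: EQTMModel
    frame: pd.DataFrame
    run_summary: RunSummary
    config: RunConfig

    @property
    def pairs_tested(self) -> int:
        return self.run_summary.pairs_tested

    @property
    def n_reported(self) -> int:
        return len(self.frame)

    def top(self, n: int = 10) -> pd.DataFrame:
        """The n most significant pairs (smallest p, NaN last)."""
        return self.frame.sort_values("p", kind="stable", na_position="last").head(n)

    def significant(self, alpha: float) -> pd.DataFrame:
        return self.frame[self.frame["p"] < alpha]

    def summary(self) -> str:
        """A human-readable run and results summary table."""
        d = self.model.dataset
        s = self.run_summary
        mode = self.config.mode
        lines = [
            "eQTM mapping results",
            "=" * 56,
            f"{'method':<24}{self.config.method}",
            f"{'modality':<24}{mode.modality.value}",
            f"{'window (bp)':<24}{mode.window if mode.window else '-'}",
            f"{'p-value threshold':<24}{self.config.effective_p_max or '-'}",
            f"{'samples (n)':<24}{d.n}",
            f"{'covariates (m)':<24}{d.covariates.m}",
            f"{'genes':<24}{d.expression.n_loci}",
            f"{'CpG loci':<24}{d.methylation.n_loci}",
            f"{'pairs tested':<24}{s.pairs_tested}",
            f"{'pairs reported':<24}{self.n_reported}",
            f"{'degenerate loci':<24}{s.degenerate_loci}",
            f"{'device':<24}{s.device}",
            "-" * 56,
        ]
        if len(self.frame):
            with pd.option_context("display.float_format", "{:.4g}".format):
                head = self.top(min(10, len(self.frame)))
                lines.append(head.to_string(index=False))
        else:
            lines.append("(no pairs passed the threshold)")
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Effect size vs -log10(p) scatter for the reported pairs."""
        import matplotlib.pyplot as plt  # noqa: PLC0415 - optional dependency

        if ax is None:
            _, ax = plt.subplots()
        p = self.frame["p"].to_numpy()
        with np.errstate(divide="ignore"):
            neglog = -np.log10(np.clip(p, 1e-300, None))
        ax.scatter(self.frame["est"], neglog, s=8, alpha=0.6)
        ax.set_xlabel("methylation coefficient" if self.config.method == "mlr"
                      else "Pearson r")
        ax.set_ylabel(r"$-\log_{10} p$")
        ax.set_title(f"{self.config.mode.modality.value} eQTM associations")
        return ax
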