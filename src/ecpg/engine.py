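"""End-to-end orchestration: device selection, chunk planning, block dispatch.

The gene x CpG grid is tiled into blocks sized to a memory budget; each
block is fitted by the batched regression core under the modality's pair
mask, and passing rows are streamed to the result writer. Results are
independent of the tiling: every statistic for a pair is computed from
that pair's rows alone, with a fixed reduction order, so any chunk
decomposition produces the identical output file (asserted in tests).
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from threadpoolctl import threadpool_limits

from .errors import ConfigurationError, DeviceError, EcpgError
from .io import (BASE_RESULT_FIELDS, AlignedDataset, LociAnnotation,
                 ResultWriter)
from .mapping import MappingMode, PairSelection, enumerate_pairs
from .regress import batched_mlr, pearson_block, validate_design

logger = logging.getLogger(__name__)

#: Working-set cost model constants (see docs/methods.md): number of
#: result-sized temporaries per block and a safety factor for allocator
#: overhead and short-lived copies.
RESULT_MATRICES_PER_BLOCK = 6
OVERHEAD_FACTOR = 1.5

#: Default per-run memory budget for automatic chunk sizing: 2 GiB.
DEFAULT_MEMORY_BUDGET = 2 << 30

#: Cap on the automatic CpG chunk size.
AUTO_CPG_CHUNK_CAP = 100_000


@dataclass(frozen=True)
class DeviceDescriptor:
    kind: Literal["cpu", "accelerator"]
    cpu_threads: int = 1

    def __str__(self) -> str:
        if self.kind == "cpu":
            return f"cpu({self.cpu_threads} threads)"
        return "accelerator"


def _accelerator_available() -> bool:
    try:
        import torch  # noqa: PLC0415 - optional accelerator probe
    except ImportError:
        return False
    try:
        return bool(torch.cuda.is_available())
    except Exception:  # noqa: BLE001 - a broken CUDA stack means "no device"
        return False


def select_device(request: str = "auto", cpu_threads: int = 1) -> DeviceDescriptor:
    """Resolve a device request to a concrete descriptor.

    ``auto`` picks an accelerator when one is detected and falls back to
    the CPU otherwise; ``cpu`` always selects the CPU; ``accelerator``
    raises DeviceError when none is present.
    """
    if cpu_threads < 1:
        raise ConfigurationError(f"cpu_threads must be >= 1, got {cpu_threads}")
    if request == "cpu":
        return DeviceDescriptor("cpu", cpu_threads)
    if request == "accelerator":
        if not _accelerator_available():
            raise DeviceError("accelerator requested but no CUDA device is available")
        return DeviceDescriptor("accelerator")
    if request == "auto":
        if _accelerator_available():
            return DeviceDescriptor("accelerator")
        return DeviceDescriptor("cpu", cpu_threads)
    raise ConfigurationError(f"unknown device request {request!r}")


def block_working_set_bytes(n_genes: int, n_cpgs: int, n_samples: int,
                            m_covariates: int, bytes_per_value: int) -> int:
    """Modeled peak bytes for one gene-block x CpG-block computation.

    cost = OVERHEAD * bpv * (2*G*n + 2*C*n + (m+1)*n + K*G*C)

    counting the raw and residualized input blocks, the design, and K
    result-sized G x C temporaries (estimates, standard errors, t, p,
    cross-products, residual sums of squares).
    """
    raw = (2 * n_genes * n_samples + 2 * n_cpgs * n_samples
           + (m_covariates + 1) * n_samples
           + RESULT_MATRICES_PER_BLOCK * n_genes * n_cpgs)
    return int(OVERHEAD_FACTOR * bytes_per_value * raw)


def estimate_genes_per_chunk(n_samples: int, n_cpgs_per_block: int,
                             m_covariates: int, bytes_per_value: int,
                             memory_budget: int) -> int:
    """Largest gene-block size whose modeled working set fits the budget.

    Inverts the closed-form cost model of ``block_working_set_bytes``;
    raises ConfigurationError (reporting the minimum viable budget) when
    even a single gene does not fit.
    """
    for name, v in (("n_samples", n_samples), ("n_cpgs_per_block", n_cpgs_per_block),
                    ("bytes_per_value", bytes_per_value),
                    ("memory_budget", memory_budget)):
        if v <= 0:
            raise ConfigurationError(f"{name} must be positive, got {v}")
    if m_covariates < 0:
        raise ConfigurationError(f"m_covariates must be >= 0, got {m_covariates}")
    fixed = (2 * n_cpgs_per_block * n_samples + (m_covariates + 1) * n_samples)
    per_gene = 2 * n_samples + RESULT_MATRICES_PER_BLOCK * n_cpgs_per_block
    budget_units = memory_budget / (OVERHEAD_FACTOR * bytes_per_value)
    genes = int((budget_units - fixed) // per_gene)
    if genes < 1:
        minimum = block_working_set_bytes(1, n_cpgs_per_block, n_samples,
                                          m_covariates, bytes_per_value)
        raise ConfigurationError(
            f"memory budget {memory_budget} B cannot hold one gene against "
            f"{n_cpgs_per_block} CpGs; minimum budget is {minimum} B"
        )
    return genes


@dataclass(frozen=True)
class ChunkPlan:
    """Block boundaries tiling the gene x CpG grid exactly once."""

    gene_bounds: tuple[tuple[int, int], ...]
    cpg_bounds: tuple[tuple[int, int], ...]
    n_samples: int
    m_covariates: int
    bytes_per_value: int

    @property
    def n_blocks(self) -> int:
        return len(self.gene_bounds) * len(self.cpg_bounds)

    def block_estimate(self, gi: int, ci: int) -> int:
        g0, g1 = self.gene_bounds[gi]
        c0, c1 = self.cpg_bounds[ci]
        return block_working_set_bytes(g1 - g0, c1 - c0, self.n_samples,
                                       self.m_covariates, self.bytes_per_value)

    @property
    def max_block_estimate(self) -> int:
        return max(self.block_estimate(gi, ci)
                   for gi in range(len(self.gene_bounds))
                   for ci in range(len(self.cpg_bounds)))


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end mapping run needs beyond the data."""

    mode: MappingMode
    method: Literal["mlr", "pearson"] = "mlr"
    device_request: Literal["auto", "cpu", "accelerator"] = "auto"
    cpu_threads: int = 1
    gene_chunk: int | Literal["auto"] | None = None  # None = all genes in one block
    cpg_chunk: int | Literal["auto"] | None = None
    memory_budget: int = DEFAULT_MEMORY_BUDGET
    p_max: float | None = None         # overrides the mode's default when set
    no_filter: bool = False            # report every pair, ignoring p_max defaults
    columns: tuple[str, ...] = BASE_RESULT_FIELDS
    with_covariate_stats: bool = False
    output_path: str | os.PathLike | None = None

    def __post_init__(self) -> None:
        if self.method not in ("mlr", "pearson"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.memory_budget <= 0:
            raise ConfigurationError("memory_budget must be positive")
        if self.cpu_threads < 1:
            raise ConfigurationError("cpu_threads must be >= 1")
        for chunk, name in ((self.gene_chunk, "gene_chunk"),
                            (self.cpg_chunk, "cpg_chunk")):
            if chunk is not None and chunk != "auto" and chunk < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {chunk}")

    @property
    def effective_p_max(self) -> float | None:
        if self.no_filter:
            return None
        return self.p_max if self.p_max is not None else self.mode.p_max


def _bounds(total: int, chunk: int) -> tuple[tuple[int, int], ...]:
    return tuple((start, min(start + chunk, total))
                 for start in range(0, total, chunk))


def plan_chunks(n_genes: int, n_cpgs: int, config: RunConfig, *,
                n_samples: int, m_covariates: int,
                bytes_per_value: int = 8) -> ChunkPlan:
    """Resolve chunk settings into explicit block boundaries.

    Explicit sizes are honored verbatim; ``auto`` sizes are filled from
    the closed-form memory model; unset sizes take the whole axis.
    """
    if n_genes < 1 or n_cpgs < 1:
        raise ConfigurationError("locus counts must be positive")
    cpg_chunk = config.cpg_chunk
    if cpg_chunk == "auto":
        cpg_chunk = min(n_cpgs, AUTO_CPG_CHUNK_CAP)
    elif cpg_chunk is None:
        cpg_chunk = n_cpgs
    gene_chunk = config.gene_chunk
    if gene_chunk == "auto":
        gene_chunk = min(n_genes, estimate_genes_per_chunk(
            n_samples, min(cpg_chunk, n_cpgs), m_covariates, bytes_per_value,
            config.memory_budget))
    elif gene_chunk is None:
        gene_chunk = n_genes
    return ChunkPlan(_bounds(n_genes, min(gene_chunk, n_genes)),
                     _bounds(n_cpgs, min(cpg_chunk, n_cpgs)),
                     n_samples, m_covariates, bytes_per_value)


@dataclass
class RunSummary:
    """Accounting for one completed mapping run."""

    pairs_tested: int = 0
    rows_written: int = 0
    degenerate_loci: int = 0
    n_blocks: int = 0
    device: str = "cpu"
    elapsed_seconds: float = 0.0

    def __str__(self) -> str:
        return (f"pairs tested: {self.pairs_tested}; rows written: "
                f"{self.rows_written}; degenerate loci: {self.degenerate_loci}; "
                f"blocks: {self.n_blocks}; device: {self.device}; "
                f"elapsed: {self.elapsed_seconds:.2f}s")


def _available_fields(config: RunConfig,
                      covariate_names: Sequence[str]) -> tuple[str, ...]:
    fields = list(BASE_RESULT_FIELDS)
    if config.with_covariate_stats and config.method == "mlr":
        for name in ("intercept",) + tuple(f"cov_{c}" for c in covariate_names):
            fields += [f"{name}_est", f"{name}_se", f"{name}_t", f"{name}_p"]
    return tuple(fields)


def run_mapping(dataset: AlignedDataset,
                gene_annot: LociAnnotation | None,
                cpg_annot: LociAnnotation | None,
                config: RunConfig) -> RunSummary:
    """Execute a full eQTM mapping run and stream results to disk.

    For every pair selected by the modality exactly one association is
    computed (MLR or Pearson); rows with p strictly below the effective
    threshold (when one is set) are written in gene-major, CpG-minor
    order. A failing block aborts the run, removes the partial output
    file, and reports the block coordinates.
    """
    if config.output_path is None:
        raise ConfigurationError("config.output_path is required")
    start_time = time.perf_counter()
    device = select_device(config.device_request, config.cpu_threads)
    expr, meth = dataset.expression, dataset.methylation
    design = validate_design(dataset.covariates) if config.method == "mlr" else None
    selection = enumerate_pairs(gene_annot, cpg_annot, expr.locus_ids,
                                meth.locus_ids, config.mode)
    plan = plan_chunks(expr.n_loci, meth.n_loci, config,
                       n_samples=dataset.n,
                       m_covariates=dataset.covariates.m)
    logger.info("device=%s plan=%dx%d blocks (max modeled working set %d B)",
                device, len(plan.gene_bounds), len(plan.cpg_bounds),
                plan.max_block_estimate)

    fields = _available_fields(config, dataset.covariates.covariate_names)
    summary = RunSummary(n_blocks=plan.n_blocks, device=str(device))
    degenerate: set[str] = set()
    writer = ResultWriter(config.output_path, config.columns,
                          available_fields=fields,
                          p_max=config.effective_p_max)
    try:
        with threadpool_limits(limits=device.cpu_threads):
            for gi, (g0, g1) in enumerate(plan.gene_bounds):
                mask_full = selection.mask_for_genes(slice(g0, g1))
                gene_rows = _GeneBlockBuffer()
                for ci, (c0, c1) in enumerate(plan.cpg_bounds):
                    try:
                        _compute_block(expr, meth, design, config, g0, g1,
                                       c0, c1, mask_full[:, c0:c1],
                                       summary, degenerate, gene_rows)
                    except EcpgError:
                        raise
                    except Exception as exc:  # noqa: BLE001
                        raise EcpgError(
                            f"block (gene block {gi}: [{g0},{g1}), CpG block "
                            f"{ci}: [{c0},{c1})) failed: {exc}"
                        ) from exc
                    logger.debug("block (%d,%d) done", gi, ci)
                summary.rows_written += gene_rows.flush(writer, expr.locus_ids,
                                                        meth.locus_ids, g0)
    except BaseException:
        writer.close()
        if os.path.exists(config.output_path):
            os.remove(config.output_path)
        raise
    writer.close()
    summary.degenerate_loci = len(degenerate)
    summary.elapsed_seconds = time.perf_counter() - start_time
    logger.info("%s", summary)
    return summary


class _GeneBlockBuffer:
    """Collects masked block results so rows emit gene-major, CpG-minor."""

    def __init__(self) -> None:
        self._parts: list[tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]] = []

    def add(self, g_local: np.ndarray, c_global: np.ndarray,
            fields: dict[str, np.ndarray]) -> None:
        self._parts.append((g_local, c_global, fields))

    def flush(self, writer: ResultWriter, gene_ids: Sequence[str],
              cpg_ids: Sequence[str], g_offset: int) -> int:
        if not self._parts:
            return 0
        g = np.concatenate([p[0] for p in self._parts])
        c = np.concatenate([p[1] for p in self._parts])
        fields = {k: np.concatenate([p[2][k] for p in self._parts])
                  for k in self._parts[0][2]}
        order = np.lexsort((c, g))
        genes = [gene_ids[g_offset + gi] for gi in g[order]]
        cpgs = [cpg_ids[cj] for cj in c[order]]
        ordered = {k: v[order] for k, v in fields.items()}
        return writer.write_rows(genes, cpgs, ordered, ordered["p"])


def _compute_block(expr, meth, design, config: RunConfig, g0, g1, c0, c1,
                   mask: np.ndarray, summary: RunSummary,
                   degenerate: set[str], buffer: _GeneBlockBuffer) -> None:
    summary.pairs_tested += int(mask.sum())
    if not mask.any():
        return
    gene_ids = expr.locus_ids[g0:g1]
    cpg_ids = meth.locus_ids[c0:c1]
    expr_block = expr.values[g0:g1]
    meth_block = meth.values[c0:c1]
    if config.method == "mlr":
        block = batched_mlr(expr_block, meth_block, design, gene_ids, cpg_ids,
                            with_covariate_stats=config.with_covariate_stats)
    else:
        block = pearson_block(expr_block, meth_block, gene_ids, cpg_ids)
    nan_cols = np.isnan(block.p).all(axis=0)
    degenerate.update(cpg_ids[j] for j in np.nonzero(nan_cols)[0])
    if config.method == "pearson":
        nan_rows = np.isnan(block.p).all(axis=1)
        degenerate.update(gene_ids[i] for i in np.nonzero(nan_rows)[0])
    g_local, c_local = np.nonzero(mask)
    fields: dict[str, np.ndarray] = {
        "est": block.est[mask], "se": block.se[mask],
        "t": block.t[mask], "p": block.p[mask],
    }
    if block.extra:
        for key, matrix in block.extra.items():
            fields[key] = matrix[mask]
    buffer.add(g_local, c_local + c0, fields)
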