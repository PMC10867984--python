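"""Readers, writers and sample alignment for locus-by-sample matrices.

Expression and methylation matrices are CSV with samples in columns and
loci in rows; the covariate table is CSV with covariates in columns and
samples in rows; genomic annotations are BED (0-based, half-open, name in
column 4, optional strand in column 6).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: Numeric serialization format for result files: shortest representation
#: that round-trips an IEEE double exactly.
FLOAT_FORMAT = "%.17g"

#: Result fields a caller may select for output, beyond the id columns.
BASE_RESULT_FIELDS = ("est", "se", "t", "p")


@dataclass(frozen=True)
class LocusMatrix:
    """A labeled numeric matrix of loci (rows) by samples (columns)."""

    locus_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (loci, samples), float64

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValueError("value matrix shape does not match id lists")
        _check_unique(self.locus_ids, "locus id")
        _check_unique(self.sample_ids, "sample id")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "LocusMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return LocusMatrix(self.locus_ids, tuple(sample_ids),
                           np.ascontiguousarray(self.values[:, cols]))


@dataclass(frozen=True)
class CovariateTable:
    """Samples (rows) by covariates (columns); m = number of covariates."""

    sample_ids: tuple[str, ...]
    covariate_names: tuple[str, ...]
    values: np.ndarray  # shape (samples, covariates), float64

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.covariate_names)):
            raise ValueError("value matrix shape does not match id lists")
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.covariate_names, "covariate name")

    @property
    def m(self) -> int:
        return len(self.covariate_names)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CovariateTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return CovariateTable(tuple(sample_ids), self.covariate_names,
                              np.ascontiguousarray(self.values[rows, :]))


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str  # '+', '-' or '.' (unknown)


@dataclass(frozen=True)
class LociAnnotation:
    """Mapping locus id -> genomic interval, preserving file order."""

    records: Mapping[str, BedRecord]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.records

    def __getitem__(self, locus_id: str) -> BedRecord:
        return self.records[locus_id]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AlignedDataset:
    """Expression, methylation and covariates on one shared sample order."""

    expression: LocusMatrix
    methylation: LocusMatrix
    covariates: CovariateTable
    n: int = field(init=False)

    def __post_init__(self) -> None:
        sids = self.expression.sample_ids
        if self.methylation.sample_ids != sids or self.covariates.sample_ids != sids:
            raise AlignmentError("components do not share one sample order")
        if len(sids) < 3:
            raise AlignmentError(f"only {len(sids)} shared samples; need >= 3")
        object.__setattr__(self, "n", len(sids))


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise FormatError(f"duplicate {what}: {i!r}")
            seen.add(i)


def _check_header_duplicates(path) -> None:
    import csv

    with open(path, newline="") as handle:
        header = next(csv.reader(handle), None)
    if not header:
        raise FormatError(f"{path}: empty file")
    names = header[1:]
    if len(set(names)) != len(names):
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise FormatError(f"{path}: duplicate column id: {name!r}")
            seen.add(name)


def _read_csv_frame(path, index_what: str) -> pd.DataFrame:
    # the C parser's round_trip mode preserves every bit of a serialized
    # double, keeping write->read an exact identity
    _check_header_duplicates(path)
    try:
        frame = pd.read_csv(path, index_col=0, header=0,
                            float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate {index_what}: {dup!r}")
    return frame


def _to_numeric(frame: pd.DataFrame, path,
                drop_missing: bool) -> tuple[pd.DataFrame, np.ndarray]:
    for col in frame.columns:
        if frame[col].dtype == object:
            converted = np.empty(len(frame), dtype=np.float64)
            for i, cell in enumerate(frame[col]):
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    converted[i] = np.nan
                    continue
                try:
                    converted[i] = float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at row "
                        f"{frame.index[i]!r}, column {col!r}"
                    ) from None
            frame[col] = converted
    numeric = frame.astype(np.float64)
    missing = numeric.isna()
    if missing.to_numpy().any():
        if not drop_missing:
            r, c = np.argwhere(missing.to_numpy())[0]
            raise FormatError(
                f"{path}: missing value at row {frame.index[r]!r}, column "
                f"{frame.columns[c]!r} (pass drop_missing=True to drop such loci)"
            )
        keep = ~missing.any(axis=1)
        for locus in numeric.index[~keep]:
            logger.warning("dropping locus %r: missing values", locus)
        numeric = numeric.loc[keep]
        if numeric.shape[0] == 0:
            raise FormatError(f"{path}: all rows dropped for missing values")
    return numeric, numeric.to_numpy(dtype=np.float64)


def read_locus_matrix(path, *, drop_missing: bool = False) -> LocusMatrix:
    """Read a loci-by-samples CSV (header = sample ids, first column = locus ids).

    Missing cells are a hard error unless ``drop_missing`` is set, in which
    case rows containing them are dropped with a log line each.
    """
    frame = _read_csv_frame(path, "locus id")
    numeric, values = _to_numeric(frame, path, drop_missing)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite value in matrix")
    return LocusMatrix(tuple(numeric.index), tuple(numeric.columns), values)


def read_covariates(path) -> CovariateTable:
    """Read a samples-by-covariates CSV (header = covariate names).

    A file whose header has zero covariate columns after the sample-id
    column yields m = 0 and an intercept-only model downstream. Covariates
    must be numeric; categorical ones are pre-encoded by the user.
    """
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    if not lines:
        raise FormatError(f"{path}: empty file")
    if lines[0].strip(' ,"') == "":  # header with no covariate columns
        sample_ids = tuple(s.strip() for s in lines[1:] if s.strip())
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}: duplicate sample id")
        if not sample_ids:
            raise FormatError(f"{path}: no samples")
        return CovariateTable(sample_ids, (),
                              np.empty((len(sample_ids), 0), dtype=np.float64))
    frame = _read_csv_frame(path, "sample id")
    _, values = _to_numeric(frame, path, drop_missing=False)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite covariate value")
    return CovariateTable(tuple(frame.index), tuple(frame.columns), values)


def read_bed(path) -> LociAnnotation:
    """Read a BED file into a LociAnnotation.

    Requires >= 4 whitespace/tab-delimited columns (chrom, start, end,
    name); column 6, when present, is the strand. Coordinates are 0-based
    half-open per the BED standard; empty intervals are rejected.
    """
    records: dict[str, BedRecord] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            if not chrom:
                raise FormatError(f"{path}:{lineno}: empty chromosome name")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if name in records:
                raise FormatError(f"{path}:{lineno}: duplicate name {name!r}")
            records[name] = BedRecord(chrom, start, end, strand)
    return LociAnnotation(records)


def align_samples(expression: LocusMatrix, methylation: LocusMatrix,
                  covariates: CovariateTable) -> AlignedDataset:
    """Intersect the three sample-id sets, ordered as in the expression matrix.

    Constant covariate columns are rejected after alignment: they would
    collide with the implicit intercept of the regression design.
    """
    meth_set = set(methylation.sample_ids)
    cov_set = set(covariates.sample_ids)
    shared = [s for s in expression.sample_ids if s in meth_set and s in cov_set]
    if not shared:
        raise AlignmentError("no samples shared by expression, methylation and covariates")
    if len(shared) < 3:
        raise AlignmentError(f"only {len(shared)} shared samples; need >= 3")
    dropped = (len(expression.sample_ids) - len(shared),
               len(methylation.sample_ids) - len(shared),
               len(covariates.sample_ids) - len(shared))
    if any(dropped):
        logger.info("dropped samples (expression=%d, methylation=%d, covariates=%d)",
                    *dropped)
    cov = covariates.subset_samples(shared)
    for j, name in enumerate(cov.covariate_names):
        col = cov.values[:, j]
        if np.ptp(col) == 0.0:
            raise AlignmentError(
                f"covariate {name!r} is constant after sample alignment; "
                "it collides with the implicit intercept"
            )
    return AlignedDataset(expression.subset_samples(shared),
                          methylation.subset_samples(shared), cov)


def write_locus_matrix(matrix: LocusMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, index=list(matrix.locus_ids),
                         columns=list(matrix.sample_ids))
    frame.to_csv(path, float_format=FLOAT_FORMAT)


def write_covariates(table: CovariateTable, path) -> None:
    frame = pd.DataFrame(table.values, index=list(table.sample_ids),
                         columns=list(table.covariate_names))
    frame.to_csv(path, float_format=FLOAT_FORMAT)


def write_bed(annotation: LociAnnotation, path) -> None:
    with open(path, "w") as handle:
        for name, rec in annotation.records.items():
            handle.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t.\t{rec.strand}\n")


class ResultWriter:
    """Stream (gene, CpG) association rows to a CSV file with p filtering.

    A row passes the filter iff ``p_max`` is unset or the row's p-value is
    strictly below it; rows with a NaN p-value (degenerate loci) never pass
    a filter but are written when no filter is set. Numeric cells use a
    shortest-exact double serialization so files are byte-comparable
    across chunk decompositions.
    """

    def __init__(self, path, columns: Sequence[str],
                 available_fields: Sequence[str] = BASE_RESULT_FIELDS,
                 p_max: float | None = None) -> None:
        unknown = [c for c in columns if c not in available_fields]
        if unknown:
            raise ConfigurationError(
                f"unknown result column(s) {unknown}; available: {list(available_fields)}"
            )
        if p_max is not None and not (0.0 < p_max <= 1.0):
            raise ConfigurationError(f"p_max must be in (0, 1], got {p_max}")
        self.path = path
        self.columns = tuple(columns)
        self.p_max = p_max
        self.rows_written = 0
        self._handle = open(path, "w")
        self._handle.write(",".join(("gene_id", "cpg_id") + self.columns) + "\n")

    def write_rows(self, gene_ids: Iterable[str], cpg_ids: Iterable[str],
                   fields: Mapping[str, np.ndarray], p: np.ndarray) -> int:
        """Write one flattened block; returns the number of rows written."""
        written = 0
        cells = [np.asarray(fields[c]) for c in self.columns]
        p = np.asarray(p)
        out = []
        for i, (g, c) in enumerate(zip(gene_ids, cpg_ids)):
            pi = p[i]
            if self.p_max is not None and not (pi < self.p_max):
                continue
            row = [g, c]
            for cell in cells:
                v = cell[i]
                row.append("nan" if math.isnan(v) else FLOAT_FORMAT % v)
            out.append(",".join(row))
            written += 1
        if out:
            self._handle.write("\n".join(out) + "\n")
        self.rows_written += written
        return written

    def close(self) -> None:
        self._handle.close()

    def __enter__(self) -> "ResultWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_results(results, path, columns: Sequence[str] = BASE_RESULT_FIELDS,
                  p_max: float | None = None) -> int:
    """Write an iterable of (gene_id, cpg_id, {field: value}) records.

    Returns the number of rows written (those with p strictly below
    ``p_max``, or all rows when no threshold is given).
    """
    results = list(results)
    with ResultWriter(path, columns, p_max=p_max) as writer:
        if results:
            genes = [r[0] for r in results]
            cpgs = [r[1] for r in results]
            fields = {c: np.array([r[2][c] for r in results], dtype=np.float64)
                      for c in writer.columns}
            p = np.array([r[2]["p"] for r in results], dtype=np.float64)
            writer.write_rows(genes, cpgs, fields, p)
        return writer.rows_written
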