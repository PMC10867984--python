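"""Genomic classification of (gene, CpG) pairs into mapping modalities.

Four modalities are supported, all anchored on the gene's transcript
start site (TSS):

* ``cis``    — CpG within a symmetric window (default 1 Mb) of the TSS,
               same chromosome;
* ``distal`` — CpG outside a window (default 50 kb) of the TSS but on the
               same chromosome;
* ``trans``  — CpG on a different chromosome;
* ``all``    — every pair, no annotation required.

With the default windows (1 Mb cis, 50 kb distal) the cis and distal sets
overlap for distances in (50 kb, 1 Mb]; this follows the window
definitions literally and is intentional. Window boundaries are
inclusive for cis (distance <= window) and exclusive for distal
(distance > window), so the two defaults also partition cleanly whenever
the same window value is used for both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigurationError
from .io import BedRecord, LociAnnotation

logger = logging.getLogger(__name__)

CIS_WINDOW_DEFAULT = 1_000_000
DISTAL_WINDOW_DEFAULT = 50_000
TRANS_P_MAX_DEFAULT = 1e-5


class Modality(str, Enum):
    CIS = "cis"
    DISTAL = "distal"
    TRANS = "trans"
    ALL = "all"


@dataclass(frozen=True)
class MappingMode:
    """A modality plus its window and default output p-value threshold."""

    modality: Modality
    window: int | None = None
    p_max: float | None = None

    def __post_init__(self) -> None:
        modality = Modality(self.modality)
        object.__setattr__(self, "modality", modality)
        if self.window is None:
            default = {Modality.CIS: CIS_WINDOW_DEFAULT,
                       Modality.DISTAL: DISTAL_WINDOW_DEFAULT}.get(modality)
            object.__setattr__(self, "window", default)
        if self.window is not None and self.window <= 0:
            raise ConfigurationError(f"window must be positive, got {self.window}")
        if self.p_max is None and modality in (Modality.TRANS, Modality.ALL):
            object.__setattr__(self, "p_max", TRANS_P_MAX_DEFAULT)
        if self.p_max is not None and not (0.0 < self.p_max <= 1.0):
            raise ConfigurationError(f"p_max must be in (0, 1], got {self.p_max}")

    @property
    def needs_annotation(self) -> bool:
        return self.modality is not Modality.ALL


def tss_of(record: BedRecord) -> tuple[str, int]:
    """Transcript start site of a gene interval.

    '+' or unknown strand anchors at ``start``; '-' strand at ``end - 1``,
    the last base of the half-open interval.
    """
    pos = record.end - 1 if record.strand == "-" else record.start
    return record.chrom, pos


def cpg_position(record: BedRecord) -> tuple[str, int]:
    """Genomic position of a CpG probe: the interval start.

    CpG probes are single-base intervals by convention; a wider interval
    is accepted with a warning and anchored at its start.
    """
    if record.end - record.start > 1:
        logger.warning("CpG interval %s:%d-%d wider than one base; using start",
                       record.chrom, record.start, record.end)
    return record.chrom, record.start


def pair_in_mode(gene: BedRecord, cpg: BedRecord, mode: MappingMode) -> bool:
    """Whether one (gene, CpG) pair belongs to the mode's pair set."""
    if mode.modality is Modality.ALL:
        return True
    g_chrom, g_pos = tss_of(gene)
    c_chrom, c_pos = cpg_position(cpg)
    if mode.modality is Modality.TRANS:
        return g_chrom != c_chrom
    if g_chrom != c_chrom:
        return False
    distance = abs(c_pos - g_pos)
    if mode.modality is Modality.CIS:
        return distance <= mode.window
    return distance > mode.window  # DISTAL


@dataclass(frozen=True)
class PairSelection:
    """Lazy per-gene CpG masks over an ordered gene x CpG grid."""

    gene_ids: tuple[str, ...]
    cpg_ids: tuple[str, ...]
    mode: MappingMode
    _gene_chrom: np.ndarray | None   # object arrays; None entry = unannotated
    _gene_pos: np.ndarray | None
    _cpg_chrom: np.ndarray | None
    _cpg_pos: np.ndarray | None

    def mask_for_genes(self, gene_slice: slice) -> np.ndarray:
        """Boolean (genes-in-slice x all-CpGs) membership mask."""
        n_g = len(range(*gene_slice.indices(len(self.gene_ids))))
        n_c = len(self.cpg_ids)
        if self.mode.modality is Modality.ALL:
            return np.ones((n_g, n_c), dtype=bool)
        g_chrom = self._gene_chrom[gene_slice]
        g_pos = self._gene_pos[gene_slice]
        g_ok = np.array([c is not None for c in g_chrom])
        c_ok = np.array([c is not None for c in self._cpg_chrom])
        same = (g_chrom[:, None] == self._cpg_chrom[None, :]) \
            & g_ok[:, None] & c_ok[None, :]
        if self.mode.modality is Modality.TRANS:
            return ~same & g_ok[:, None] & c_ok[None, :]
        dist = np.abs(np.where(c_ok, self._cpg_pos, 0)[None, :].astype(np.int64)
                      - np.where(g_ok, g_pos, 0)[:, None].astype(np.int64))
        if self.mode.modality is Modality.CIS:
            return same & (dist <= self.mode.window)
        return same & (dist > self.mode.window)

    def iter_gene_blocks(self, block: int) -> Iterator[tuple[slice, np.ndarray]]:
        for start in range(0, len(self.gene_ids), block):
            sl = slice(start, min(start + block, len(self.gene_ids)))
            yield sl, self.mask_for_genes(sl)

    @property
    def count(self) -> int:
        """Total selected pairs, computed without materializing pair lists."""
        total = 0
        for _, mask in self.iter_gene_blocks(512):
            total += int(mask.sum())
        return total


def enumerate_pairs(gene_annot: LociAnnotation | None,
                    cpg_annot: LociAnnotation | None,
                    gene_ids: Sequence[str], cpg_ids: Sequence[str],
                    mode: MappingMode) -> PairSelection:
    """Build the pair selection for a mode over ordered locus id lists.

    Loci missing from the annotation are excluded from cis/distal/trans
    (logged once per locus); in ``all`` mode annotations are ignored and
    every pair is selected. Ordering is gene-major, CpG input order.
    """
    if not gene_ids or not cpg_ids:
        raise ConfigurationError("gene and CpG id lists must be nonempty")
    if mode.modality is Modality.ALL:
        return PairSelection(tuple(gene_ids), tuple(cpg_ids), mode,
                             None, None, None, None)
    if gene_annot is None or cpg_annot is None:
        raise ConfigurationError(
            f"{mode.modality.value} mode requires gene and CpG annotations"
        )

    def positions(ids, annot, anchor, what):
        chroms = np.empty(len(ids), dtype=object)
        pos = np.zeros(len(ids), dtype=np.int64)
        for i, locus in enumerate(ids):
            if locus not in annot:
                logger.warning("%s locus %r missing from annotation; "
                               "excluded from %s mode", what, locus,
                               mode.modality.value)
                chroms[i] = None
                continue
            chroms[i], pos[i] = anchor(annot[locus])
        return chroms, pos

    g_chrom, g_pos = positions(gene_ids, gene_annot, tss_of, "gene")
    c_chrom, c_pos = positions(cpg_ids, cpg_annot, cpg_position, "CpG")
    g_set = {c for c in g_chrom if c is not None}
    c_set = {c for c in c_chrom if c is not None}
    if g_set and c_set and not (g_set & c_set):
        logger.warning("gene and CpG annotations share no chromosome names "
                       "(%s vs %s); check naming conventions",
                       sorted(g_set)[:3], sorted(c_set)[:3])
    return PairSelection(tuple(gene_ids), tuple(cpg_ids), mode,
                         g_chrom, g_pos, c_chrom, c_pos)
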