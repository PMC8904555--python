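"""Quality-control filtering of the count matrix and dataset composition.

Cells are kept when they have at least ``min_reads_per_cell`` total reads
spread over at least ``min_genes_per_cell`` distinct genes; genes are kept
when at least ``min_reads_per_gene`` reads map to them from at least
``min_cells_per_gene`` distinct cells.  Both rules are inclusive ("at
least"), applied in a single pass each, cells first — no iteration to a
fixed point.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .matrix import CellGeneMatrix

log = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "filter_cells",
    "filter_genes",
    "apply_qc",
    "qc_summary",
    "biotype_composition",
    "compare_gene_sets",
]


@dataclasses.dataclass
class QCThresholds:
    """Inclusive minimums for cell- and gene-level filtering."""

    min_reads_per_cell: int = 10_000
    min_genes_per_cell: int = 300
    min_reads_per_gene: int = 100
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


def filter_cells(matrix: CellGeneMatrix, thresholds: QCThresholds | None = None) -> CellGeneMatrix:
    """Keep cells with total reads and detected genes above the thresholds."""
    t = thresholds or QCThresholds()
    reads = matrix.counts.sum(axis=1)
    genes_detected = (matrix.counts > 0).sum(axis=1)
    keep = (reads >= t.min_reads_per_cell) & (genes_detected >= t.min_genes_per_cell)
    if not keep.any():
        log.warning("cell filter removed every cell")
    return matrix.subset_cells(keep)


def filter_genes(matrix: CellGeneMatrix, thresholds: QCThresholds | None = None) -> CellGeneMatrix:
    """Keep genes with enough reads contributed by enough distinct cells."""
    t = thresholds or QCThresholds()
    reads = matrix.counts.sum(axis=0)
    cells_expressing = (matrix.counts > 0).sum(axis=0)
    keep = (reads >= t.min_reads_per_gene) & (cells_expressing >= t.min_cells_per_gene)
    if not keep.any():
        log.warning("gene filter removed every gene")
    return matrix.subset_genes(keep)


def apply_qc(matrix: CellGeneMatrix, thresholds: QCThresholds | None = None) -> CellGeneMatrix:
    """Cells first, then genes, one pass each."""
    return filter_genes(filter_cells(matrix, thresholds), thresholds)


def qc_summary(raw: CellGeneMatrix, filtered: CellGeneMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample dispensed / post-QC cell counts and the per-cell
    detected-gene distribution of the filtered matrix.

    Returns ``(table, genes_per_cell)`` where ``table`` has one row per
    sample with columns ``n_cells_raw`` and ``n_cells_postqc``.
    """
    raw_counts = raw.sample_of.value_counts()
    post_counts = filtered.sample_of.value_counts()
    extra = post_counts.index.difference(raw_counts.index)
    if len(extra):
        raise ConsistencyError(f"samples in filtered but not raw data: {list(extra)}")
    table = pd.DataFrame(
        {
            "n_cells_raw": raw_counts,
            "n_cells_postqc": post_counts.reindex(raw_counts.index, fill_value=0),
        }
    ).loc[list(dict.fromkeys(raw.sample_of))]
    table.index.name = "sample"
    genes_per_cell = pd.Series(
        (filtered.counts > 0).sum(axis=1), index=filtered.cell_ids, name="genes_detected"
    )
    return table, genes_per_cell


def biotype_composition(matrix: CellGeneMatrix, biotype_of: pd.Series) -> pd.DataFrame:
    """Percentage of expressed genes per RNA biotype, per sample.

    A gene counts as expressed in a sample when it has at least one read in
    that sample's cells.  Genes absent from ``biotype_of`` fall into the
    ``unannotated`` category.  Rows sum to 100 (up to rounding).
    """
    biotypes = biotype_of.reindex(matrix.gene_ids).fillna("unannotated")
    rows = {}
    for sample in matrix.samples:
        mask = (matrix.sample_of == sample).to_numpy()
        expressed = matrix.counts[mask, :].sum(axis=0) > 0
        tally = biotypes[expressed].value_counts()
        rows[sample] = 100.0 * tally / tally.sum() if tally.sum() else tally.astype(float)
    out = pd.DataFrame(rows).T.fillna(0.0)
    out.index.name = "sample"
    return out


def compare_gene_sets(set_a, set_b) -> dict:
    """Venn-style comparison of two gene-id sets."""
    a, b = set(set_a), set(set_b)
    union = a | b
    n = len(union)
    overlap = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    return {
        "overlap": overlap,
        "a_only": only_a,
        "b_only": only_b,
        "union": n,
        "overlap_fraction": overlap / n if n else 0.0,
        "a_only_fraction": only_a / n if n else 0.0,
        "b_only_fraction": only_b / n if n else 0.0,
    }
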