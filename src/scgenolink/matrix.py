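"""Cell x gene count matrix container and file I/O.

The central object of the pipeline is a read-count matrix from full-length
single-cell RNA-seq (no UMIs: counts are read totals), with every cell
labelled by the biological sample it was dispensed from.  Two on-disk
dialects are supported: a sparse Matrix Market triplet with barcode/feature
sidecar tables (features x barcodes, the convention of most single-cell
tooling) and a dense delimited table (cells x genes).  The cell -> sample
map travels separately as a well-list TSV with columns ``barcode`` and
``sample``, mirroring the dispensing report of nano-well platforms.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import ConsistencyError, FormatError

__all__ = [
    "CellGeneMatrix",
    "read_matrix",
    "write_matrix",
    "read_well_list",
    "write_well_list",
]


@dataclasses.dataclass
class CellGeneMatrix:
    """Integer read counts for cells (rows) by genes (columns).

    Parameters
    ----------
    counts
        Non-negative integer array, one row per cell.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    sample_of
        Series mapping every cell id to its sample label.
    """

    counts: np.ndarray
    cell_ids: pd.Index
    gene_ids: pd.Index
    sample_of: pd.Series

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D cells x genes array")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise FormatError(
                f"id lengths ({len(self.cell_ids)} cells, {len(self.gene_ids)} genes) "
                f"do not match counts shape {self.counts.shape}"
            )
        if self.cell_ids.has_duplicates:
            raise FormatError("duplicate cell ids")
        if self.gene_ids.has_duplicates:
            raise FormatError("duplicate gene ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts must be integers")
            self.counts = as_int
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts must be non-negative")
        self.sample_of = pd.Series(self.sample_of)
        missing = self.cell_ids.difference(self.sample_of.index)
        if len(missing):
            raise ConsistencyError(f"cells without a sample label: {list(missing[:5])}")
        self.sample_of = self.sample_of.reindex(self.cell_ids)

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def samples(self) -> list[str]:
        """Sample labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_of))

    def cells_of(self, sample: str) -> pd.Index:
        return self.cell_ids[(self.sample_of == sample).to_numpy()]

    # ------------------------------------------------------------------
    def subset_cells(self, keep) -> "CellGeneMatrix":
        """Return a new matrix restricted to ``keep`` (bool mask or cell ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.cell_ids.get_indexer(keep)
            if (idx < 0).any():
                raise ConsistencyError("subset references unknown cell ids")
        cells = self.cell_ids[idx]
        return CellGeneMatrix(
            self.counts[idx, :], cells, self.gene_ids, self.sample_of.loc[cells]
        )

    def subset_genes(self, keep) -> "CellGeneMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.gene_ids.get_indexer(keep)
            if (idx < 0).any():
                raise ConsistencyError("subset references unknown gene ids")
        return CellGeneMatrix(
            self.counts[:, idx], self.cell_ids, self.gene_ids[idx], self.sample_of
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.gene_ids)

    def __eq__(self, other) -> bool:  # element-wise identity incl. labels
        if not isinstance(other, CellGeneMatrix):
            return NotImplemented
        return (
            self.cell_ids.equals(other.cell_ids)
            and self.gene_ids.equals(other.gene_ids)
            and np.array_equal(self.counts, other.counts)
            and self.sample_of.equals(other.sample_of)
        )


# ----------------------------------------------------------------------
# well list


def read_well_list(path) -> pd.Series:
    """Read a well-list TSV (columns ``barcode``, ``sample``) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("barcode", "sample"):
        if col not in df.columns:
            raise FormatError(f"well list {path} lacks required column '{col}'")
    return pd.Series(df["sample"].to_numpy(), index=pd.Index(df["barcode"], name="cell_id"))


def write_well_list(sample_of: pd.Series, path) -> None:
    pd.DataFrame({"barcode": sample_of.index, "sample": sample_of.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ----------------------------------------------------------------------
# matrix I/O


def _read_mtx_dir(directory: Path) -> tuple[np.ndarray, pd.Index, pd.Index]:
    mtx = directory / "matrix.mtx"
    barcodes = directory / "barcodes.tsv"
    features = directory / "features.tsv"
    for p in (mtx, barcodes, features):
        if not p.exists():
            raise FormatError(f"missing matrix component: {p}")
    try:
        mat = spio.mmread(mtx)
    except Exception as exc:  # malformed triplets, out-of-range coordinates
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    genes = pd.Index(pd.read_csv(features, sep="\t", header=None)[0].astype(str))
    cells = pd.Index(pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str))
    # features x barcodes on disk -> cells x genes in memory
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx} declares shape {mat.shape} but features.tsv has {len(genes)} rows "
            f"and barcodes.tsv has {len(cells)} rows"
        )
    dense = np.asarray(sparse.coo_matrix(mat).T.todense())
    return dense, cells, genes


def read_matrix(path, well_list=None, sample_of: pd.Series | None = None) -> CellGeneMatrix:
    """Read a count matrix from an MTX directory or a dense CSV file.

    Exactly one of ``well_list`` (path to a barcode/sample TSV) or
    ``sample_of`` (an in-memory mapping) must supply the cell -> sample map.
    """
    path = Path(path)
    if path.is_dir():
        counts, cells, genes = _read_mtx_dir(path)
    else:
        df = pd.read_csv(path, index_col=0)
        counts = df.to_numpy()
        cells = pd.Index(df.index.astype(str))
        genes = pd.Index(df.columns.astype(str))
    if well_list is not None:
        sample_of = read_well_list(well_list)
    if sample_of is None:
        raise ConsistencyError("a well list or sample_of mapping is required")
    return CellGeneMatrix(counts, cells, genes, sample_of)


def write_matrix(matrix: CellGeneMatrix, path, dense: bool = False) -> None:
    """Write to an MTX directory (default) or a dense CSV (``dense=True``)."""
    path = Path(path)
    if dense:
        matrix.to_frame().to_csv(path)
        return
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        path / "matrix.mtx",
        sparse.coo_matrix(matrix.counts.T),  # features x barcodes
        field="integer",
    )
    pd.Series(matrix.gene_ids).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
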