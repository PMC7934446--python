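"""Sparse bin-by-cell matrix I/O.

The on-disk exchange layout mirrors the 10x triplet: a Matrix Market
coordinate file (``matrix.mtx``, integer, rows = bins, columns = cells)
with ``bins.bed`` and ``barcodes.tsv`` sidecars.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp

from .genome import GenomeBins, InputError, read_bins_bed, write_bins_bed

MTX_NAME = "matrix.mtx"
BINS_NAME = "bins.bed"
BARCODES_NAME = "barcodes.tsv"


@dataclass
class BinByCellMatrix:
    """A B x C matrix of non-negative integer read counts.

    Rows are genomic bins, columns are cells; entry (j, i) is the number
    of reads overlapping bin j in cell i.
    """

    counts: sp.csr_matrix
    bins: GenomeBins
    barcodes: list[str]
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise InputError("count matrix has non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InputError("count matrix has negative entries")
        b, c = self.counts.shape
        if b != len(self.bins):
            raise InputError(
                f"matrix has {b} rows but bin annotation has {len(self.bins)}"
            )
        if c != len(self.barcodes):
            raise InputError(
                f"matrix has {c} columns but {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InputError("cell barcodes are not unique")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Per-cell total read counts (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def bin_means(self) -> np.ndarray:
        """Per-bin mean raw count across cells (row sums / C)."""
        return np.asarray(self.counts.sum(axis=1)).ravel() / self.n_cells

    def nonzero_proportions(self) -> np.ndarray:
        """Fraction of cells with a non-zero entry, per bin."""
        return self.counts.getnnz(axis=1) / self.n_cells


@dataclass(frozen=True)
class CellSummary:
    """Per-cell library sizes and zero fractions."""

    library_sizes: np.ndarray
    sparsity_per_cell: np.ndarray
    zero_size_cells: np.ndarray = field(default_factory=lambda: np.array([], int))


def summarize_cells(m: BinByCellMatrix) -> CellSummary:
    """Exact per-cell column sums and zero fractions.

    Cells whose library size is zero are flagged (``zero_size_cells``
    holds their column indices); estimation drops them up front.
    """
    lib = m.library_sizes()
    nnz_per_cell = m.counts.getnnz(axis=0)
    sparsity = 1.0 - nnz_per_cell / m.n_bins
    return CellSummary(
        library_sizes=lib,
        sparsity_per_cell=sparsity,
        zero_size_cells=np.flatnonzero(lib == 0),
    )


def read_matrix(mtx_path, bins_bed_path, barcodes_path,
                group_label: str | None = None) -> BinByCellMatrix:
    """Load a Matrix Market count file with its bin and barcode sidecars.

    Duplicate stored triplets are summed (the common coordinate-format
    dialect) with a warning.
    """
    raw = scipy.io.mmread(mtx_path)
    coo = sp.coo_matrix(raw)
    n_stored = len(coo.data)
    counts = sp.csr_matrix(coo)
    counts.sum_duplicates()
    if counts.nnz < n_stored:
        warnings.warn(
            f"{mtx_path}: {n_stored - counts.nnz} duplicate triplets summed",
            stacklevel=2,
        )
    if not np.issubdtype(coo.dtype, np.integer):
        if not np.allclose(counts.data, np.round(counts.data)):
            raise InputError(f"{mtx_path}: non-integer entries")
        counts = counts.astype(np.int64)
    if counts.nnz and counts.data.min() < 0:
        raise InputError(f"{mtx_path}: negative entries")
    bins = read_bins_bed(bins_bed_path)
    with open(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    b, c = counts.shape
    if b != len(bins):
        raise InputError(
            f"{mtx_path} declares {b} rows but {bins_bed_path} has {len(bins)} bins"
        )
    if c != len(barcodes):
        raise InputError(
            f"{mtx_path} declares {c} columns but {barcodes_path} has "
            f"{len(barcodes)} barcodes"
        )
    return BinByCellMatrix(counts, bins, barcodes, group_label=group_label)


def write_matrix(m: BinByCellMatrix, out_dir) -> None:
    """Write the matrix.mtx / bins.bed / barcodes.tsv triplet."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, MTX_NAME), sp.coo_matrix(m.counts), field="integer"
    )
    write_bins_bed(m.bins, os.path.join(out_dir, BINS_NAME))
    with open(os.path.join(out_dir, BARCODES_NAME), "w") as fh:
        for bc in m.barcodes:
            fh.write(bc + "\n")


def read_matrix_dir(in_dir, group_label: str | None = None) -> BinByCellMatrix:
    """Load a triplet directory written by :func:`write_matrix`."""
    return read_matrix(
        os.path.join(in_dir, MTX_NAME),
        os.path.join(in_dir, BINS_NAME),
        os.path.join(in_dir, BARCODES_NAME),
        group_label=group_label,
    )
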