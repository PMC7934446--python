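"""Feature-matrix conversions.

A simulated bin-by-cell matrix can be reduced to the formats common in
downstream chromatin-accessibility pipelines: a peak-by-cell matrix
(the most read-enriched bins), a region-by-cell matrix aggregated over
a user-supplied BED region list, and a binarized matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GenomeBins, InputError
from .matrix_io import BinByCellMatrix


@dataclass(frozen=True)
class RegionSet:
    """Ordered genomic regions, 0-based half-open; overlaps are allowed."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise InputError("region arrays have unequal lengths")
        if len(self.chroms) == 0:
            raise InputError("empty region set")
        if np.any(self.starts >= self.ends):
            raise InputError("regions must satisfy start < end")

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        try:
            df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                             names=["chrom", "start", "end"],
                             dtype={"chrom": str, "start": np.int64,
                                    "end": np.int64})
        except (ValueError, pd.errors.ParserError) as exc:
            raise InputError(f"{path}: malformed BED: {exc}") from None
        if len(df) == 0:
            raise InputError(f"{path}: empty BED file")
        return cls(
            chroms=df["chrom"].to_numpy(dtype=object),
            starts=df["start"].to_numpy(),
            ends=df["end"].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )


def top_bin_indices(bin_means: np.ndarray, n_peaks: int) -> np.ndarray:
    """Indices of the ``n_peaks`` largest bin means, in genomic order.

    Ties are broken by ascending bin index, so the selection is the
    first ``n_peaks`` entries of a stable sort by (-mean, index).
    """
    b = len(bin_means)
    if not 1 <= n_peaks <= b:
        raise InputError(f"n_peaks must lie in [1, {b}], got {n_peaks}")
    order = np.lexsort((np.arange(b), -np.asarray(bin_means, dtype=float)))
    return np.sort(order[:n_peaks])


def get_peak_by_cell(m: BinByCellMatrix, n_peaks: int) -> BinByCellMatrix:
    """Keep the ``n_peaks`` bins with the largest mean read count.

    Selected rows are emitted in genomic order so the bin sidecar stays
    a sorted BED.
    """
    idx = top_bin_indices(m.bin_means(), n_peaks)
    sub = GenomeBins(
        chroms=m.bins.chroms[idx],
        starts=m.bins.starts[idx],
        ends=m.bins.ends[idx],
        bin_width=m.bins.bin_width,
    )
    return BinByCellMatrix(
        counts=m.counts[idx, :],
        bins=sub,
        barcodes=list(m.barcodes),
        group_label=m.group_label,
    )


def region_bin_map(bins: GenomeBins, regions: RegionSet) -> sp.csr_matrix:
    """Sparse R x B indicator of >= 1 bp overlap between regions and bins."""
    rows, cols = [], []
    bin_frame = bins.to_frame()
    by_chrom = {
        str(ch): grp for ch, grp in bin_frame.groupby("chrom", sort=False)
    }
    missing = []
    for r in range(len(regions)):
        ch = str(regions.chroms[r])
        grp = by_chrom.get(ch)
        if grp is None:
            missing.append(ch)
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        hit = (starts < regions.ends[r]) & (ends > regions.starts[r])
        for b in grp.index.to_numpy()[hit]:
            rows.append(r)
            cols.append(b)
    if missing:
        warnings.warn(
            f"regions on chromosomes absent from the bin space produce "
            f"all-zero rows: {sorted(set(missing))}",
            stacklevel=2,
        )
    data = np.ones(len(rows), dtype=np.int64)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(regions), len(bins))
    )


def get_feature_by_cell(m: BinByCellMatrix, features: RegionSet) -> sp.csr_matrix:
    """Region-by-cell counts: sum of all bins overlapping each region.

    A bin counts toward a region on any overlap (>= 1 bp), unweighted;
    pre-split regions at bin boundaries for proportional assignment.
    """
    indicator = region_bin_map(m.bins, features)
    return sp.csr_matrix(indicator @ m.counts)


def get_binary(m: BinByCellMatrix) -> BinByCellMatrix:
    """Binarize: entry 1 iff the count is positive; annotations preserved."""
    binary = m.counts.copy()
    binary.data = np.ones_like(binary.data)
    binary.eliminate_zeros()
    return BinByCellMatrix(
        counts=binary,
        bins=m.bins,
        barcodes=list(m.barcodes),
        group_label=m.group_label,
    )
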