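"""Fixed-width genomic binning.

A bin-by-cell scATAC-seq matrix indexes its rows by an ordered set of
fixed-width, non-overlapping windows ("bins") that tile each chromosome
end to end.  The default window is 5 kbp; at that width the canonical
human chromosomes span roughly 600,000 bins.  This module builds the bin
space from a UCSC-style ``chrom.sizes`` file and round-trips it through
BED3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 5000

#: GRCh38 canonical chromosome lengths (UCSC hg38.chrom.sizes, chr1-22, X, Y).
HG38_CANONICAL_SIZES: dict[str, int] = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559,
    "chr4": 190214555, "chr5": 181538259, "chr6": 170805979,
    "chr7": 159345973, "chr8": 145138636, "chr9": 138394717,
    "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189,
    "chr16": 90338345, "chr17": 83257441, "chr18": 80373285,
    "chr19": 58617616, "chr20": 64444167, "chr21": 46709983,
    "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
}


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass(frozen=True)
class ChromSizes:
    """Ordered (chromosome, length) pairs as read from a chrom.sizes file."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise InputError("duplicate chromosome names in chrom sizes")
        for name, length in self.entries:
            if length < 1:
                raise InputError(f"chromosome {name!r} has non-positive length {length}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def hg38_canonical_chrom_sizes() -> ChromSizes:
    """Canonical human (GRCh38) chromosome sizes, chr1-22 plus X and Y."""
    return ChromSizes(tuple(HG38_CANONICAL_SIZES.items()))


@dataclass(frozen=True)
class GenomeBins:
    """Ordered fixed-width bins tiling a genome; coordinates 0-based half-open.

    Within each chromosome the bins are contiguous, sorted and
    non-overlapping; every bin has width ``bin_width`` except possibly
    the last per chromosome, and their union covers ``[0, length)``.
    """

    chroms: np.ndarray  # per-bin chromosome name
    starts: np.ndarray  # int64, 0-based inclusive
    ends: np.ndarray  # int64, exclusive
    bin_width: int = field(default=DEFAULT_BIN_WIDTH)

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise InputError("bin_width must be >= 1")
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise InputError("bin arrays have unequal lengths")
        if len(self.starts) == 0:
            raise InputError("empty bin set")
        widths = self.ends - self.starts
        if np.any(widths < 1) or np.any(widths > self.bin_width):
            raise InputError("bin widths must lie in [1, bin_width]")
        # sorted and non-overlapping within each chromosome; full tilings
        # built by make_bins are additionally contiguous by construction
        same = self.chroms[1:] == self.chroms[:-1]
        if np.any(self.starts[1:][same] < self.ends[:-1][same]):
            raise InputError("bins are unsorted or overlapping within a chromosome")

    def __len__(self) -> int:
        return len(self.starts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeBins):
            return NotImplemented
        return (
            np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )


def read_chrom_sizes(path) -> ChromSizes:
    """Parse a two-column whitespace-delimited (name, length) file."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise InputError(f"{path}, line {lineno}: expected two columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise InputError(
                    f"{path}, line {lineno}: length {fields[1]!r} is not an integer"
                ) from None
            if length <= 0:
                raise InputError(f"{path}, line {lineno}: non-positive length {length}")
            if any(name == n for n, _ in entries):
                raise InputError(f"{path}, line {lineno}: duplicate chromosome {name!r}")
            entries.append((name, length))
    if not entries:
        raise InputError(f"{path}: no chromosomes found")
    return ChromSizes(tuple(entries))


def make_bins(sizes: ChromSizes, bin_width: int = DEFAULT_BIN_WIDTH) -> GenomeBins:
    """Tile each chromosome with ``ceil(L / bin_width)`` windows.

    Bin ``k`` of a chromosome of length ``L`` spans
    ``[k * bin_width, min((k + 1) * bin_width, L))``; the trailing
    partial window is kept so the bins exactly cover the chromosome.
    """
    if bin_width < 1:
        raise InputError("bin_width must be >= 1")
    if len(sizes) == 0:
        raise InputError("empty chromosome list")
    chroms, starts, ends = [], [], []
    for name, length in sizes:
        n = -(-length // bin_width)  # ceil
        s = np.arange(n, dtype=np.int64) * bin_width
        e = np.minimum(s + bin_width, length)
        chroms.append(np.full(n, name, dtype=object))
        starts.append(s)
        ends.append(e)
    return GenomeBins(
        chroms=np.concatenate(chroms),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        bin_width=bin_width,
    )


def write_bins_bed(bins: GenomeBins, path) -> None:
    """Write bins as headerless, tab-delimited BED3."""
    bins.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path, bin_width: int | None = None) -> GenomeBins:
    """Read a BED3 file back into a :class:`GenomeBins`.

    ``bin_width`` defaults to the widest interval in the file, which for
    any bin set written by :func:`write_bins_bed` recovers the original.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": np.int64, "end": np.int64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"{path}: malformed BED: {exc}") from None
    if len(df) == 0:
        raise InputError(f"{path}: empty BED file")
    widths = df["end"].to_numpy() - df["start"].to_numpy()
    if np.any(widths < 1):
        raise InputError(f"{path}: intervals must satisfy start < end")
    if bin_width is None:
        bin_width = int(widths.max())
    try:
        return GenomeBins(
            chroms=df["chrom"].to_numpy(dtype=object),
            starts=df["start"].to_numpy(),
            ends=df["end"].to_numpy(),
            bin_width=bin_width,
        )
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None
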