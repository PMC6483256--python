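"""Fixed-width genomic bin grids.

All coordinates are 0-based half-open (BED convention). A bin with index
``k`` at resolution ``r`` covers ``[k*r, (k+1)*r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class GenomicBin:
    """One fixed-width bin on a chromosome."""

    chrom: str
    index: int
    resolution: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"bin index must be non-negative, got {self.index}")
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")

    @property
    def start(self) -> int:
        return self.index * self.resolution

    @property
    def end(self) -> int:
        return self.start + self.resolution


@dataclass(frozen=True)
class BinGrid:
    """A genome-wide grid of fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Mapping from chromosome name to chromosome length in bp.
    resolution
        Bin width in bp (5,000 or 10,000 are typical for loop calling).
    """

    chrom_sizes: Mapping[str, int] = field()
    resolution: int = 5000

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
        # freeze the mapping so the grid is safely shareable
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom`` (the last bin may be partial)."""
        size = self.chrom_sizes[chrom]
        return -(-size // self.resolution)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the bin containing base position ``pos``."""
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside chromosome {chrom!r}")
        return pos // self.resolution

    def bin(self, chrom: str, index: int) -> GenomicBin:
        if index >= self.n_bins(chrom):
            raise ValueError(f"bin index {index} outside chromosome {chrom!r}")
        return GenomicBin(chrom, index, self.resolution)

    def bin_start(self, index: int) -> int:
        return index * self.resolution
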