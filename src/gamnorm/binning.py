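"""Genome binning: fixed-width windows over named chromosomes.

A *bin* (or *window*) is a fixed-length genomic interval at the chosen
resolution. Coordinates are 0-based half-open: bin ``i`` of a chromosome
covers ``[i * resolution, (i + 1) * resolution)``; the final bin may be
shorter when the chromosome length is not a multiple of the resolution.
Global bin indices concatenate per-chromosome indices in chromosome order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBinning"]


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width binning of a genome.

    Parameters
    ----------
    chromosomes:
        Ordered chromosome names.
    lengths:
        Chromosome lengths in base pairs, same order as ``chromosomes``.
    resolution:
        Bin width in base pairs.
    """

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    resolution: int
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("chromosomes and lengths differ in length")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        offsets: dict[str, int] = {}
        total = 0
        for chrom, length in zip(self.chromosomes, self.lengths):
            offsets[chrom] = total
            total += math.ceil(length / self.resolution)
        object.__setattr__(self, "_offsets", offsets)

    # -- sizes ---------------------------------------------------------

    def n_bins(self, chromosome: str) -> int:
        """Number of bins on one chromosome (``ceil(length / resolution)``)."""
        return math.ceil(self.length_of(chromosome) / self.resolution)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chromosomes)

    def length_of(self, chromosome: str) -> int:
        try:
            i = self.chromosomes.index(chromosome)
        except ValueError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None
        return self.lengths[i]

    # -- index mapping -------------------------------------------------

    def chrom_slice(self, chromosome: str) -> slice:
        """Global-index slice covering one chromosome's bins."""
        if chromosome not in self._offsets:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        start = self._offsets[chromosome]
        return slice(start, start + self.n_bins(chromosome))

    def bin_index(self, chromosome: str, start: int) -> int:
        """Global bin index of the bin whose interval contains ``start``."""
        local = start // self.resolution
        if start < 0 or local >= self.n_bins(chromosome):
            raise IndexError(f"position {start} outside {chromosome}")
        return self._offsets[chromosome] + local

    def bin_coords(self, index: int) -> tuple[str, int, int]:
        """Map a global bin index back to ``(chromosome, start, stop)``."""
        if index < 0 or index >= self.total_bins:
            raise IndexError(f"bin index {index} out of range")
        for chrom in self.chromosomes:
            n = self.n_bins(chrom)
            off = self._offsets[chrom]
            if index < off + n:
                local = index - off
                start = local * self.resolution
                stop = min(start + self.resolution, self.length_of(chrom))
                return chrom, start, stop
        raise AssertionError("unreachable")

    def bin_table(self) -> pd.DataFrame:
        """All bins as a (chrom, start, stop) frame in global order."""
        rows = [self.bin_coords(i) for i in range(self.total_bins)]
        return pd.DataFrame(rows, columns=["chrom", "start", "stop"])

    # -- constructors --------------------------------------------------

    @classmethod
    def single(cls, n_bins: int, resolution: int = 1, chromosome: str = "chr1") -> "GenomeBinning":
        """Convenience binning with one chromosome of ``n_bins`` bins."""
        return cls((chromosome,), (n_bins * resolution,), resolution)

    def chrom_bin_starts(self, chromosome: str) -> np.ndarray:
        n = self.n_bins(chromosome)
        return np.arange(n, dtype=np.int64) * self.resolution
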