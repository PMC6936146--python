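"""Core in-memory containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .binning import GenomeBinning

__all__ = ["CosegregationMatrix", "ContactMatrix", "BiasTrack", "MISSING"]

#: Sentinel for bins without data (written as the literal "NA" in text files).
MISSING = float("nan")

#: Bias names with constrained value ranges (used for validation on IO).
KNOWN_BIASES = ("wdf", "fragment_length", "gc", "mappability")


@dataclass
class CosegregationMatrix:
    """Binary detection table: one row per genomic bin, one column per
    nuclear profile (NP).

    An entry of 1 means the bin's DNA was observed in that NP's sequencing
    library; 0 means it was not. All GAM frequencies and biases derive from
    this table.
    """

    binning: GenomeBinning
    np_ids: tuple[str, ...]
    detection: np.ndarray  # (total_bins, n_nps), values in {0, 1}

    def __post_init__(self) -> None:
        self.np_ids = tuple(self.np_ids)
        det = np.asarray(self.detection)
        if det.ndim != 2:
            raise ValueError("detection must be 2-D (bins x NPs)")
        if det.shape != (self.binning.total_bins, len(self.np_ids)):
            raise ValueError(
                f"detection shape {det.shape} does not match "
                f"{self.binning.total_bins} bins x {len(self.np_ids)} NPs"
            )
        if det.size and not np.isin(det, (0, 1)).all():
            raise ValueError("detection entries must be 0 or 1")
        self.detection = det.astype(np.uint8)

    @property
    def n_nps(self) -> int:
        return len(self.np_ids)

    def chromosome_block(self, chromosome: str) -> np.ndarray:
        """Detection rows for one chromosome (bins x NPs view)."""
        return self.detection[self.binning.chrom_slice(chromosome)]


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric contact matrix with a valid-bin mask.

    ``data`` holds the dense symmetric matrix; entries at masked (invalid)
    bins may be NaN. ``mask`` is True for bins that carry co-segregation
    information. Raw GAM entries are linkage-disequilibrium values
    ``D_AB = f_AB - f_A f_B`` and may be negative; ``provenance`` records
    whether (and how) the matrix has been normalized.
    """

    binning: GenomeBinning
    chromosome: str
    data: np.ndarray
    mask: np.ndarray | None = None
    provenance: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = self.binning.n_bins(self.chromosome)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} != ({n}, {n})")
        finite = np.isfinite(d)
        both = finite & finite.T
        if not np.allclose(d[both], d.T[both], rtol=1e-8, atol=1e-12):
            raise ValueError("contact matrix must be symmetric")
        self.data = d
        if self.mask is None:
            self.mask = finite.any(axis=1)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length does not match bin count")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def values(self) -> np.ndarray:
        """Copy of ``data`` with masked rows/columns set to NaN."""
        out = self.data.copy()
        out[~self.mask, :] = np.nan
        out[:, ~self.mask] = np.nan
        return out

    def with_data(self, data: np.ndarray, provenance: str,
                  mask: np.ndarray | None = None, **meta: Any) -> "ContactMatrix":
        return ContactMatrix(self.binning, self.chromosome, data,
                             mask=self.mask.copy() if mask is None else mask,
                             provenance=provenance, meta={**self.meta, **meta})


@dataclass
class BiasTrack:
    """One real value per bin for a named per-bin bias.

    Known biases: ``wdf`` (number of NPs detecting the bin) and
    ``fragment_length`` (summed detected-run lengths) are non-negative
    integers; ``gc`` and ``mappability`` lie in [0, 1]. Bins without data
    carry NaN.
    """

    binning: GenomeBinning
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.binning.total_bins,):
            raise ValueError(
                f"track length {v.shape} != {self.binning.total_bins} bins")
        finite = v[np.isfinite(v)]
        if self.name in ("gc", "mappability") and finite.size:
            if finite.min() < 0 or finite.max() > 1:
                raise ValueError(f"{self.name} values must lie in [0, 1]")
        if self.name in ("wdf", "fragment_length") and finite.size:
            if finite.min() < 0 or not np.allclose(finite, np.round(finite)):
                raise ValueError(f"{self.name} values must be non-negative integers")
        self.values = v

    def chromosome_values(self, chromosome: str) -> np.ndarray:
        return self.values[self.binning.chrom_slice(chromosome)]
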