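"""Segregation frequencies, raw GAM contact matrices, and the detection
biases computed directly from a co-segregation table.

The raw GAM contact value between two bins A and B is their linkage
disequilibrium over nuclear profiles,

    D_AB = f_AB - f_A * f_B,

where f_A is the fraction of NPs detecting A and f_AB the fraction
detecting both. D_AB measures excess co-detection over independence and
may be negative; it is bounded in [-0.25, 0.25].

Two detection biases are quantified per bin:

* window detection frequency (WDF): the number of NPs detecting the bin;
* fragment-length bias: for each NP, the length (in bins) of the maximal
  run of consecutively detected bins containing the bin (0 when the bin is
  undetected in that NP), summed over NPs. The per-NP mean is deliberately
  not taken: the NP count is shared by all bins and cancels in any
  comparison.

A bin detected only as isolated single-bin fragments has fragment-length
bias equal to its WDF; longer fragments push the fragment-length bias up,
which is what makes the two biases distinct distributions on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import GenomeBinning
from .types import BiasTrack, ContactMatrix, CosegregationMatrix

__all__ = [
    "SegregationFrequencies",
    "segregation_frequencies",
    "raw_contact_matrix",
    "window_detection_frequency",
    "fragment_length_bias",
]


@dataclass
class SegregationFrequencies:
    """Per-bin and pairwise detection frequencies for one chromosome."""

    coseg_binning: GenomeBinning
    chromosome: str
    f: np.ndarray        # per-bin detection frequency f_A in [0, 1]
    f_pair: np.ndarray   # symmetric co-detection frequency matrix f_AB
    n_nps: int

    def __post_init__(self) -> None:
        if self.n_nps < 1:
            raise ValueError("at least one nuclear profile required")
        n = self.f.shape[0]
        if self.f_pair.shape != (n, n):
            raise ValueError("f and f_pair sizes disagree")


def segregation_frequencies(coseg: CosegregationMatrix,
                            chromosome: str) -> SegregationFrequencies:
    """Detection frequencies ``f_A`` and cis co-detection frequencies
    ``f_AB`` for one chromosome.

    ``f_A`` is the fraction of NPs detecting bin A; ``f_AB`` the fraction
    simultaneously detecting A and B. ``f_AA = f_A`` and
    ``f_AB <= min(f_A, f_B)`` by construction.
    """
    if coseg.n_nps == 0:
        raise ValueError("degenerate input: co-segregation matrix has no NPs")
    block = coseg.chromosome_block(chromosome).astype(np.float64)
    m = coseg.n_nps
    f = block.sum(axis=1) / m
    f_pair = (block @ block.T) / m
    return SegregationFrequencies(coseg.binning, chromosome, f, f_pair, m)


def raw_contact_matrix(freqs: SegregationFrequencies) -> ContactMatrix:
    """Raw GAM contact matrix ``D_AB = f_AB - f_A f_B``.

    Bins with ``f_A`` equal to 0 or 1 carry no co-segregation information
    (their D row is identically 0) and are flagged invalid in the mask;
    the computed values remain available in ``.data``.
    """
    d = freqs.f_pair - np.outer(freqs.f, freqs.f)
    mask = (freqs.f > 0) & (freqs.f < 1)
    return ContactMatrix(freqs.coseg_binning, freqs.chromosome, d, mask=mask,
                         provenance="raw", meta={"n_nps": freqs.n_nps})


def window_detection_frequency(coseg: CosegregationMatrix) -> BiasTrack:
    """WDF bias: per-bin count of NPs in which the bin is detected."""
    counts = coseg.detection.sum(axis=1).astype(float)
    return BiasTrack(coseg.binning, "wdf", counts)


def _run_lengths(column: np.ndarray) -> np.ndarray:
    """Length of the maximal detected run covering each position (0 if
    undetected)."""
    out = np.zeros(column.size, dtype=np.int64)
    padded = np.concatenate(([0], column.astype(np.int8), [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def fragment_length_bias(coseg: CosegregationMatrix) -> BiasTrack:
    """Fragment-length bias: summed containing-run lengths over NPs.

    Runs are maximal stretches of consecutively detected bins, computed per
    chromosome within each NP — a cryosection fragment is a physical piece
    of a single chromosome, so runs never span chromosome boundaries.
    """
    total = np.zeros(coseg.binning.total_bins, dtype=np.int64)
    for chrom in coseg.binning.chromosomes:
        sl = coseg.binning.chrom_slice(chrom)
        block = coseg.detection[sl]
        acc = np.zeros(block.shape[0], dtype=np.int64)
        for j in range(block.shape[1]):
            acc += _run_lengths(block[:, j])
        total[sl] = acc
    return BiasTrack(coseg.binning, "fragment_length", total.astype(float))
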