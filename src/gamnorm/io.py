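"""Readers and writers for GAM file formats.

Formats
-------
* Co-segregation table: TSV with header ``chrom<TAB>start<TAB>stop`` followed
  by one 0/1 column per nuclear profile (the GEO-style segregation layout).
* Contact matrix: dense whitespace text (with ``#key=value`` metadata lines)
  or TSV triplets ``(bin_i, bin_j, value)``.
* Bias track: bedGraph rows ``chrom start stop value`` aligned to bin
  boundaries; missing bins are written as the literal ``NA``.
* Genome sequence: FASTA (via pyfaidx), used to compute per-bin GC content.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import GenomeBinning
from .types import BiasTrack, ContactMatrix, CosegregationMatrix

__all__ = [
    "read_cosegregation_table",
    "write_cosegregation_table",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_bias_track",
    "write_bias_track",
    "gc_content_track",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Input file violates the documented layout."""


# ---------------------------------------------------------------------------
# co-segregation tables
# ---------------------------------------------------------------------------

def read_cosegregation_table(path: str | Path,
                             resolution: int | None = None) -> CosegregationMatrix:
    """Read a tab-separated co-segregation table.

    The first three columns are ``chrom``, ``start``, ``stop``; every
    remaining column is one nuclear profile with 0/1 detection entries.
    The binning is inferred from the rows: resolution defaults to
    ``stop - start`` of the first row, chromosome order to first appearance.
    Count-valued columns are thresholded to ``count > 0`` with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={0: str},
                         on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: inconsistent row widths: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least chrom/start/stop columns")
    chrom_col, start_col, stop_col = df.columns[:3]
    np_ids = tuple(str(c) for c in df.columns[3:])

    if df.empty:
        res = resolution if resolution is not None else 1
        binning = GenomeBinning((), (), res)
        return CosegregationMatrix(binning, np_ids,
                                   np.zeros((0, len(np_ids)), dtype=np.uint8))

    starts = df[start_col].to_numpy(dtype=np.int64)
    stops = df[stop_col].to_numpy(dtype=np.int64)
    if resolution is None:
        resolution = int(stops[0] - starts[0])
    if resolution <= 0:
        raise FormatError(f"{path}: non-positive resolution {resolution}")
    if (starts % resolution != 0).any():
        bad = int(np.flatnonzero(starts % resolution != 0)[0])
        raise FormatError(
            f"{path}: row {bad + 2}: start {starts[bad]} is not a multiple "
            f"of resolution {resolution}")

    chroms = df[chrom_col].astype(str)
    order = list(dict.fromkeys(chroms))
    lengths = tuple(int(stops[(chroms == c).to_numpy()].max()) for c in order)
    binning = GenomeBinning(tuple(order), lengths, resolution)

    values = df.iloc[:, 3:].to_numpy()
    try:
        values = values.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric detection entry: {exc}") from exc
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: missing/non-finite detection entry")
    if (values < 0).any() or not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: detection entries must be non-negative integers")
    if (values > 1).any():
        warnings.warn(
            f"{path}: count-valued entries thresholded to detection = (count > 0)",
            stacklevel=2)
        log.warning("%s: thresholding count-valued co-segregation entries", path)
    detection = (values > 0).astype(np.uint8)

    # normalise row order to (chromosome order, start ascending)
    full = np.zeros((binning.total_bins, len(np_ids)), dtype=np.uint8)
    for row, (chrom, start) in enumerate(zip(chroms, starts)):
        full[binning.bin_index(chrom, int(start))] = detection[row]
    return CosegregationMatrix(binning, np_ids, full)


def write_cosegregation_table(coseg: CosegregationMatrix, path: str | Path) -> None:
    """Write the TSV layout accepted by :func:`read_cosegregation_table`."""
    table = coseg.binning.bin_table()
    out = pd.concat(
        [table, pd.DataFrame(coseg.detection, columns=list(coseg.np_ids))],
        axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def _parse_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    return meta


def read_contact_matrix(path: str | Path, format: str = "dense_text",
                        binning: GenomeBinning | None = None,
                        chromosome: str | None = None) -> ContactMatrix:
    """Read a symmetric per-chromosome contact matrix.

    ``dense_text`` is a square whitespace-separated matrix; ``#chrom=...``
    and ``#resolution=...`` header lines carry the binning when no
    ``binning`` is supplied. ``triplet_text`` rows are
    ``bin_i<TAB>bin_j<TAB>value`` (bin indices local to the chromosome);
    the matrix is symmetrized by mirroring and unlisted pairs are 0.
    """
    path = Path(path)
    meta = _parse_meta(path)
    chromosome = chromosome or meta.get("chrom", "chr1")
    resolution = int(meta.get("resolution", binning.resolution if binning else 1))

    if format == "dense_text":
        mat = np.loadtxt(path, ndmin=2)
        if mat.shape[0] != mat.shape[1]:
            raise FormatError(f"{path}: dense matrix is {mat.shape}, not square")
        n = mat.shape[0]
        if binning is None:
            binning = GenomeBinning.single(n, resolution, chromosome)
        finite = np.isfinite(mat) & np.isfinite(mat).T
        if not np.allclose(mat[finite], mat.T[finite], rtol=1e-8, atol=1e-12):
            raise FormatError(f"{path}: dense matrix is not symmetric")
    elif format == "triplet_text":
        trip = np.loadtxt(path, ndmin=2, comments="#")
        if trip.size and trip.shape[1] != 3:
            raise FormatError(f"{path}: triplet rows must have 3 columns")
        if binning is None:
            hi = int(trip[:, :2].max()) + 1 if trip.size else 0
            binning = GenomeBinning.single(max(hi, 1), resolution, chromosome)
        n = binning.n_bins(chromosome)
        mat = np.zeros((n, n))
        for i, j, v in trip:
            i, j = int(i), int(j)
            if not (0 <= i < n and 0 <= j < n):
                raise IndexError(f"{path}: triplet index ({i}, {j}) outside "
                                 f"{n}-bin binning")
            mat[i, j] = v
            mat[j, i] = v
    else:
        raise ValueError(f"unknown contact-matrix format {format!r}")

    return ContactMatrix(binning, chromosome, mat,
                         provenance=meta.get("provenance", "raw"))


def write_contact_matrix(matrix: ContactMatrix, path: str | Path,
                         format: str = "dense_text") -> None:
    path = Path(path)
    header = (f"chrom={matrix.chromosome} resolution={matrix.binning.resolution} "
              f"provenance={matrix.provenance}")
    vals = matrix.values
    if format == "dense_text":
        np.savetxt(path, vals, header=header, comments="#", fmt="%.10g")
    elif format == "triplet_text":
        with open(path, "w") as fh:
            fh.write(f"#{header}\n")
            n = matrix.n_bins
            for i in range(n):
                for j in range(i, n):
                    v = vals[i, j]
                    if np.isfinite(v) and v != 0:
                        fh.write(f"{i}\t{j}\t{v:.10g}\n")
    else:
        raise ValueError(f"unknown contact-matrix format {format!r}")


# ---------------------------------------------------------------------------
# bias tracks
# ---------------------------------------------------------------------------

def read_bias_track(path: str | Path, binning: GenomeBinning,
                    name: str = "user") -> BiasTrack:
    """Read a bedGraph-like track (chrom, start, stop, value) onto a binning.

    Every interval must coincide with exactly one bin; bins not covered get
    NaN. The literal ``NA`` denotes an explicitly missing value.
    """
    values = np.full(binning.total_bins, np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, stop, value = parts
            start, stop = int(start), int(stop)
            if chrom not in binning.chromosomes:
                raise KeyError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start % binning.resolution != 0:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start}, {stop}) not aligned "
                    f"to a bin boundary at resolution {binning.resolution}")
            idx = binning.bin_index(chrom, start)
            _, bstart, bstop = binning.bin_coords(idx)
            if stop != bstop:
                raise FormatError(
                    f"{path}:{lineno}: interval stop {stop} != bin stop {bstop}")
            values[idx] = np.nan if value == "NA" else float(value)
    return BiasTrack(binning, name, values)


def write_bias_track(track: BiasTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            chrom, start, stop = track.binning.bin_coords(i)
            text = "NA" if not np.isfinite(v) else f"{v:.10g}"
            fh.write(f"{chrom}\t{start}\t{stop}\t{text}\n")


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content_track(fasta: str | Path, binning: GenomeBinning) -> BiasTrack:
    """Per-bin GC fraction among non-N bases, computed from a FASTA genome.

    Bins consisting entirely of N get NaN. Case-insensitive.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(fasta))
    for chrom in binning.chromosomes:
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from {fasta}")
    values = np.full(binning.total_bins, np.nan)
    for i in range(binning.total_bins):
        chrom, start, stop = binning.bin_coords(i)
        seq = str(genome[chrom][start:stop]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt:
            values[i] = (seq.count("G") + seq.count("C")) / acgt
    return BiasTrack(binning, "gc", values)
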