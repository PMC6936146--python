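"""Evaluation of bias removal: stratified heat maps, bias-contact
correlations, cross-matrix correlation, and bias-distribution tests.

The stratified heat map pools all valid bins genome-wide, sorts them by a
per-bin bias, splits them into S quantile sets (default 20), and averages
the cis contact values between every pair of sets. A matrix free of the
bias produces a flat (single-colour) S-by-S map; residual bias shows up as
a gradient along the axes.

The bias-contact correlation pairs every cis entry D_ij with the product
b_i * b_j of the per-bin bias values — the natural pairing under the
multiplicative per-bin factor model that all the normalizers assume — and
reports the Pearson correlation; values near zero indicate the bias has
been removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import BiasTrack, ContactMatrix

__all__ = [
    "StratifiedHeatmap",
    "stratified_heatmap",
    "bias_correlation",
    "cross_matrix_correlation",
    "bias_distribution_test",
    "BiasTestResult",
]


@dataclass
class StratifiedHeatmap:
    """S-by-S matrix of mean contacts between bias-quantile strata."""

    n_strata: int
    assignment: dict[str, np.ndarray]  # per-chromosome stratum index (0-based), -1 = unused
    values: np.ndarray                 # (S, S) mean contact per stratum pair
    counts: np.ndarray                 # (S, S) number of contributing pairs


def _as_matrix_list(matrices) -> list[ContactMatrix]:
    if isinstance(matrices, ContactMatrix):
        return [matrices]
    return list(matrices)


def _pooled_valid_bins(mats: list[ContactMatrix], bias: BiasTrack):
    """(chromosome, local index, bias value) for every usable bin."""
    entries = []
    for m in mats:
        b = bias.chromosome_values(m.chromosome)
        ok = m.mask & np.isfinite(b)
        for i in np.flatnonzero(ok):
            entries.append((m.chromosome, i, b[i]))
    return entries


def stratified_heatmap(matrices, bias: BiasTrack,
                       strata: int = 20) -> StratifiedHeatmap:
    """Average cis contacts between pairs of bias-quantile strata.

    Bins from all supplied chromosomes are pooled, sorted by bias value
    (ties broken by stable bin order, for determinism) and split into
    ``strata`` near-equal sets. Cell (s, t) is the mean of entries
    D_ij over cis pairs with i in set s, j in set t, i != j, both valid.
    The diagonal D_ii is excluded: self-contacts are f_A(1 - f_A) by
    construction and would dominate the strata.
    """
    mats = _as_matrix_list(matrices)
    entries = _pooled_valid_bins(mats, bias)
    if len(entries) < strata:
        raise ValueError(
            f"only {len(entries)} valid bins for {strata} strata")
    order = np.argsort([e[2] for e in entries], kind="stable")
    groups = np.array_split(order, strata)
    stratum_of: dict[str, np.ndarray] = {
        m.chromosome: np.full(m.n_bins, -1, dtype=int) for m in mats}
    for s, grp in enumerate(groups):
        for gi in grp:
            chrom, i, _ = entries[gi]
            stratum_of[chrom][i] = s

    sums = np.zeros((strata, strata))
    counts = np.zeros((strata, strata), dtype=np.int64)
    for m in mats:
        lab = stratum_of[m.chromosome]
        used = np.flatnonzero(lab >= 0)
        sub = m.data[np.ix_(used, used)]
        ls = lab[used]
        iu, ju = np.triu_indices(len(used), k=1)
        np.add.at(sums, (ls[iu], ls[ju]), sub[iu, ju])
        np.add.at(counts, (ls[iu], ls[ju]), 1)
    sums = sums + sums.T - np.diag(np.diag(sums))
    counts = counts + counts.T - np.diag(np.diag(counts))
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return StratifiedHeatmap(strata, stratum_of, values, counts)


def _pooled_pairs(mats: list[ContactMatrix], bias: BiasTrack):
    """Cis (D_ij, b_i * b_j) pairs over i < j, both bins valid."""
    contacts, products = [], []
    for m in mats:
        b = bias.chromosome_values(m.chromosome)
        ok = m.mask & np.isfinite(b)
        idx = np.flatnonzero(ok)
        sub = m.data[np.ix_(idx, idx)]
        bb = b[idx]
        iu, ju = np.triu_indices(len(idx), k=1)
        contacts.append(sub[iu, ju])
        products.append(bb[iu] * bb[ju])
    return np.concatenate(contacts), np.concatenate(products)


def bias_correlation(matrices, bias: BiasTrack) -> float:
    """Pearson correlation between cis contacts D_ij and bias products
    b_i * b_j, pooled genome-wide. Near zero means the bias is gone."""
    mats = _as_matrix_list(matrices)
    d, p = _pooled_pairs(mats, bias)
    if d.size < 2 or d.max() == d.min() or p.max() == p.min():
        raise ValueError("correlation undefined: zero variance in contacts "
                         "or bias products")
    return float(stats.pearsonr(d, p).statistic)


def cross_matrix_correlation(A: ContactMatrix, B: ContactMatrix,
                             method: str = "spearman") -> float:
    """Rank (or linear) correlation between two contact matrices over the
    cis pairs where both are valid and at least one entry is nonzero."""
    if A.n_bins != B.n_bins or A.chromosome != B.chromosome:
        raise ValueError("matrices are on different binnings")
    both = A.mask & B.mask
    idx = np.flatnonzero(both)
    sa = A.data[np.ix_(idx, idx)]
    sb = B.data[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    a, b = sa[iu, ju], sb[iu, ju]
    keep = np.isfinite(a) & np.isfinite(b) & ((a != 0) | (b != 0))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("no common valid pairs")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


@dataclass
class BiasTestResult:
    """Paired-test report comparing WDF and fragment-length biases."""

    chromosome: str
    n: int
    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    degenerate: bool = False  # all per-bin differences were zero


def bias_distribution_test(wdf: BiasTrack, fragment: BiasTrack,
                           per_chromosome: bool = True) -> list[BiasTestResult]:
    """Paired Student's t-test and Wilcoxon signed-rank test of the WDF
    bias against the fragment-length bias.

    The two tracks are paired per bin; tests run per chromosome (or pooled
    genome-wide with ``per_chromosome=False``). Raw p-values are reported,
    without multiplicity correction. When every difference is zero the
    Wilcoxon test is degenerate and reported as such (statistic/p-value
    NaN), not raised.
    """
    if wdf.binning is not fragment.binning and \
            wdf.binning != fragment.binning:
        raise ValueError("tracks are on different binnings")
    binning = wdf.binning
    scopes = ([(c, binning.chrom_slice(c)) for c in binning.chromosomes]
              if per_chromosome else [("genome", slice(None))])
    out = []
    for chrom, sl in scopes:
        w = wdf.values[sl]
        f = fragment.values[sl]
        ok = np.isfinite(w) & np.isfinite(f)
        w, f = w[ok], f[ok]
        diff = f - w
        if diff.size == 0:
            continue
        if np.all(diff == 0):
            out.append(BiasTestResult(chrom, diff.size, 0.0, 1.0,
                                      np.nan, np.nan, degenerate=True))
            continue
        t = stats.ttest_rel(f, w)
        try:
            wil = stats.wilcoxon(f, w)
            ws, wp = float(wil.statistic), float(wil.pvalue)
        except ValueError:
            ws, wp = np.nan, np.nan
        out.append(BiasTestResult(chrom, diff.size, float(t.statistic),
                                  float(t.pvalue), ws, wp))
    return out
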