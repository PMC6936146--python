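"""Normalization of raw GAM contact matrices.

Five methods are implemented, all aiming to remove multiplicative per-bin
detection biases from the signed linkage-disequilibrium matrix D:

* **NLD** — normalized linkage disequilibrium: each D_AB is divided by its
  sign-dependent theoretical maximum

      D_max = min(f_A f_B, (1 - f_A)(1 - f_B))        if D_AB < 0
      D_max = min(f_B (1 - f_A), f_A (1 - f_B))       if D_AB > 0

  giving values bounded in [-1, 1] (the D' statistic of population
  genetics applied to co-segregation).
* **VC** — vanilla coverage: D_ij / (e_i e_j) with e_i the 1-norm of row i.
* **SCN** — sequential component normalization: same form with 2-norms,
  run for exactly one iteration by default.
* **ICE** — iterative correction: e_i is the row 1-norm divided by its
  mean over nonzero rows, iterated until max|e_i - 1| < tol (default
  1e-3) or max_iter (default 100) is reached.
* **KR2** — Knight-Ruiz balancing in the 2-norm, for signed matrices:
  square the matrix elementwise (D2 = D ∘ D), balance D2 with the
  Knight-Ruiz algorithm (D3 = diag(x) D2 diag(x)), then restore the
  original signs (D_norm = D3 ∘ sign(D)). No square root is taken.

Row norms for VC/SCN/ICE use absolute values so that all scale factors
are positive on the signed GAM matrix; every method therefore preserves
entry signs. Masked bins (and rows that become structurally zero) are
excluded before scaling and reported as NaN afterwards.

The Knight-Ruiz balancer solves diag(x) D x = e for a positive vector x
on a non-negative symmetric matrix by an inner-outer Newton scheme: each
outer step linearizes the balance equations and solves

    (B_k + diag(B_k e)) y_{k+1} = (B_k + I) e,
    B_k = diag(x_k) D diag(x_k),  y_{k+1} = diag(x_k)^{-1} x_{k+1}

with conjugate gradients, truncated adaptively (forcing-term strategy)
and safeguarded so iterates stay in a cone around the current point.
The balanced matrix is diag(x) D diag(x), whose row sums are all one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import SegregationFrequencies
from .types import ContactMatrix

__all__ = [
    "BalanceResult",
    "BalanceError",
    "kr_balance",
    "normalize_nld",
    "normalize_vc",
    "normalize_scn",
    "normalize_ice",
    "normalize_kr2",
    "normalize",
    "METHODS",
]

log = logging.getLogger(__name__)

METHODS = ("nld", "vc", "scn", "ice", "kr2")


class BalanceError(ValueError):
    """Structural problem that prevents balancing (e.g. an all-zero row)."""


@dataclass
class BalanceResult:
    """Outcome of one normalization run.

    ``matrix`` is the normalized matrix (a :class:`ContactMatrix` from the
    ``normalize_*`` front ends, a plain array from :func:`kr_balance`);
    ``x`` the per-valid-bin positive scale factors (None for NLD, which is
    not a per-bin factor method); ``residual`` the final balance error;
    ``iterations`` the outer-iteration count.
    """

    matrix: Any
    x: np.ndarray | None
    residual: float
    iterations: int
    converged: bool
    method: str = ""
    meta: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------

def kr_balance(D: np.ndarray, tolerance: float = 1e-6,
               max_outer: int = 300, x0: np.ndarray | None = None,
               delta: float = 0.1, Delta: float = 3.0) -> BalanceResult:
    """Balance a non-negative symmetric matrix so all row sums equal one.

    Finds x > 0 with ``diag(x) D x = e`` (e the all-ones vector) by the
    inner-outer Newton/conjugate-gradient scheme and returns the balanced
    matrix ``diag(x) D diag(x)`` together with x, the final residual
    ``max|diag(x) D x - e|``, and the outer-iteration count. ``delta`` and
    ``Delta`` bound the inner iterates y within [delta, Delta] per outer
    step (the standard safeguard cone).

    Raises :class:`BalanceError` on an all-zero row: the caller must mask
    such bins first, because no positive scaling can give them unit sum.
    """
    A = np.asarray(D, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("matrix must be square")
    if n == 0:
        return BalanceResult(A.copy(), np.ones(0), 0.0, 0, True, "kr")
    if (A < 0).any():
        raise ValueError("Knight-Ruiz balancing requires a non-negative matrix")
    if not np.allclose(A, A.T, rtol=1e-8, atol=1e-12):
        raise ValueError("Knight-Ruiz balancing requires a symmetric matrix")
    zero_rows = ~(A.sum(axis=1) > 0)
    if zero_rows.any():
        raise BalanceError(
            f"{int(zero_rows.sum())} all-zero row(s); mask these bins before "
            "balancing")

    e = np.ones(n)
    x = e.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
    # forcing-term parameters of the inner-outer scheme
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tolerance * 0.5
    rt = tolerance ** 2

    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rho_km1
    rold = rout
    outer = 0

    while rout > rt and outer < max_outer:
        outer += 1
        k = 0
        y = e.copy()
        inner_tol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > inner_tol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            # matrix-vector product with the Jacobian B_k + diag(B_k e)
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / float(p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        # Adjust the inner relative tolerance for the next outer step.
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, np.finfo(float).tiny))

    residual = float(np.abs(x * (A @ x) - 1.0).max())
    converged = residual <= tolerance
    if not converged:
        warnings.warn(
            f"Knight-Ruiz balancing did not converge in {outer} outer "
            f"iterations (residual {residual:.3g} > {tolerance:g})",
            stacklevel=2)
    balanced = A * np.outer(x, x)
    return BalanceResult(balanced, x, residual, outer, converged, "kr")


# ---------------------------------------------------------------------------
# helpers shared by the matrix front ends
# ---------------------------------------------------------------------------

def _valid_submatrix(raw: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    idx = np.flatnonzero(raw.mask)
    V = raw.data[np.ix_(idx, idx)].astype(float)
    if not np.isfinite(V).all():
        raise ValueError("non-finite entries among valid bins")
    return V, idx


def _reassemble(raw: ContactMatrix, sub: np.ndarray, idx: np.ndarray,
                provenance: str, **meta: Any) -> ContactMatrix:
    n = raw.n_bins
    out = np.full((n, n), np.nan)
    out[np.ix_(idx, idx)] = sub
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return ContactMatrix(raw.binning, raw.chromosome, out, mask=mask,
                         provenance=provenance, meta={**raw.meta, **meta})


def _drop_zero_norm_rows(V: np.ndarray, idx: np.ndarray, method: str,
                         ord_: int = 1) -> tuple[np.ndarray, np.ndarray]:
    norms = np.abs(V).sum(axis=1) if ord_ == 1 else np.sqrt((V ** 2).sum(axis=1))
    keep = norms > 0
    if not keep.all():
        warnings.warn(
            f"{method}: {int((~keep).sum())} zero-norm row(s) masked",
            stacklevel=3)
        V = V[np.ix_(keep, keep)]
        idx = idx[keep]
    return V, idx


# ---------------------------------------------------------------------------
# the five methods
# ---------------------------------------------------------------------------

def normalize_nld(raw: ContactMatrix,
                  freqs: SegregationFrequencies) -> BalanceResult:
    """Normalized linkage disequilibrium: D_AB / D_max, bounded in [-1, 1].

    D_max is the sign-dependent theoretical extreme of D_AB given the
    marginal frequencies f_A, f_B. Entries with D_AB = 0 map to 0 (the
    ratio is formally 0/positive only when 0 < f < 1, which the mask
    guarantees). Bins with f_A in {0, 1} have D_max = 0 and are masked.
    """
    if freqs.chromosome != raw.chromosome or freqs.f.shape[0] != raw.n_bins:
        raise ValueError("frequencies do not match the contact matrix bins")
    informative = (freqs.f > 0) & (freqs.f < 1)
    work = ContactMatrix(raw.binning, raw.chromosome, raw.data,
                         mask=raw.mask & informative,
                         provenance=raw.provenance, meta=raw.meta)
    V, idx = _valid_submatrix(work)
    f = freqs.f[idx]
    fa = f[:, None]
    fb = f[None, :]
    dmax_neg = np.minimum(fa * fb, (1 - fa) * (1 - fb))
    dmax_pos = np.minimum(fb * (1 - fa), fa * (1 - fb))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(V > 0, V / dmax_pos, np.where(V < 0, V / dmax_neg, 0.0))
    result = _reassemble(raw, out, idx, "nld")
    return BalanceResult(result, None, 0.0, 0, True, "nld")


def normalize_vc(raw: ContactMatrix) -> BalanceResult:
    """Vanilla coverage: single-pass division by row/column 1-norms."""
    V, idx = _valid_submatrix(raw)
    V, idx = _drop_zero_norm_rows(V, idx, "vc", ord_=1)
    e = np.abs(V).sum(axis=1)
    out = V / np.outer(e, e)
    result = _reassemble(raw, out, idx, "vc")
    return BalanceResult(result, e, 0.0, 1, True, "vc")


def normalize_scn(raw: ContactMatrix, iterations: int = 1) -> BalanceResult:
    """Sequential component normalization: division by row 2-norms.

    One iteration by default — on GAM data further iterations do not help
    and the single pass is the reference behaviour.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    V, idx = _valid_submatrix(raw)
    V, idx = _drop_zero_norm_rows(V, idx, "scn", ord_=2)
    scale = np.ones(V.shape[0])
    for _ in range(iterations):
        e = np.sqrt((V ** 2).sum(axis=1))
        V = V / np.outer(e, e)
        scale *= e
    result = _reassemble(raw, V, idx, "scn", iterations=iterations)
    return BalanceResult(result, scale, 0.0, iterations, True, "scn")


def normalize_ice(raw: ContactMatrix, max_iter: int = 100,
                  tol: float = 1e-3) -> BalanceResult:
    """Iterative correction: repeat D_ij <- D_ij / (e_i e_j) with e_i the
    row 1-norm divided by its mean over nonzero rows, until
    max|e_i - 1| < tol or ``max_iter`` is reached."""
    V, idx = _valid_submatrix(raw)
    V, idx = _drop_zero_norm_rows(V, idx, "ice", ord_=1)
    scale = np.ones(V.shape[0])
    converged = False
    it = 0
    err = np.inf
    for it in range(1, max_iter + 1):
        s = np.abs(V).sum(axis=1)
        nz = s > 0
        e = np.ones_like(s)
        if nz.any():
            e[nz] = s[nz] / s[nz].mean()
        V = V / np.outer(e, e)
        scale *= e
        err = float(np.abs(e - 1.0).max())
        if err < tol:
            converged = True
            break
    if max_iter == 0:
        it = 0
    if not converged and max_iter > 0:
        log.warning("ICE stopped at max_iter=%d with error %.3g", max_iter, err)
    result = _reassemble(raw, V, idx, "ice", tol=tol, max_iter=max_iter)
    return BalanceResult(result, scale, float(err), it, converged, "ice")


def normalize_kr2(raw: ContactMatrix, tolerance: float = 1e-6,
                  max_outer: int = 300) -> BalanceResult:
    """Knight-Ruiz 2-norm balancing of a signed contact matrix.

    Three steps: D2 = D ∘ D (elementwise square, making the matrix
    non-negative), D3 = KR(D2) (Knight-Ruiz balanced square), and
    D_norm = D3 ∘ sign(D) (restore the signs of the input). The reported
    x is the balancing vector of D2.
    """
    V, idx = _valid_submatrix(raw)
    D2 = V * V
    keep = D2.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"kr2: {int((~keep).sum())} structurally zero row(s) masked",
            stacklevel=2)
        V = V[np.ix_(keep, keep)]
        D2 = D2[np.ix_(keep, keep)]
        idx = idx[keep]
    kr = kr_balance(D2, tolerance=tolerance, max_outer=max_outer)
    out = kr.matrix * np.sign(V)
    result = _reassemble(raw, out, idx, "kr2",
                         tolerance=tolerance, max_outer=max_outer)
    return BalanceResult(result, kr.x, kr.residual, kr.iterations,
                         kr.converged, "kr2")


def normalize(raw: ContactMatrix, method: str,
              freqs: SegregationFrequencies | None = None,
              **options: Any) -> BalanceResult:
    """Dispatch to one of the five normalization methods.

    ``method`` is one of ``nld``, ``vc``, ``scn``, ``ice``, ``kr2``;
    ``freqs`` is required for ``nld``. Count-data regression methods
    (e.g. HiCNorm) are deliberately unsupported: raw GAM contacts are
    real-valued linkage disequilibria, not counts.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(
            f"unknown normalization method {method!r}; choose from {METHODS}")
    if method == "nld":
        if freqs is None:
            raise ValueError("nld requires segregation frequencies")
        res = normalize_nld(raw, freqs)
    elif method == "vc":
        res = normalize_vc(raw, **options)
    elif method == "scn":
        res = normalize_scn(raw, **options)
    elif method == "ice":
        res = normalize_ice(raw, **options)
    else:
        res = normalize_kr2(raw, **options)
    res.meta.update(options)
    log.info("normalize method=%s converged=%s iterations=%d residual=%.3g "
             "masked=%d", method, res.converged, res.iterations, res.residual,
             int((~res.matrix.mask).sum()))
    return res
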