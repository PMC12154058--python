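"""Spectral preprocessing: Savitzky-Golay, SNV, derivatives, airPLS.

All transforms are pure functions that accept either a single spectrum
(:class:`~fritqc.grid.Spectrum` or 1-D array) or a whole set
(:class:`~fritqc.grid.SpectraSet` or 2-D matrix, applied row-wise) and return
the same type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .grid import FormatError, Spectrum, SpectraSet

__all__ = [
    "SGParams",
    "AirPLSParams",
    "savgol",
    "snv",
    "derivative",
    "airpls",
    "airpls_correct",
    "pipeline_sg_snv",
    "pipeline_derivative",
    "pipeline_airpls",
    "PIPELINES",
]

ArrayLike = Union[np.ndarray, Spectrum, SpectraSet]


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter settings (window 51, cubic, per the workflow)."""

    window: int = 51
    polyorder: int = 3
    deriv_order: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("S-G window must be odd")
        if self.window <= self.polyorder:
            raise ValueError("S-G window must exceed the polynomial order")
        if not (0 <= self.deriv_order <= self.polyorder):
            raise ValueError("derivative order must be in [0, polyorder]")


@dataclass(frozen=True)
class AirPLSParams:
    """airPLS settings: Whittaker penalty lambda, iteration cap, stop ratio."""

    lam: float = 1e5
    max_iter: int = 50
    tol_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.tol_ratio < 1):
            raise ValueError("tol_ratio must be in (0, 1)")


def _apply(x: ArrayLike, fn):
    """Dispatch a row-wise transform over Spectrum/SpectraSet/ndarray."""
    if isinstance(x, Spectrum):
        return x.copy_with(fn(x.absorbance[None, :])[0])
    if isinstance(x, SpectraSet):
        return x.with_matrix(fn(x.X))
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return fn(arr[None, :])[0]
    return fn(arr)


def savgol(x: ArrayLike, params: SGParams = SGParams(), step_nm: float = 1.0):
    """Savitzky-Golay smoothing / differentiation.

    Derivatives are scaled by ``step_nm ** -deriv_order`` so a first
    derivative is in absorbance per nm.  Edges use scipy's polynomial-fit
    extension ("interp"), which, like the interior filter, reproduces
    polynomials up to ``polyorder`` exactly.
    """
    def fn(X):
        if params.window > X.shape[1]:
            raise ValueError("S-G window exceeds the number of grid points")
        return savgol_filter(X, params.window, params.polyorder,
                             deriv=params.deriv_order, delta=step_nm,
                             axis=1, mode="interp")
    return _apply(x, fn)


def snv(x: ArrayLike):
    """Standard normal variate: per-spectrum centring and unit-variance scaling.

    Uses the sample (n-1) standard deviation.  Inverts the multiplicative
    scatter model a*s + b exactly (affine invariance for a > 0).
    """
    def fn(X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise FormatError("SNV is undefined for a constant spectrum")
        return (X - mu) / sd
    return _apply(x, fn)


def derivative(x: ArrayLike, order: int = 1, params: SGParams = SGParams(),
               step_nm: float = 1.0):
    """Savitzky-Golay derivative of the given order (1 or 2 in the workflow)."""
    p = SGParams(params.window, params.polyorder, order)
    return savgol(x, p, step_nm)


class AirPLSResult(NamedTuple):
    baseline: np.ndarray
    corrected: np.ndarray
    converged: bool
    n_iter: int


def _whittaker_banded(lam: float, n: int) -> np.ndarray:
    """Upper-banded (solveh_banded form) representation of lam * D2'D2.

    D2 is the (n-2) x n second-difference operator; D2'D2 is pentadiagonal
    with diagonal [1, 5, 6, ..., 6, 5, 1], first off-diagonal
    [-2, -4, ..., -4, -2] and second off-diagonal all ones.
    """
    ab = np.zeros((3, n))
    ab[0, 2:] = lam                      # second super-diagonal
    ab[1, 1:] = -4.0 * lam               # first super-diagonal
    ab[1, 1] = ab[1, n - 1] = -2.0 * lam
    ab[2, :] = 6.0 * lam                 # main diagonal
    ab[2, 0] = ab[2, n - 1] = lam
    ab[2, 1] = ab[2, n - 2] = 5.0 * lam
    if n == 3:
        ab[2, 1] = 4.0 * lam
    return ab


def _airpls_single(y: np.ndarray, params: AirPLSParams) -> AirPLSResult:
    n = y.size
    pen = _whittaker_banded(params.lam, n)
    w = np.ones(n)
    total = np.abs(y).sum()
    z = y.copy()
    converged = False
    t = 0
    for t in range(1, params.max_iter + 1):
        ab = pen.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        d = y - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn < params.tol_ratio * total:
            converged = True
            break
        w = np.zeros(n)
        w[neg] = np.exp(t * np.abs(d[neg]) / dssn)
        # anchor the ends so the baseline stays attached to the signal
        w[0] = w[-1] = np.exp(t * np.abs(d[neg]).max() / dssn)
    return AirPLSResult(z, y - z, converged, t)


def airpls(x: ArrayLike, params: AirPLSParams = AirPLSParams()):
    """Adaptive iteratively reweighted penalized least squares baseline fit.

    At iteration t the Whittaker smoother minimises
    sum_i w_i (x_i - z_i)^2 + lam * sum (d2 z)^2; weights are zeroed where the
    residual is non-negative (peaks) and grow as exp(t*|d_i|/|d_neg|) below
    the baseline.  Stops when the mass of negative residuals falls under
    ``tol_ratio`` of the total signal.  Non-convergence returns the last
    iterate with ``converged=False`` rather than raising.

    Returns an :class:`AirPLSResult` with ``baseline``/``corrected`` shaped
    like the input (Spectrum in, Spectrum out; matrix in, matrix out).
    """
    if isinstance(x, Spectrum):
        r = _airpls_single(x.absorbance, params)
        return AirPLSResult(x.copy_with(r.baseline), x.copy_with(r.corrected),
                            r.converged, r.n_iter)
    if isinstance(x, SpectraSet):
        res = [_airpls_single(row, params) for row in x.X]
        return AirPLSResult(
            x.with_matrix(np.array([r.baseline for r in res])),
            x.with_matrix(np.array([r.corrected for r in res])),
            all(r.converged for r in res),
            max(r.n_iter for r in res),
        )
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        if arr.size < 3:
            raise ValueError("airPLS needs at least 3 points")
        return _airpls_single(arr, params)
    res = [_airpls_single(row, params) for row in arr]
    return AirPLSResult(np.array([r.baseline for r in res]),
                        np.array([r.corrected for r in res]),
                        all(r.converged for r in res),
                        max(r.n_iter for r in res))


def airpls_correct(x: ArrayLike, params: AirPLSParams = AirPLSParams()):
    """Baseline-corrected signal only (``airpls(...).corrected``)."""
    return airpls(x, params).corrected


# ---------------------------------------------------------------------------
# Fixed pipelines used by the classification/regression workflows.

def pipeline_sg_snv(x: ArrayLike, window: int = 51):
    """S-G smoothing (window 51, cubic) followed by SNV."""
    return snv(savgol(x, SGParams(window=window, polyorder=3, deriv_order=0)))


def pipeline_derivative(x: ArrayLike, order: int = 1, window: int = 51):
    """S-G derivative; order 1 for classification, 2 for adulteration figures."""
    return derivative(x, order=order, params=SGParams(window=window, polyorder=3))


def pipeline_airpls(x: ArrayLike, params: AirPLSParams = AirPLSParams()):
    """airPLS baseline removal alone."""
    return airpls_correct(x, params)


#: Named preprocessing registry used by the evaluation harness.
PIPELINES = {
    "raw": lambda x: x,
    "sg_snv": pipeline_sg_snv,
    "der": pipeline_derivative,
    "airpls": pipeline_airpls,
}
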