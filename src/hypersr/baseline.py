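"""Fluorescence baseline removal by asymmetric weighted least squares (AsLS).

Raman spectra of environmental particles ride on an intense, irregular
fluorescence background that changes from pixel to pixel.  AsLS estimates a
smooth baseline with a Whittaker smoother and iteratively re-weights points:
points above the running baseline (candidate Raman peaks) get the small
weight ``p``, points below get ``1 - p``, so the baseline hugs the lower
envelope of the spectrum.

The smoother solves exactly, per spectrum,

    min_z  sum_i w_i (y_i - z_i)^2 + lam * sum_i (Delta^2 z)_i^2

with a second-order difference penalty, i.e. the banded linear system
(W + lam * D2' D2) z = W y.

Corrected spectra may be slightly negative — no clipping is applied here;
non-negativity is enforced later as an MCR constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, TransformerMixin

from .hyperdata import HyperCube

__all__ = ["BaselineParams", "AslsBaseline", "whittaker_smooth",
           "asls_baseline", "correct_cube", "AslsDivergenceError"]


class AslsDivergenceError(RuntimeError):
    """AsLS objective increased for several consecutive iterations."""

    def __init__(self, trace):
        self.trace = list(trace)
        super().__init__(
            f"AsLS objective increased for 3 consecutive iterations; "
            f"trace={self.trace}"
        )


@dataclass
class BaselineParams:
    """AsLS settings: smoothness weight, asymmetry, iteration control.

    lam : smoothness penalty weight (dimensionless, > 0); larger = stiffer.
    p : asymmetry weight in (0, 1); weight of points above the baseline.
    max_iter : maximum re-weighting iterations.
    tol : fraction of weights allowed to change before we call it converged
          (0.0 = stop only when the weight set is exactly unchanged).
    """

    lam: float = 1e5
    p: float = 1e-3
    max_iter: int = 10
    tol: float = 0.0

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _second_diff_penalty(n: int, lam: float) -> sparse.csc_matrix:
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return (lam * (d2.T @ d2)).tocsc()


def whittaker_smooth(y, lam, w=None):
    """Penalized least-squares smoother with a second-difference penalty.

    Solves (W + lam D2'D2) z = W y exactly via a sparse banded factorization.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("spectrum must be 1-D with length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    n = y.size
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if w.shape != y.shape:
        raise ValueError("weights must match the spectrum length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")
    A = _second_diff_penalty(n, lam) + sparse.diags(w)
    return spsolve(A.tocsc(), w * y)


def _asls_objective(y, z, w, lam):
    d2z = np.diff(z, n=2)
    return float(np.sum(w * (y - z) ** 2) + lam * np.sum(d2z**2))


def asls_baseline(y, params: BaselineParams | None = None):
    """Estimate and subtract a smooth baseline from one spectrum.

    Returns ``(baseline, corrected)`` where ``corrected = y - baseline``.
    Iterates Whittaker smoothing with asymmetric re-weighting until the
    weight set stops changing or ``max_iter`` is reached.  Raises
    :class:`AslsDivergenceError` if the weighted objective increases for
    three consecutive iterations (the safeguard for pathological input).
    """
    if params is None:
        params = BaselineParams()
    y = np.asarray(y, dtype=float)
    w = np.ones(y.size)
    z = whittaker_smooth(y, params.lam, w)
    trace = [_asls_objective(y, z, w, params.lam)]
    n_increase = 0
    for _ in range(params.max_iter - 1):
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        changed = np.mean(w_new != w)
        if changed <= params.tol:
            break
        w = w_new
        z = whittaker_smooth(y, params.lam, w)
        trace.append(_asls_objective(y, z, w, params.lam))
        if trace[-1] > trace[-2] * (1 + 1e-12):
            n_increase += 1
            if n_increase >= 3:
                raise AslsDivergenceError(trace)
        else:
            n_increase = 0
    return z, y - z


class AslsBaseline(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer applying AsLS row-wise to a spectra matrix.

    ``transform(X)`` returns the baseline-corrected spectra; the estimated
    baselines of the last transform are kept in ``baselines_``.  The
    transformer is stateless (``fit`` only validates), so it composes with
    pipelines without leaking information between datasets.
    """

    def __init__(self, lam=1e5, p=1e-3, max_iter=10, tol=0.0):
        self.lam = lam
        self.p = p
        self.max_iter = max_iter
        self.tol = tol

    def _params(self) -> BaselineParams:
        return BaselineParams(lam=self.lam, p=self.p,
                              max_iter=self.max_iter, tol=self.tol)

    def fit(self, X, y=None):
        self._params()  # validate
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_spectra, n_channels)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        params = self._params()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_spectra, n_channels)")
        out = np.empty_like(X)
        baselines = np.empty_like(X)
        for i, row in enumerate(X):
            baselines[i], out[i] = asls_baseline(row, params)
        self.baselines_ = baselines
        return out


def correct_cube(cube: HyperCube, params: BaselineParams | None = None,
                 return_baseline: bool = False):
    """AsLS-correct every pixel spectrum of a cube.

    The corrected cube's ``meta`` records the parameters used.  Per-spectrum
    failures are re-raised with the offending pixel coordinates.
    """
    if params is None:
        params = BaselineParams()
    corrected = np.empty_like(cube.intensities)
    baselines = np.empty_like(cube.intensities)
    for y in range(cube.ny):
        for x in range(cube.nx):
            try:
                b, c = asls_baseline(cube.intensities[y, x], params)
            except Exception as exc:
                raise type(exc)(
                    f"baseline correction failed at pixel (y={y}, x={x}): {exc}"
                ) from exc
            baselines[y, x] = b
            corrected[y, x] = c
    meta = dict(cube.meta)
    meta.update(baseline_lam=params.lam, baseline_p=params.p,
                baseline_max_iter=params.max_iter)
    out = HyperCube(corrected, cube.wavenumbers.copy(),
                    pixel_size=cube.pixel_size, origin=cube.origin, meta=meta)
    if return_baseline:
        base = HyperCube(baselines, cube.wavenumbers.copy(),
                         pixel_size=cube.pixel_size, origin=cube.origin)
        return out, base
    return out
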