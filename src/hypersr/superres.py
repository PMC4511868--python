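"""Multi-frame super-resolution of sub-pixel-shifted chemical maps.

Each low-resolution map C_k (M1 x M2 pixels) is modelled as a warped,
blurred and decimated view of one ideal high-resolution map c:

    C_k = X @ H @ T_k @ c + E_k

where T_k is the known integer translation on the high-resolution grid
(piezo-stage shifts, exact permutation), H is space-invariant blur by the
optical point spread function, X is uniform decimation by the integer
factor k (stride-k subsampling, phase 0) and E_k is additive Gaussian
noise.  With N frames the largest sensible upsampling factor follows the
rule of thumb k = floor(sqrt(N)) (the unknowns k^2*M1*M2 must not exceed
the N*M1*M2 measurements).

The map is recovered by MAP estimation with an L1 data term and a
bilateral total-variation (BTV) prior:

    min_c  sum_k ||X H T_k c - C_k||_1  +  lambda * BTV(c)
    BTV(c) = sum_{(l,m) half-plane, |l|,|m| <= P} alpha^(|l|+|m|)
             * || c - S_x^l S_y^m c ||_1

solved by steepest descent on the sub-gradient (sign(0) = 0), starting
from a shift-and-add estimate.  Steps that would increase the objective
are rejected, so the recorded objective trace is non-increasing; persistent
rejection halves the step once and then aborts with a diagnostic — the
behaviour observed when frame positions are unreliable (e.g. stage
vibrations) and no high-resolution image can be found.

Boundary conventions: T_k is circular (exact permutation); H and the BTV
shifts use symmetric (edge-mirrored) padding.  H is materialized once per
solve as a sparse matrix so its adjoint is exactly its transpose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from .hyperdata import MapImage

__all__ = ["PSFModel", "ShiftedMapSeries", "SRConfig", "SRResult",
           "SuperResolution", "choose_decimation", "apply_forward",
           "apply_adjoint", "initial_estimate", "btv_penalty_gradient",
           "solve_super_resolution", "SRDivergenceError"]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


class SRDivergenceError(RuntimeError):
    """The MAP objective kept increasing after the step-size safeguard."""

    def __init__(self, trace):
        self.trace = list(trace)
        super().__init__(
            "super-resolution solver failed to decrease the objective "
            f"after halving the step; objective trace: {self.trace}"
        )


@dataclass
class PSFModel:
    """Optical blur model: isotropic Gaussian FWHM (μm) or explicit kernel.

    An explicit kernel is given on the high-resolution pixel pitch, must be
    non-negative, and is normalized to unit sum.  Even a rough Gaussian
    guess of the instrument PSF is workable for reconstruction.
    """

    fwhm: float | None = None
    kernel: np.ndarray | None = None

    def __post_init__(self):
        if (self.fwhm is None) == (self.kernel is None):
            raise ValueError("give exactly one of fwhm or kernel")
        if self.kernel is not None:
            self.kernel = np.asarray(self.kernel, dtype=float)
            if self.kernel.ndim != 2 or np.any(self.kernel < 0):
                raise ValueError("kernel must be a non-negative 2-D array")
            s = self.kernel.sum()
            if s <= 0:
                raise ValueError("kernel must have positive sum")
            self.kernel = self.kernel / s
        elif not self.fwhm >= 0:
            raise ValueError("fwhm must be >= 0")

    def kernel_at(self, pitch: float) -> np.ndarray:
        """Normalized convolution kernel sampled at the given pitch (μm)."""
        if self.kernel is not None:
            return self.kernel
        sigma = self.fwhm / FWHM_PER_SIGMA / pitch
        if sigma < 1e-9:
            return np.ones((1, 1))
        r = max(1, int(math.ceil(4.0 * sigma)))
        ax = np.arange(-r, r + 1)
        g = np.exp(-0.5 * (ax / sigma) ** 2)
        k = np.outer(g, g)
        return k / k.sum()


@dataclass
class ShiftedMapSeries:
    """N low-resolution maps with their known sub-pixel stage shifts (μm).

    ``shifts[k] = (dx, dy)`` is the stage translation of frame k relative
    to the reference frame.  All maps share shape and pitch; shifts are
    sub-pixel (|component| < pixel size) unless ``strict=False``.
    """

    maps: list
    shifts: np.ndarray
    lr_pixel_size: float
    strict: bool = True

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=float)
        if len(self.maps) == 0:
            raise ValueError("series needs at least one map")
        if self.shifts.shape != (len(self.maps), 2):
            raise ValueError("shifts must be (N, 2) (dx, dy) in μm")
        shape = self.maps[0].values.shape
        for i, m in enumerate(self.maps):
            if m.values.shape != shape:
                raise ValueError(f"map {i} shape {m.values.shape} != {shape}")
            if abs(m.pixel_size - self.lr_pixel_size) > 1e-12:
                raise ValueError(f"map {i} pixel size differs from series")
        if self.strict and np.any(np.abs(self.shifts) >= self.lr_pixel_size - 1e-12):
            bad = int(np.argmax(np.max(np.abs(self.shifts), axis=1)))
            raise ValueError(
                f"shift {tuple(self.shifts[bad])} of frame {bad} is not "
                f"sub-pixel (pixel size {self.lr_pixel_size} μm)"
            )

    @property
    def n_frames(self) -> int:
        return len(self.maps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[0].values.shape

    def hr_shifts(self, k: int) -> np.ndarray:
        """Shifts in integer high-resolution pixels; validates divisibility."""
        pitch = self.lr_pixel_size / k
        px = self.shifts / pitch
        rounded = np.round(px)
        if np.max(np.abs(px - rounded)) > 1e-6:
            bad = int(np.argmax(np.max(np.abs(px - rounded), axis=1)))
            raise ValueError(
                f"shift {tuple(self.shifts[bad])} μm of frame {bad} is not an "
                f"integer multiple of the HR pitch {pitch} μm"
            )
        return rounded.astype(int)


@dataclass
class SRConfig:
    """Solver settings: upsampling factor, prior weight and descent control.

    k : integer upsampling/decimation factor (L = k*M).
    lambda_reg : BTV prior weight (0 = pure L1 data fit).
    alpha : BTV spatial decay in (0, 1]; P : BTV window radius.
    beta : gradient step; None = 1/N.
    """

    k: int = 1
    lambda_reg: float = 0.01
    alpha: float = 0.7
    P: int = 2
    beta: float | None = None
    n_iter: int = 50
    tol: float = 1e-6
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.P < 0:
            raise ValueError("P must be >= 0")
        if self.beta is not None and not self.beta > 0:
            raise ValueError("beta must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class SRResult:
    """Reconstructed high-resolution map plus solver diagnostics."""

    map: MapImage
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    config: SRConfig | None = None


def choose_decimation(N: int, M1: int | None = None, M2: int | None = None) -> int:
    """Largest integer k with k^2 <= N (unknowns must not exceed data)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return math.isqrt(N)


# ---------------------------------------------------------------------------
# operators

def _mirror(idx: np.ndarray, n: int) -> np.ndarray:
    """Symmetric (edge-inclusive) boundary index fold, period 2n."""
    idx = np.mod(idx, 2 * n)
    return np.where(idx >= n, 2 * n - 1 - idx, idx)


def _blur_matrix(shape: tuple[int, int], kernel: np.ndarray) -> sparse.csr_matrix:
    """Sparse matrix of convolution with symmetric boundary on a 2-D grid."""
    ny, nx = shape
    ky, kx = kernel.shape
    ry, rx = ky // 2, kx // 2
    Y, X = np.mgrid[0:ny, 0:nx]
    rows_base = (Y * nx + X).ravel()
    rows, cols, vals = [], [], []
    for a in range(ky):
        for b in range(kx):
            w = kernel[a, b]
            if w == 0:
                continue
            sy = _mirror(Y + a - ry, ny)
            sx = _mirror(X + b - rx, nx)
            rows.append(rows_base)
            cols.append((sy * nx + sx).ravel())
            vals.append(np.full(ny * nx, w))
    H = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx),
    )
    return H.tocsr()


def _shift_px(shift_um, pitch):
    px = np.asarray(shift_um, dtype=float) / pitch
    rounded = np.round(px)
    if np.max(np.abs(px - rounded)) > 1e-6:
        raise ValueError(
            f"shift {tuple(np.asarray(shift_um))} μm is not an integer "
            f"number of pixels at pitch {pitch} μm"
        )
    return int(rounded[0]), int(rounded[1])


def apply_forward(hr: MapImage, shift, psf: PSFModel, k: int,
                  _H: sparse.csr_matrix | None = None) -> MapImage:
    """One frame of the acquisition model: X H T c.

    ``shift`` is the stage translation (dx, dy) in μm; it must be an integer
    number of high-resolution pixels.  The scene is translated (circular,
    exact permutation), blurred (symmetric boundary) and subsampled every
    k-th pixel starting at index 0.
    """
    ny, nx = hr.values.shape
    if ny % k or nx % k:
        raise ValueError(f"HR dimensions {(ny, nx)} not divisible by k={k}")
    sx, sy = _shift_px(shift, hr.pixel_size)
    t = np.roll(hr.values, shift=(-sy, -sx), axis=(0, 1))
    H = _H if _H is not None else _blur_matrix((ny, nx), psf.kernel_at(hr.pixel_size))
    blurred = (H @ t.ravel()).reshape(ny, nx)
    lr = blurred[::k, ::k]
    return MapImage(lr, pixel_size=hr.pixel_size * k, origin=hr.origin)


def apply_adjoint(lr: MapImage, shift, psf: PSFModel, k: int,
                  _Ht: sparse.csr_matrix | None = None) -> MapImage:
    """Exact adjoint of :func:`apply_forward`: T' H' X'.

    Zero-insertion upsampling, multiplication by the blur transpose, and the
    inverse translation.
    """
    ny, nx = lr.values.shape[0] * k, lr.values.shape[1] * k
    hr_pitch = lr.pixel_size / k
    up = np.zeros((ny, nx))
    up[::k, ::k] = lr.values
    Ht = (_Ht if _Ht is not None
          else _blur_matrix((ny, nx), psf.kernel_at(hr_pitch)).T.tocsr())
    spread = (Ht @ up.ravel()).reshape(ny, nx)
    sx, sy = _shift_px(shift, hr_pitch)
    return MapImage(np.roll(spread, shift=(sy, sx), axis=(0, 1)),
                    pixel_size=hr_pitch, origin=lr.origin)


def initial_estimate(series: ShiftedMapSeries, k: int) -> MapImage:
    """Shift-and-add starting point: upsample, translate back, average."""
    hr_pitch = series.lr_pixel_size / k
    acc = None
    for m, (dx, dy) in zip(series.maps, series.shifts):
        up = np.repeat(np.repeat(m.values, k, axis=0), k, axis=1)
        sx, sy = _shift_px((dx, dy), hr_pitch)
        back = np.roll(up, shift=(sy, sx), axis=(0, 1))
        acc = back if acc is None else acc + back
    return MapImage(acc / series.n_frames, pixel_size=hr_pitch,
                    origin=series.maps[0].origin)


# ---------------------------------------------------------------------------
# bilateral total variation

def _btv_shift_index(shape, dy, dx):
    ny, nx = shape
    Y, X = np.mgrid[0:ny, 0:nx]
    return (_mirror(Y + dy, ny) * nx + _mirror(X + dx, nx)).ravel()


def _btv_terms(P):
    """Half-plane shift set {(l, m)}: m in 0..P, l in -P..P, l>=1 when m=0."""
    return [(l, m) for m in range(0, P + 1)
            for l in range(-P, P + 1)
            if (l, m) != (0, 0) and not (m == 0 and l < 0)]


def btv_penalty_gradient(hr, alpha: float, P: int):
    """BTV penalty value and its sub-gradient (sign(0) = 0 convention).

    Shift operators use symmetric boundary; the gradient applies the exact
    adjoint of each shift so it matches finite differences of the penalty
    away from the kinks of |.|.
    """
    values = hr.values if isinstance(hr, MapImage) else np.asarray(hr, dtype=float)
    flat = values.ravel()
    n = flat.size
    penalty = 0.0
    grad = np.zeros(n)
    for l, m in _btv_terms(P):
        w = alpha ** (abs(l) + abs(m))
        idx = _btv_shift_index(values.shape, m, l)
        diff = flat - flat[idx]
        penalty += w * np.abs(diff).sum()
        sgn = np.sign(diff)
        grad += w * sgn
        np.add.at(grad, idx, -w * sgn)
    return penalty, grad.reshape(values.shape)


# ---------------------------------------------------------------------------
# MAP solver

def solve_super_resolution(series: ShiftedMapSeries, psf: PSFModel,
                           config: SRConfig) -> SRResult:
    """Recover the high-resolution map by L1 + BTV MAP steepest descent.

    Starts from the shift-and-add estimate and iterates
    ``c <- c - beta * (sum_k A_k' sign(A_k c - C_k) + lambda * grad BTV)``.
    Each iteration backtracks (halving the trial step) until the objective
    does not increase, so the recorded trace is non-increasing.  If no
    decrease exists even at a vanishing step, the nominal step is halved
    once; a second such failure raises :class:`SRDivergenceError` — the
    no-solution outcome seen when frame positions are not reproducible.
    """
    k = config.k
    M1, M2 = series.shape
    hr_shape = (M1 * k, M2 * k)
    hr_pitch = series.lr_pixel_size / k
    hr_shifts = series.hr_shifts(k)  # validates the shift grid

    H = _blur_matrix(hr_shape, psf.kernel_at(hr_pitch))
    Ht = H.T.tocsr()
    data = [m.values for m in series.maps]

    def forward(c, sx, sy):
        t = np.roll(c, shift=(-sy, -sx), axis=(0, 1))
        return (H @ t.ravel()).reshape(hr_shape)[::k, ::k]

    def adjoint_sign(r, sx, sy):
        up = np.zeros(hr_shape)
        up[::k, ::k] = r
        spread = (Ht @ up.ravel()).reshape(hr_shape)
        return np.roll(spread, shift=(sy, sx), axis=(0, 1))

    def objective_and_residuals(c):
        obj = 0.0
        residuals = []
        for (sx, sy), C_k in zip(hr_shifts, data):
            r = forward(c, sx, sy) - C_k
            residuals.append((r, sx, sy))
            obj += np.abs(r).sum()
        if config.lambda_reg > 0:
            pen, _ = btv_penalty_gradient(c, config.alpha, config.P)
            obj += config.lambda_reg * pen
        return obj, residuals

    def gradient(c, residuals):
        g = np.zeros(hr_shape)
        for r, sx, sy in residuals:
            g += adjoint_sign(np.sign(r), sx, sy)
        if config.lambda_reg > 0:
            _, gb = btv_penalty_gradient(c, config.alpha, config.P)
            g += config.lambda_reg * gb
        return g

    c = initial_estimate(series, k).values
    beta = config.beta if config.beta is not None else 1.0 / series.n_frames
    obj, residuals = objective_and_residuals(c)
    trace = [obj]
    converged = False
    halved = False
    max_backtracks = 30
    for _ in range(config.n_iter):
        g = gradient(c, residuals)
        step = beta
        accepted = False
        for _bt in range(max_backtracks + 1):
            c_trial = c - step * g
            obj_trial, res_trial = objective_and_residuals(c_trial)
            if obj_trial <= obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # even a vanishing step increases the objective: either a
            # sub-gradient stall at the optimum (treated as converged) or a
            # genuinely inconsistent problem -> halve once, then abort
            if abs(obj_trial - obj) <= config.tol * max(obj, 1e-15):
                converged = True
                break
            if not halved:
                beta *= 0.5
                halved = True
                continue
            raise SRDivergenceError(trace)
        delta = obj - obj_trial
        c, obj, residuals = c_trial, obj_trial, res_trial
        trace.append(obj)
        if delta <= config.tol * max(obj, 1e-15):
            converged = True
            break

    return SRResult(
        map=MapImage(c, pixel_size=hr_pitch, origin=series.maps[0].origin),
        objective_trace=trace, converged=converged, config=config,
    )


class SuperResolution(BaseEstimator):
    """Estimator facade over the MAP solver.

    ``fit(series)`` solves the inverse problem and exposes ``map_``,
    ``objective_trace_`` and ``converged_``.  ``k=None`` picks the factor
    with the frame-count rule.
    """

    def __init__(self, k=None, psf_fwhm=0.59, psf_kernel=None,
                 lambda_reg=0.01, alpha=0.7, P=2, beta=None, n_iter=50,
                 tol=1e-6):
        self.k = k
        self.psf_fwhm = psf_fwhm
        self.psf_kernel = psf_kernel
        self.lambda_reg = lambda_reg
        self.alpha = alpha
        self.P = P
        self.beta = beta
        self.n_iter = n_iter
        self.tol = tol

    def fit(self, series: ShiftedMapSeries, y=None):
        k = self.k if self.k is not None else choose_decimation(series.n_frames)
        psf = (PSFModel(kernel=self.psf_kernel) if self.psf_kernel is not None
               else PSFModel(fwhm=self.psf_fwhm))
        config = SRConfig(k=k, lambda_reg=self.lambda_reg, alpha=self.alpha,
                          P=self.P, beta=self.beta, n_iter=self.n_iter,
                          tol=self.tol)
        result = solve_super_resolution(series, psf, config)
        self.result_ = result
        self.map_ = result.map
        self.objective_trace_ = result.objective_trace
        self.converged_ = result.converged
        self.k_ = k
        return self
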