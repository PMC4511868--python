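"""Multivariate curve resolution by alternating least squares (MCR-ALS).

The bilinear model of hyperspectral unmixing is ``D = C @ St + E``: the
unfolded pixel-spectra matrix D (pixels x wavenumbers) is the product of
per-pixel component concentrations C and pure component spectra St (rows),
plus residual E.  ALS alternates constrained least-squares updates of C
given St and of St given C.  Constraints here: element-wise non-negativity
(concentrations and Raman intensities are physical) and unit Euclidean norm
of every pure spectrum (kills the intrinsic scale ambiguity).

Rank is probed by SVD; initial spectra come from SIMPLISMA, which picks the
"purest" pixel spectra by a purity-ratio / determinant sequence.  Fit
quality is tracked by the lack of fit lof = 100*sqrt(sum E^2 / sum D^2) and
explained variance r2 = 100*(1 - sum E^2 / sum D^2); the two are tied by
r2 = 100*(1 - (lof/100)^2).

Several cubes sharing a wavenumber axis can be fit jointly by stacking
their unfolded rows (a column-wise augmented multiset); the model then has
one shared St and a block of C rows per cube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .hyperdata import MultisetMatrix

__all__ = ["MCRModel", "SimplismaParams", "MCRALS", "svd_scree",
           "simplisma_init", "mcr_als", "fit_metrics"]


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, MultisetMatrix):
        return D.data
    return np.asarray(D, dtype=float)


@dataclass
class MCRModel:
    """A fitted bilinear decomposition D ~= C @ St."""

    C: np.ndarray
    St: np.ndarray
    E: np.ndarray
    lof: float
    r2: float
    n_iter: int
    converged: bool
    constraints: dict = field(default_factory=dict)
    lof_trace: list = field(default_factory=list)


@dataclass
class SimplismaParams:
    """SIMPLISMA settings: number of components and the noise offset alpha
    (fraction of the largest row mean added to purity denominators)."""

    n_components: int = 2
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


def fit_metrics(D, E):
    """Lack of fit (%) and explained variance (%) of a residual E against D."""
    D = _as_matrix(D)
    E = np.asarray(E, dtype=float)
    if D.shape != E.shape:
        raise ValueError(f"shape mismatch: D {D.shape} vs E {E.shape}")
    ss_d = float(np.sum(D * D))
    if ss_d == 0:
        raise ValueError("sum of squared data is zero; lof undefined")
    ratio = float(np.sum(E * E)) / ss_d
    return 100.0 * np.sqrt(ratio), 100.0 * (1.0 - ratio)


def svd_scree(D, threshold=1e-2):
    """All singular values (descending) and a suggested rank.

    The suggestion counts singular values with sigma_i / sigma_1 above
    ``threshold``; it is a starting point the analyst confirms, not a
    decision (minor components at low SNR fall below any fixed cut).
    """
    D = _as_matrix(D)
    if D.ndim != 2:
        raise ValueError("D must be a matrix")
    s = np.linalg.svd(D, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        warnings.warn("degenerate (all-zero) matrix: suggested rank 0")
        return s, 0
    rank = int(np.sum(s / s[0] >= threshold))
    return s, rank


def simplisma_init(D, params: SimplismaParams | None = None, **kwargs):
    """Select the purest pixel spectra as initial St estimates (SIMPLISMA).

    For each row i let mu_i, sigma_i be its mean and standard deviation over
    wavenumbers and ``offset = alpha * max_j mu_j``.  The first pick
    maximizes the purity ``p_i = sigma_i / (mu_i + offset)``; subsequent
    picks maximize ``p_i * det(COO)`` where COO is the correlation-around-
    origin matrix of the length-scaled candidates already selected plus i,
    which drives selections toward mutually independent rows.

    Returns the selected rows, stacked as an (n_components, n_wavenumbers)
    array, plus the selected row indices in ``.selected_`` order.
    """
    if params is None:
        params = SimplismaParams(**kwargs) if kwargs else SimplismaParams()
    X = _as_matrix(D)
    n_rows, n_cols = X.shape
    ncomp = params.n_components
    if ncomp > min(n_rows, n_cols):
        raise ValueError("n_components exceeds matrix dimensions")
    if len(np.unique(X, axis=0)) < ncomp:
        raise ValueError("fewer distinct rows than requested components")

    mu = X.mean(axis=1)
    sigma = X.std(axis=1)
    offset = params.alpha * float(mu.max())
    purity = sigma / (mu + offset + np.finfo(float).tiny)
    # length-scaled rows for the determinant weighting
    norm = np.sqrt(mu**2 + (sigma + offset) ** 2)
    Z = X / (norm[:, None] + np.finfo(float).tiny)

    selected: list[int] = []
    for _ in range(ncomp):
        if not selected:
            weights = np.ones(n_rows)
        else:
            S = Z[selected]
            base = S @ S.T / n_cols
            cross = Z @ S.T / n_cols
            diag = np.einsum("ij,ij->i", Z, Z) / n_cols
            weights = np.empty(n_rows)
            for i in range(n_rows):
                m = np.empty((len(selected) + 1, len(selected) + 1))
                m[0, 0] = diag[i]
                m[0, 1:] = cross[i]
                m[1:, 0] = cross[i]
                m[1:, 1:] = base
                weights[i] = np.linalg.det(m)
        score = purity * np.maximum(weights, 0.0)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))

    return _SimplismaResult(X[selected].copy(), selected)


class _SimplismaResult(np.ndarray):
    """An (n_components, n_wavenumbers) array carrying the picked row ids."""

    def __new__(cls, arr, selected):
        obj = np.asarray(arr, dtype=float).view(cls)
        obj.selected_ = list(selected)
        return obj

    def __array_finalize__(self, obj):
        if obj is not None:
            self.selected_ = getattr(obj, "selected_", None)


# ---------------------------------------------------------------------------
# ALS core

def _ls_rows(A, B, nonneg, mode):
    """Solve min ||B - X A|| row-wise for X (shape rows(B) x rows(A))."""
    if nonneg and mode == "nnls":
        At = A.T
        X = np.empty((B.shape[0], A.shape[0]))
        for i in range(B.shape[0]):
            X[i], _ = nnls(At, B[i])
        return X
    sol, _, rank, _ = np.linalg.lstsq(A.T, B.T, rcond=None)
    if rank < A.shape[0]:
        warnings.warn("rank-deficient normal equations; pseudo-inverse fallback")
    X = sol.T
    if nonneg:
        X = np.maximum(X, 0.0)
    return X


def mcr_als(D, St0, nonneg=True, normalize=True, tol=1e-3, max_iter=50,
            nonneg_mode="nnls") -> MCRModel:
    """Alternating least squares on D with initial spectra St0.

    Each cycle updates C given St (row-wise constrained LS), measures the
    lack of fit, then updates St given C and re-normalizes the spectra
    (concentrations are rescaled so C @ St is unchanged).  Stops when the
    relative change of lof between consecutive cycles drops below ``tol``
    (default 0.1%) or at ``max_iter``; a model that hits max_iter is
    returned flagged unconverged.
    """
    X = _as_matrix(D)
    St = np.asarray(St0, dtype=float).copy()
    if St.ndim != 2 or St.shape[1] != X.shape[1]:
        raise ValueError("St0 must be (n_components, n_wavenumbers)")
    if not np.all(np.isfinite(X)):
        raise ValueError("D contains non-finite values")
    if normalize:
        St = _normalize_rows(St)[0]

    lof_trace: list[float] = []
    converged = False
    C = np.zeros((X.shape[0], St.shape[0]))
    for it in range(1, max_iter + 1):
        C = _ls_rows(St, X, nonneg, nonneg_mode)
        E = X - C @ St
        lof, _ = fit_metrics(X, E)
        lof_trace.append(lof)
        if len(lof_trace) >= 2:
            prev = lof_trace[-2]
            if abs(prev - lof) < tol * max(prev, 1e-12) or lof < 1e-10:
                converged = True
                break
        elif lof < 1e-10:
            converged = True
            break
        St = _ls_rows(C.T, X.T, nonneg, nonneg_mode).T
        if normalize:
            St, norms = _normalize_rows(St)
            C = C * norms[None, :]

    E = X - C @ St
    lof, r2 = fit_metrics(X, E)
    order = np.argsort(-np.sum(C * C, axis=0))  # by explained-variance share
    return MCRModel(
        C=C[:, order], St=St[order], E=E, lof=lof, r2=r2, n_iter=it,
        converged=converged,
        constraints={"nonneg": bool(nonneg), "nonneg_mode": nonneg_mode,
                     "normalize": "St rows, unit Euclidean norm" if normalize else None},
        lof_trace=lof_trace,
    )


def _normalize_rows(St):
    norms = np.linalg.norm(St, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return St / safe[:, None], safe


class MCRALS(BaseEstimator):
    """Scikit-learn style MCR-ALS decomposition estimator.

    Parameters
    ----------
    n_components : int or None
        Model rank.  None = take the SVD scree suggestion at ``svd_threshold``.
    init : "simplisma" or array (n_components, n_wavenumbers)
        Initial pure-spectra estimates.
    alpha : float
        SIMPLISMA noise offset (fraction of the largest row mean).
    nonneg, normalize : bool
        Apply non-negativity (both factors) and unit-norm St rows.
    nonneg_mode : "nnls" or "clip"
        Active-set NNLS per row/column, or plain LS clipped at zero (fast).
    tol : float
        Relative lack-of-fit change that counts as converged (default 0.1%).

    Attributes (after ``fit``): ``C_``, ``St_``, ``E_``, ``lof_``, ``r2_``,
    ``n_iter_``, ``converged_``, ``singular_values_``, ``lof_trace_``.
    """

    def __init__(self, n_components=None, init="simplisma", alpha=0.05,
                 nonneg=True, normalize=True, nonneg_mode="nnls",
                 tol=1e-3, max_iter=50, svd_threshold=1e-2):
        self.n_components = n_components
        self.init = init
        self.alpha = alpha
        self.nonneg = nonneg
        self.normalize = normalize
        self.nonneg_mode = nonneg_mode
        self.tol = tol
        self.max_iter = max_iter
        self.svd_threshold = svd_threshold

    def fit(self, D, y=None):
        X = _as_matrix(D)
        s, suggested = svd_scree(X, threshold=self.svd_threshold)
        self.singular_values_ = s
        ncomp = self.n_components if self.n_components is not None else max(suggested, 1)
        if isinstance(self.init, str) and self.init == "simplisma":
            St0 = simplisma_init(X, SimplismaParams(ncomp, self.alpha))
        else:
            St0 = np.asarray(self.init, dtype=float)
            if St0.shape[0] != ncomp:
                raise ValueError("init spectra count does not match n_components")
        model = mcr_als(X, St0, nonneg=self.nonneg, normalize=self.normalize,
                        tol=self.tol, max_iter=self.max_iter,
                        nonneg_mode=self.nonneg_mode)
        self.model_ = model
        self.C_ = model.C
        self.St_ = model.St
        self.E_ = model.E
        self.lof_ = model.lof
        self.r2_ = model.r2
        self.n_iter_ = model.n_iter
        self.converged_ = model.converged
        self.lof_trace_ = model.lof_trace
        return self

    def transform(self, D):
        """Concentrations of new spectra under the fitted pure spectra."""
        X = _as_matrix(D)
        return _ls_rows(self.St_, X, self.nonneg, self.nonneg_mode)

    def fit_transform(self, D, y=None):
        return self.fit(D).C_
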