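"""Quintic smoothing splines for digitized marker trajectories.

High-speed-video digitization leaves frame-to-frame jitter that is fatal to
finite-difference differentiation, so coordinates are smoothed before any
kinematic quantity is computed.  The smoother is a penalized quintic
regression spline: a degree-5 B-spline basis on the (uniform) frame grid,
fit by ridge regression with a roughness penalty on the integrated squared
third derivative,

    min_f  sum_i (y_i - f(t_i))^2 + lam * int f'''(t)^2 dt.

The null space of the penalty contains all quadratics, so a ballistic
(constant-acceleration) flight arc is reproducible without shrinkage at any
penalty, and the quintic basis reproduces polynomials up to degree five
exactly when the penalty is small.  The penalty weight is chosen by
generalized cross-validation (GCV) unless a fixed value is supplied.

The x and y coordinates of a marker share a single penalty weight selected
by joint GCV.  Because the hat matrix then depends only on the time grid,
smoothing commutes with rotations and translations of the coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = ["SmoothingSettings", "smooth_series", "SmoothingResult"]

_DEGREE = 5
# third-derivative products of a quintic are piecewise quartic; 3-point
# Gauss-Legendre integrates quartics exactly
_N_GAUSS = 3
_MAX_BASIS = 120


@dataclass(frozen=True)
class SmoothingSettings:
    """How marker coordinates are smoothed.

    method : "gcv" selects the penalty by generalized cross-validation;
        "fixed" uses ``penalty`` as given (on the unit-interval rescaled
        time axis; useful for bitwise-reproducible tests).
    penalty : fixed penalty weight, required when method == "fixed".
    max_basis : cap on the number of B-spline basis functions.
    """

    method: str = "gcv"
    penalty: float | None = None
    max_basis: int = _MAX_BASIS

    def __post_init__(self) -> None:
        if self.method not in ("gcv", "fixed"):
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if self.method == "fixed" and (self.penalty is None or self.penalty < 0):
            raise ValueError("method='fixed' requires a non-negative penalty")


@dataclass(frozen=True)
class SmoothingResult:
    values: np.ndarray
    penalty: float
    edof: float  # effective degrees of freedom tr(H)


def _basis(n: int, max_basis: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix, penalty matrix and knot vector on t in [0, 1]."""
    x = np.linspace(0.0, 1.0, n)
    n_interior = max(0, min(n - _DEGREE - 3, max_basis - _DEGREE - 1))
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    t = np.concatenate(
        [np.zeros(_DEGREE + 1), interior, np.ones(_DEGREE + 1)]
    )
    nb = len(t) - _DEGREE - 1
    A = BSpline.design_matrix(x, t, _DEGREE).toarray()

    # penalty int B_i''' B_j''' via exact Gauss quadrature per knot span
    spans = np.unique(t)
    nodes, weights = leggauss(_N_GAUSS)
    mids = 0.5 * (spans[1:] + spans[:-1])
    half = 0.5 * np.diff(spans)
    xq = (mids[:, None] + half[:, None] * nodes[None, :]).ravel()
    wq = np.repeat(half, _N_GAUSS) * np.tile(weights, len(half))
    d3 = BSpline(t, np.eye(nb), _DEGREE).derivative(3)(xq)
    P = d3.T @ (wq[:, None] * d3)
    return A, P, t


def _fit(A: np.ndarray, P: np.ndarray, Y: np.ndarray, lam: float):
    M = A.T @ A + lam * P
    nb = M.shape[0]
    try:
        c = cho_factor(M)
    except np.linalg.LinAlgError:
        c = cho_factor(M + 1e-12 * np.trace(M) / nb * np.eye(nb))
    coef = cho_solve(c, A.T @ Y)
    edof = float(np.trace(cho_solve(c, A.T @ A)))
    return coef, edof


def smooth_series(
    Y: np.ndarray, settings: SmoothingSettings | None = None
) -> SmoothingResult:
    """Smooth one or several coordinate series sampled on a uniform grid.

    Y has shape (n,) or (n, m); columns share the penalty weight (joint GCV
    across columns), which is what makes smoothing equivariant under
    rotations mixing the columns.
    """
    settings = settings or SmoothingSettings()
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, m = Y.shape
    if n < _DEGREE + 3:
        raise ValueError(
            f"quintic smoothing needs at least {_DEGREE + 3} frames, got {n}"
        )
    if np.ptp(Y, axis=0).max() == 0.0:
        # degenerate: a stationary marker is already smooth
        out = Y[:, 0] if squeeze else Y
        return SmoothingResult(out.copy(), 0.0, float(min(n, 1)))

    A, P, _ = _basis(n, settings.max_basis)
    scale = np.trace(A.T @ A) / np.trace(P)

    if settings.method == "fixed":
        lam = float(settings.penalty)  # type: ignore[arg-type]
        coef, edof = _fit(A, P, Y, lam)
    else:
        best = None
        for lam in scale * np.logspace(-10.0, 3.0, 40):
            coef, edof = _fit(A, P, Y, lam)
            rss = float(np.sum((Y - A @ coef) ** 2))
            denom = max(1.0 - edof / n, 1e-10) ** 2
            gcv = rss / (m * n) / denom
            if best is None or gcv < best[0]:
                best = (gcv, lam, coef, edof)
        _, lam, coef, edof = best  # type: ignore[misc]

    out = A @ coef
    if squeeze:
        out = out[:, 0]
    return SmoothingResult(out, float(lam), edof)
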