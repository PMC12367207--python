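"""Whittaker-smoother baseline estimation with adaptive iterative reweighting.

The baseline ``z`` of an observed spectrum ``y`` minimises a penalized
least-squares loss balancing two terms::

    sum_i w_i (y_i - z_i)**2  +  lam * || D^(p) z ||**2

where ``D^(p)`` is the order-``p`` forward-difference operator, ``lam``
weights smoothness against fidelity and the weights ``w`` are updated
adaptively: channels lying above the current baseline (peaks) receive
weight zero, channels below it are emphasised exponentially, so over the
iterations the smoother relaxes onto the lower envelope of the spectrum
(airPLS).  Each iterate solves the banded symmetric positive-definite
normal equations ``(W + lam * D'D) z = W y`` via a Cholesky
factorisation, costing O(n) time and memory.

Three parameters govern a fit: ``lam`` (smoothness weight, larger means
smoother), ``tau`` (convergence tolerance on the negative-residual mass,
smaller means more iterations) and ``p`` (difference order, 1 or 2).
The classical defaults are ``(lam=100, tau=1e-3, p=1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.linalg import solve_banded, solveh_banded

__all__ = [
    "Spectrum",
    "AirPLSParams",
    "BaselineFitResult",
    "build_penalty",
    "weighted_whittaker",
    "airpls_baseline",
    "airpls_fit",
    "DEFAULT_PARAMS",
]

# Clip on the reweighting exponent: preserves weight ordering while
# keeping the Whittaker system factorizable in double precision
# (exp(50)^2 ~ 3e43 stays far from overflow during the Cholesky).
_EXP_CLIP = 50.0
_MIN_POINTS = 8


@dataclass
class Spectrum:
    """A single spectrum on a strictly increasing wavenumber grid.

    Synthetic spectra additionally carry the ground-truth decomposition
    (``true_signal`` + ``true_baseline``), a shape label such as ``"B&E"``
    and, when noise was added, the target signal-to-noise ratio.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    true_baseline: np.ndarray | None = None
    true_signal: np.ndarray | None = None
    shape_label: str | None = None
    snr: float | None = None
    spectrum_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        n = self.wavenumbers.size
        if n < _MIN_POINTS:
            raise ValueError(f"spectrum needs at least {_MIN_POINTS} points, got {n}")
        if self.intensities.size != n:
            raise ValueError("wavenumbers and intensities lengths differ")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        for name in ("true_baseline", "true_signal"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{name} length differs from grid length")
                setattr(self, name, v)

    @property
    def n(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray, **meta) -> "Spectrum":
        """Copy of this spectrum with new intensities; merges ``meta``."""
        out = replace(self, intensities=np.asarray(intensities, dtype=float))
        out.meta = {**self.meta, **meta}
        return out


@dataclass(frozen=True)
class AirPLSParams:
    """Parameters of one airPLS fit: ``(lam, tau, p, max_iter)``."""

    lam: float = 100.0
    tau: float = 1e-3
    p: int = 1
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.p not in (1, 2):
            raise ValueError("difference order p must be 1 or 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")

    @classmethod
    def defaults(cls) -> "AirPLSParams":
        """Classical airPLS defaults (lam=100, tau=1e-3, p=1)."""
        return cls()

    @classmethod
    def optimized(cls, lam: float, tau: float, max_iter: int = 100) -> "AirPLSParams":
        """Parameters for the optimized mode, which fixes ``p = 2``."""
        return cls(lam=lam, tau=tau, p=2, max_iter=max_iter)


DEFAULT_PARAMS = AirPLSParams()


@dataclass
class BaselineFitResult:
    """Outcome of one airPLS fit.

    ``weights_final`` holds the weights used in the last linear solve,
    normalized by their maximum so entries lie in [0, 1]; ``weight_scale``
    is that maximum, so ``weight_scale * weights_final`` reproduces the
    raw weights of the final Whittaker system.
    """

    baseline: np.ndarray
    corrected: np.ndarray
    weights_final: np.ndarray
    iterations: int
    converged: bool
    weight_scale: float = 1.0


def build_penalty(n: int, p: int) -> sparse.csc_matrix:
    """Return the order-``p`` difference penalty ``D'D`` as a sparse matrix.

    ``D`` is the (n-p) x n forward-difference operator; the product is
    positive semidefinite with a null space of polynomials of degree < p.
    """
    if p not in (1, 2):
        raise ValueError("difference order p must be 1 or 2")
    if n <= p:
        raise ValueError(f"grid length n={n} must exceed difference order p={p}")
    D = sparse.identity(n, format="csc")
    for _ in range(p):
        D = D[1:] - D[:-1]
    return (D.T @ D).tocsc()


def _penalty_bands(n: int, p: int) -> np.ndarray:
    """Upper-banded storage of ``D'D`` for :func:`scipy.linalg.solveh_banded`."""
    DtD = build_penalty(n, p).todia()
    ab = np.zeros((p + 1, n))
    for k in range(p + 1):
        ab[p - k, k:] = DtD.diagonal(k)
    return ab


def weighted_whittaker(
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    p: int = 2,
    _pen_bands: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the weighted Whittaker system ``(W + lam*D'D) z = W y``.

    Uses a banded Cholesky solve (O(n)).  ``_pen_bands`` lets callers
    reuse ``lam * D'D`` bands across repeated solves on the same grid.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.ndim != 1 or w.shape != y.shape:
        raise ValueError("y and w must be 1-D arrays of equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities contain non-finite values")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("all-zero weights make the system singular")
    if not lam > 0:
        raise ValueError("lam must be positive")

    if _pen_bands is None:
        _pen_bands = lam * _penalty_bands(y.size, p)
    ab = _pen_bands.copy()
    ab[-1] += w
    try:
        z = solveh_banded(ab, w * y, lower=False)
        if np.all(np.isfinite(z)):
            return z
    except np.linalg.LinAlgError:
        pass
    # Extreme weight dynamic range can defeat the Cholesky; fall back to
    # a pivoted banded LU on the full (non-symmetric storage) band.
    p = ab.shape[0] - 1
    n = y.size
    ab_full = np.zeros((2 * p + 1, n))
    ab_full[: p + 1] = ab
    for k in range(1, p + 1):
        ab_full[p + k, : n - k] = ab[p - k, k:]
    z = solve_banded((p, p), ab_full, w * y)
    if not np.all(np.isfinite(z)):
        raise np.linalg.LinAlgError("weighted Whittaker system is numerically singular")
    return z


def airpls_baseline(
    y: np.ndarray, params: AirPLSParams = DEFAULT_PARAMS
) -> BaselineFitResult:
    """Run the adaptive iteratively reweighted fit on a raw intensity vector.

    Iteration ``t`` solves the Whittaker system with the current weights,
    forms the residual ``d = y - z`` and the negative-residual mass
    ``m = sum(|d_i|, d_i < 0)``, and stops when ``m < tau * sum(|y|)``.
    Otherwise weights are updated to ``0`` where ``d_i >= 0`` and
    ``exp(t*|d_i|/m)`` where ``d_i < 0`` (exponent clipped for overflow
    safety, ``m`` floored to avoid 0/0).  Initial weights are all ones.
    Hitting ``max_iter`` returns ``converged=False`` rather than raising.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities contain non-finite values")
    n = y.size
    if n <= params.p:
        raise ValueError("spectrum too short for the requested difference order")

    abs_sum = float(np.sum(np.abs(y)))
    if abs_sum == 0.0:
        zeros = np.zeros(n)
        return BaselineFitResult(zeros, zeros.copy(), np.ones(n), 1, True, 1.0)

    pen = params.lam * _penalty_bands(n, params.p)
    w = np.ones(n)
    m_floor = np.finfo(float).eps * abs_sum
    threshold = params.tau * abs_sum

    z = y.copy()
    w_used = w
    converged = False
    t = 0
    for t in range(1, params.max_iter + 1):
        w_used = w
        z = weighted_whittaker(y, w, params.lam, params.p, _pen_bands=pen)
        d = y - z
        neg = d < 0
        m = float(np.sum(np.abs(d[neg])))
        if m < threshold:
            converged = True
            break
        m = max(m, m_floor)
        w_new = np.zeros(n)
        w_new[neg] = np.exp(np.minimum(t * np.abs(d[neg]) / m, _EXP_CLIP))
        w = w_new

    scale = float(np.max(w_used))
    w_norm = w_used / scale if scale > 0 else w_used
    return BaselineFitResult(
        baseline=z,
        corrected=y - z,
        weights_final=w_norm,
        iterations=t,
        converged=converged,
        weight_scale=scale,
    )


def airpls_fit(spectrum: Spectrum, params: AirPLSParams = DEFAULT_PARAMS) -> BaselineFitResult:
    """Fit the airPLS baseline of a :class:`Spectrum`."""
    return airpls_baseline(spectrum.intensities, params)
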