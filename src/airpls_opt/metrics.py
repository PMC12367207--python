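"""Evaluation mathematics for baseline-correction quality.

Core quantities:

- ``mae(a, b)`` — mean absolute error between a fitted and a true baseline;
- ``percentage_improvement(mae_ref, mae_new)`` — signed relative MAE
  reduction in percent; 90% corresponds to one order of magnitude, 99% to
  two.  Negative values mean the new method is worse than the reference;
- ``pct_above`` — fraction of spectra whose improvement clears a threshold;
- ``loc_lic`` — logarithmic-center / linear-center parameter averages;
- ``fit_parameter_region`` — ordinary least squares of log10(tau*) on
  log10(lam*), describing the diagonal valley where optimal parameters
  concentrate;
- ``confidence_ellipse`` — chi-square-scaled covariance ellipse of 2-D
  parameter clouds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationRecord",
    "ParameterRegionFit",
    "ConfidenceEllipse",
    "mae",
    "percentage_improvement",
    "pct_above",
    "cosine_similarity",
    "loc_lic",
    "fit_parameter_region",
    "confidence_ellipse",
    "records_to_frame",
    "summarize_by_shape",
]


@dataclass
class EvaluationRecord:
    """Per-spectrum evaluation of baseline-removal strategies.

    ``mae_*`` fields are mean absolute errors of the fitted baseline
    against the true baseline under different parameter choices:
    ``dp`` defaults, ``op`` grid-search optimum, ``ml`` model-predicted,
    ``loc``/``lic`` averaged-parameter strategies.  ``pi``/``pi_ml`` are
    the corresponding signed percentage improvements over ``dp``.
    """

    spectrum_id: str | None = None
    shape_label: str | None = None
    mae_dp: float | None = None
    mae_op: float | None = None
    mae_ml: float | None = None
    mae_loc: float | None = None
    mae_lic: float | None = None
    pi: float | None = None
    pi_ml: float | None = None
    extras: dict = field(default_factory=dict)


def mae(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute error between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def percentage_improvement(mae_ref: float, mae_new: float) -> float:
    """Signed relative MAE reduction, in percent.

    ``(mae_ref - mae_new) / mae_ref * 100``: 90 means a tenfold error
    reduction, 0 no change, negative values a degradation.  A zero
    reference (degenerate perfect fit) returns 0 with a warning rather
    than dividing by zero.
    """
    if mae_ref < 0 or mae_new < 0:
        raise ValueError("MAE values must be nonnegative")
    if mae_ref == 0:
        warnings.warn("reference MAE is zero; defining improvement as 0", stacklevel=2)
        return 0.0
    return (mae_ref - mae_new) / mae_ref * 100.0


def pct_above(pis, threshold: float) -> float:
    """Percent of entries at or above ``threshold``."""
    pis = np.asarray(list(pis), dtype=float)
    if pis.size == 0:
        raise ValueError("empty improvement list")
    return float(np.mean(pis >= threshold) * 100.0)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two spectra, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def loc_lic(pairs) -> tuple[tuple[float, float], tuple[float, float]]:
    """Logarithmic-center and linear-center of a set of (lam, tau) pairs.

    LOC is the elementwise geometric mean (the midpoint in log space),
    LIC the elementwise arithmetic mean.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("empty parameter set")
    arr = arr.reshape(-1, 2)
    if np.any(arr <= 0):
        raise ValueError("parameters must be positive")
    loc = tuple(10.0 ** np.mean(np.log10(arr), axis=0))
    lic = tuple(np.mean(arr, axis=0))
    return loc, lic


@dataclass
class ParameterRegionFit:
    """OLS fit of log10(tau*) on log10(lam*) over optimized pairs."""

    slope: float
    intercept: float
    r_squared: float
    lam_log_range: tuple[float, float]
    n_pairs: int

    def predict_log_tau(self, log_lam: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(log_lam, dtype=float) + self.intercept


def fit_parameter_region(pairs) -> ParameterRegionFit:
    """Fit the diagonal optimal-parameter region in log-log space."""
    arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(arr <= 0):
        raise ValueError("parameters must be positive")
    x = np.log10(arr[:, 0])
    y = np.log10(arr[:, 1])
    if np.ptp(x) == 0:
        raise ValueError("all lam values identical: slope undefined")
    res = stats.linregress(x, y)
    return ParameterRegionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        lam_log_range=(float(x.min()), float(x.max())),
        n_pairs=arr.shape[0],
    )


@dataclass
class ConfidenceEllipse:
    """Covariance ellipse of a 2-D sample at a given confidence level.

    Semi-axes are ``sqrt(eigenvalue * chi2.ppf(level, df=2))``; ``angle``
    is the orientation of the major axis in radians.
    """

    center: np.ndarray
    semi_axes: np.ndarray  # descending
    angle: float
    level: float
    _cov_inv: np.ndarray = field(repr=False, default=None)
    _radius2: float = field(repr=False, default=0.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        d2 = np.einsum("ij,jk,ik->i", pts, self._cov_inv, pts)
        return d2 <= self._radius2


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> ConfidenceEllipse:
    """Chi-square confidence ellipse of a 2-D point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n, 2) array with n >= 3")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1e-300):
        raise ValueError("points are (nearly) collinear: degenerate covariance")
    r2 = float(stats.chi2.ppf(level, df=2))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(
        center=center,
        semi_axes=np.sqrt(evals * r2),
        angle=angle,
        level=level,
        _cov_inv=np.linalg.inv(cov),
        _radius2=r2,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate evaluation records (one row per spectrum)."""
    rows = []
    for r in records:
        row = {
            "spectrum_id": r.spectrum_id,
            "shape_label": r.shape_label,
            "mae_dp": r.mae_dp,
            "mae_op": r.mae_op,
            "mae_ml": r.mae_ml,
            "mae_loc": r.mae_loc,
            "mae_lic": r.mae_lic,
            "pi": r.pi,
            "pi_ml": r.pi_ml,
        }
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_shape(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-shape mean and standard deviation of every numeric metric."""
    numeric = frame.select_dtypes("number").columns
    grouped = frame.groupby("shape_label")[list(numeric)]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{c}_{s}" for c, s in out.columns]
    return out.reset_index()
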