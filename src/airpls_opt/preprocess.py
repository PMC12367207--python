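"""Conditioning of measured spectra before parameter prediction.

Parameter prediction is trained on noise-free synthetic spectra and
degrades quickly with channel noise, so measured spectra are smoothed
first.  The standard choice is a Savitzky-Golay filter with window 15
and polynomial order 2, which raises the SNR of typical instrument
spectra above ~100 while preserving peak shapes.

The SNR estimator here is an implementer convention (max smoothed
signal amplitude above a quick baseline proxy, over a robust
first-difference noise estimate); it is monotone in the constructed SNR
of synthetic spectra and is only used for reporting and sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .baseline import AirPLSParams, Spectrum, airpls_baseline

__all__ = [
    "DenoiseSpec",
    "savgol_denoise",
    "estimate_snr",
    "resample_to_grid",
    "SNR_CAP",
]

# sentinel cap reported for (near-)noise-free spectra
SNR_CAP = 1e6

# Gaussian MAD constant: median|d| = 0.6745 * sigma_d for d ~ N(0, sigma_d)
_MAD_TO_SIGMA = 0.67448975

# For white noise e, std(diff(e - savgol(e, 15, 2))) = 1.419 * sigma:
# differencing inflates by sqrt(2) and the subtracted smooth removes part
# of the noise again.  Calibrated once on pure Gaussian noise.
_RESID_DIFF_TO_SIGMA = 1.419


@dataclass(frozen=True)
class DenoiseSpec:
    """Savitzky-Golay window (odd channel count) and polynomial order."""

    window_length: int = 15
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length < 3:
            raise ValueError("window_length must be an odd integer >= 3")
        if not 0 <= self.poly_order < self.window_length:
            raise ValueError("poly_order must be nonnegative and < window_length")


def savgol_denoise(spectrum: Spectrum, spec: DenoiseSpec = DenoiseSpec()) -> Spectrum:
    """Savitzky-Golay smooth the intensities.

    Edges use polynomial interpolation (``mode='interp'``), so inputs
    that are globally polynomial of degree <= ``poly_order`` pass
    through unchanged, boundaries included.
    """
    if spectrum.n < spec.window_length:
        raise ValueError(
            f"spectrum has {spectrum.n} points; window is {spec.window_length}"
        )
    smoothed = savgol_filter(
        spectrum.intensities, spec.window_length, spec.poly_order, mode="interp"
    )
    return spectrum.with_intensities(
        smoothed,
        denoised={"window_length": spec.window_length, "poly_order": spec.poly_order},
    )


def estimate_snr(spectrum: Spectrum, cap: float = SNR_CAP) -> float:
    """Estimate the signal-to-noise ratio of a spectrum.

    Signal amplitude: maximum of the smoothed spectrum above a quick
    airPLS baseline proxy.  Noise: robust (median-absolute-deviation)
    standard deviation of the first differences of the smoother
    residual ``y - savgol(y)``, divided by the white-noise calibration
    constant of that statistic.  Estimates beyond ``cap``
    (near-noise-free inputs) are reported as ``cap``.
    """
    y = spectrum.intensities
    if spectrum.n < 32:
        raise ValueError("need at least 32 channels to estimate SNR")
    if np.ptp(y) == 0:
        raise ValueError("SNR undefined for a constant spectrum")
    smooth = savgol_filter(y, 15, 2, mode="interp")
    proxy = airpls_baseline(
        smooth, AirPLSParams.optimized(1e4, 1e-6, max_iter=30)
    ).baseline
    amplitude = float(np.max(smooth - proxy))
    resid_diffs = np.abs(np.diff(y - smooth))
    sigma = float(np.median(resid_diffs)) / (_MAD_TO_SIGMA * _RESID_DIFF_TO_SIGMA)
    if sigma <= 0 or amplitude / sigma > cap:
        return float(cap)
    return amplitude / sigma


def resample_to_grid(spectrum: Spectrum, target_grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``target_grid`` (no extrapolation)."""
    target = np.asarray(target_grid, dtype=float)
    src = spectrum.wavenumbers
    if target[0] < src[0] or target[-1] > src[-1]:
        raise ValueError(
            "target grid extends beyond the source wavenumber range; "
            "refusing to extrapolate"
        )
    if np.any(np.diff(target) <= 0):
        raise ValueError("target grid must be strictly increasing")

    def interp(v):
        return None if v is None else np.interp(target, src, v)

    return Spectrum(
        wavenumbers=target,
        intensities=np.interp(target, src, spectrum.intensities),
        true_baseline=interp(spectrum.true_baseline),
        true_signal=interp(spectrum.true_signal),
        shape_label=spectrum.shape_label,
        snr=spectrum.snr,
        spectrum_id=spectrum.spectrum_id,
        meta={**spectrum.meta, "resampled": True},
    )
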