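"""Synthetic SERS spectra with known ground-truth baselines.

Spectra are built as ``intensities = true_signal + true_baseline (+ noise)``
from three Gaussian-peak families and four smooth baseline families:

peak families
    ``B`` (broad): 2-4 wide peaks (FWHM >= 15% of the wavenumber range)
    at a much larger intensity scale than the other families;
    ``C`` (convoluted): 6-12 narrow peaks whose centers are spaced closer
    than 1.5x their FWHM, so the envelopes overlap;
    ``D`` (distinct): 5-10 narrow peaks separated by more than 3x their
    FWHM, so every peak is resolved;
    ``B+C``: one B draw plus one C draw (compound peak shape).

baseline families
    ``E`` exponential decay, ``G`` wide Gaussian, ``P`` fifth-order
    polynomial (rescaled to stay nonnegative), ``S`` sigmoidal step.
    Compound baselines (``E+P``, ``E+G``, ``E+S``, ``G+S``) average two
    families with equal 0.5/0.5 weights.

A shape code joins the two family abbreviations with ``&``; e.g. ``B&E``
is broad peaks on an exponential baseline.  The 3 x 4 simple families
give the 12 canonical shapes.  Gaussian noise is added at a target
signal-to-noise ratio defined as ``max(true_signal) / noise_std``.

All randomness flows through :class:`numpy.random.SeedSequence` streams
derived from integer seeds, so datasets are bit-reproducible and each
spectrum can be regenerated in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .baseline import Spectrum

__all__ = [
    "SyntheticShapeSpec",
    "NoiseSpec",
    "Dataset",
    "PEAK_FAMILIES",
    "BASELINE_FAMILIES",
    "COMPOUND_BASELINES",
    "all_simple_shapes",
    "compound_shapes",
    "generate_baseline",
    "generate_peaks",
    "generate_spectrum",
    "generate_dataset",
    "add_noise",
    "SNR_LEVELS",
]

PEAK_FAMILIES = ("B", "C", "D")
BASELINE_FAMILIES = ("E", "G", "P", "S")
COMPOUND_BASELINES = ("E+P", "E+G", "E+S", "G+S")
COMPOUND_PEAK = "B+C"

# noise ladder spanning the experimentally observed range
SNR_LEVELS = tuple(np.round(np.geomspace(6.47, 49.92, 10), 2))

# broad peaks carry a ~100x larger intensity scale than convoluted/distinct
AMPLITUDE_SCALES = {"B": 100.0, "C": 1.0, "D": 1.0, "B+C": 100.0}

DEFAULT_WAVENUMBER_RANGE = (400.0, 2000.0)
DEFAULT_N_POINTS = 1024

# substream tags keeping peak, baseline and noise draws independent
_ROLE_PEAKS = 11
_ROLE_BASELINE = 23
_ROLE_NOISE = 37


def all_simple_shapes() -> list[str]:
    """The 12 canonical shape codes, e.g. ``['B&E', 'B&G', ...]``."""
    return [f"{p}&{b}" for p, b in itertools.product(PEAK_FAMILIES, BASELINE_FAMILIES)]


def compound_shapes() -> list[str]:
    """The 12 compound shapes: simple peaks on two-family mean baselines."""
    return [f"{p}&{b}" for p, b in itertools.product(PEAK_FAMILIES, COMPOUND_BASELINES)]


@dataclass(frozen=True)
class SyntheticShapeSpec:
    """Recipe for one synthetic spectrum.

    ``amplitude_scale=None`` selects the family default (broad peaks are
    simulated at ~100x the intensity of convoluted/distinct ones, which
    reproduces the characteristic gap in absolute baseline errors
    between the families).
    """

    peak_type: str = "D"
    baseline_type: str = "E"
    amplitude_scale: float | None = None
    n_points: int = DEFAULT_N_POINTS
    wavenumber_range: tuple[float, float] = DEFAULT_WAVENUMBER_RANGE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_type not in (*PEAK_FAMILIES, COMPOUND_PEAK):
            raise ValueError(f"unknown peak type {self.peak_type!r}")
        valid_baselines = (*BASELINE_FAMILIES, *COMPOUND_BASELINES)
        if self.baseline_type not in valid_baselines:
            raise ValueError(f"unknown baseline type {self.baseline_type!r}")
        if self.n_points < 8:
            raise ValueError("n_points must be at least 8")
        lo, hi = self.wavenumber_range
        if not hi > lo:
            raise ValueError("wavenumber_range must be increasing")

    @property
    def label(self) -> str:
        return f"{self.peak_type}&{self.baseline_type}"

    @property
    def scale(self) -> float:
        if self.amplitude_scale is not None:
            return self.amplitude_scale
        return AMPLITUDE_SCALES[self.peak_type]

    @property
    def baseline_ratio(self) -> float:
        """Background amplitude relative to the peak scale."""
        return _BROAD_BASELINE_RATIO if "B" in self.peak_type else 1.0

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "SyntheticShapeSpec":
        peak, baseline = label.split("&")
        return cls(peak_type=peak, baseline_type=baseline, **kwargs)

    def grid(self) -> np.ndarray:
        lo, hi = self.wavenumber_range
        return np.linspace(lo, hi, self.n_points)


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean i.i.d. Gaussian channel noise at a target SNR.

    SNR convention: ``max(true_signal) / noise_std``.
    """

    snr: float
    replicate_index: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def _role_rng(seed: int, role: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), role, sub]))


def _gaussian(x: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# Backgrounds ride on a large constant offset (~2x the varying amplitude),
# as fluorescence pedestals in measured SERS spectra do.  The offset is in
# the null space of both difference penalties, so it does not change what
# an optimally tuned fit can recover, but it does enter the convergence
# normalization of the default-parameter fit.
_BASELINE_OFFSET_FACTOR = 2.0

# Broad-peak spectra are peak-dominated: the background amplitude is a
# modest fraction of the (large) peak scale rather than tracking it one-to-one.
_BROAD_BASELINE_RATIO = 0.15


def _single_baseline(
    btype: str, x: np.ndarray, scale: float, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = float(x[0]), float(x[-1])
    width = hi - lo
    a = scale * rng.uniform(0.5, 1.5)
    c0 = scale * _BASELINE_OFFSET_FACTOR * rng.uniform(0.8, 1.2)
    if btype == "E":
        b = rng.uniform(0.5, 2.0) / width
        return a * np.exp(-b * (x - lo)) + c0
    if btype == "G":
        mu = rng.uniform(lo, hi)
        sigma = width * rng.uniform(0.5, 1.0)
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + c0
    if btype == "P":
        u = 2.0 * (x - lo) / width - 1.0
        # geometric decay keeps high-order terms gentle (slowly varying)
        coeffs = rng.standard_normal(6) * 0.4 ** np.arange(6)
        v = np.polynomial.polynomial.polyval(u, coeffs)
        v = v - v.min()
        vmax = v.max()
        if vmax > 1.0:  # cap the swing at a; never amplify a flat draw
            v = v / vmax
        return a * v + c0
    if btype == "S":
        k = rng.uniform(3.5, 6.5) / width
        xc = lo + width * rng.uniform(0.2, 0.8)
        return a / (1.0 + np.exp(-k * (x - xc))) + c0
    raise ValueError(f"unknown baseline type {btype!r}")


def generate_baseline(
    spec: SyntheticShapeSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the true baseline of ``spec`` on its wavenumber grid.

    Compound types (``"E+S"`` etc.) are the elementwise mean of the two
    named families, each drawn from its own substream ``(seed, role, k)``
    with ``k`` the component index, so components are reproducible.
    """
    x = spec.grid()
    scale = spec.scale * spec.baseline_ratio
    parts = spec.baseline_type.split("+")
    if len(parts) == 1:
        if rng is None:
            rng = _role_rng(spec.rng_seed, _ROLE_BASELINE, 0)
        return _single_baseline(parts[0], x, scale, rng)
    components = [
        _single_baseline(p, x, scale, _role_rng(spec.rng_seed, _ROLE_BASELINE, k))
        for k, p in enumerate(parts)
    ]
    return np.mean(components, axis=0)


def compound_baseline_components(spec: SyntheticShapeSpec) -> list[np.ndarray]:
    """The individual component baselines of a compound baseline spec."""
    x = spec.grid()
    scale = spec.scale * spec.baseline_ratio
    parts = spec.baseline_type.split("+")
    return [
        _single_baseline(p, x, scale, _role_rng(spec.rng_seed, _ROLE_BASELINE, k))
        for k, p in enumerate(parts)
    ]


def _draw_peak_params(
    ptype: str, lo: float, hi: float, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Draw (center, sigma, amplitude) triples for one peak family.

    Amplitudes here are relative; the caller rescales the summed signal.
    """
    width = hi - lo
    peaks: list[tuple[float, float, float]] = []
    if ptype == "B":
        # 2-3 broad peaks confined to the mid-range so signal-free
        # margins anchor the baseline on both sides
        n_peaks = int(rng.integers(2, 4))
        fwhms = width * rng.uniform(0.15, 0.17, size=n_peaks)
        min_sep = 1.2 * float(fwhms.max())
        start = lo + width * rng.uniform(0.25, 0.35)
        span = (lo + 0.80 * width) - start
        slack = max(span - (n_peaks - 1) * min_sep, 0.005 * width)
        offsets = np.sort(rng.uniform(0.0, slack, size=n_peaks))
        centers = start + offsets + np.arange(n_peaks) * min_sep
        for center, fwhm in zip(centers, fwhms):
            peaks.append((float(center), fwhm * _FWHM_TO_SIGMA, rng.uniform(0.3, 1.0)))
    elif ptype == "C":
        n_peaks = int(rng.integers(6, 11))
        mean_fwhm = width * rng.uniform(0.03, 0.045)
        center = lo + width * rng.uniform(0.15, 0.40)
        for _ in range(n_peaks):
            fwhm = mean_fwhm * rng.uniform(0.8, 1.2)
            peaks.append((center, fwhm * _FWHM_TO_SIGMA, rng.uniform(0.3, 1.0)))
            # spacing < 1.5x every FWHM (draws are within 0.8-1.2x the mean)
            center += mean_fwhm * rng.uniform(0.5, 1.15)
    elif ptype == "D":
        n_peaks = int(rng.integers(5, 8))
        fwhms = width * rng.uniform(0.02, 0.03, size=n_peaks)
        min_sep = 3.2 * float(fwhms.max())
        span = 0.7 * width
        slack = span - (n_peaks - 1) * min_sep
        offsets = np.sort(rng.uniform(0.0, slack, size=n_peaks))
        centers = lo + 0.15 * width + offsets + np.arange(n_peaks) * min_sep
        for center, fwhm in zip(centers, fwhms):
            peaks.append((float(center), fwhm * _FWHM_TO_SIGMA, rng.uniform(0.3, 1.0)))
    else:
        raise ValueError(f"unknown peak type {ptype!r}")
    return peaks


def generate_peaks(
    spec: SyntheticShapeSpec,
    rng: np.random.Generator | None = None,
    return_params: bool = False,
):
    """Draw the true (noise-free) peak signal of ``spec``.

    The summed Gaussian signal is rescaled so its maximum is
    ``amplitude_scale * U(0.7, 1.3)``.  With ``return_params=True``
    also returns the list of (center, sigma, amplitude) triples after
    rescaling.
    """
    x = spec.grid()
    lo, hi = float(x[0]), float(x[-1])
    if rng is None:
        rng = _role_rng(spec.rng_seed, _ROLE_PEAKS, 0)
    parts = spec.peak_type.split("+")
    peaks: list[tuple[float, float, float]] = []
    for ptype in parts:
        peaks.extend(_draw_peak_params(ptype, lo, hi, rng))
    signal = np.zeros_like(x)
    for center, sigma, amp in peaks:
        signal += _gaussian(x, center, sigma, amp)
    target_max = spec.scale * rng.uniform(0.7, 1.3)
    factor = target_max / signal.max()
    signal *= factor
    if return_params:
        scaled = [(c, s, a * factor) for c, s, a in peaks]
        return signal, scaled
    return signal


def generate_spectrum(spec: SyntheticShapeSpec, spectrum_id: str | None = None) -> Spectrum:
    """Assemble a noise-free spectrum: peaks + baseline on the grid."""
    x = spec.grid()
    signal = generate_peaks(spec)
    baseline = generate_baseline(spec)
    return Spectrum(
        wavenumbers=x,
        intensities=signal + baseline,
        true_baseline=baseline,
        true_signal=signal,
        shape_label=spec.label,
        spectrum_id=spectrum_id,
        meta={"rng_seed": int(spec.rng_seed)},
    )


@dataclass
class Dataset:
    """An ordered collection of spectra sharing one wavenumber grid."""

    spectra: list[Spectrum]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for s in self.spectra[1:]:
                if s.n != grid.size or not np.array_equal(s.wavenumbers, grid):
                    raise ValueError("all spectra in a dataset must share one grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Dataset(self.spectra[i], dict(self.meta))
        return self.spectra[i]

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def labels(self) -> list[str | None]:
        return [s.shape_label for s in self.spectra]

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_channels) array of intensities."""
        return np.vstack([s.intensities for s in self.spectra])

    def subset(self, indices) -> "Dataset":
        return Dataset([self.spectra[i] for i in indices], dict(self.meta))


def _spectrum_seed(master_seed: int, shape_index: int, i: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(shape_index), int(i)])
    return int(ss.generate_state(1)[0])


def generate_dataset(
    shapes: list[str] | None = None,
    n_per_shape: int = 500,
    master_seed: int = 0,
    n_points: int = DEFAULT_N_POINTS,
    wavenumber_range: tuple[float, float] = DEFAULT_WAVENUMBER_RANGE,
) -> Dataset:
    """Generate ``n_per_shape`` spectra for each shape code.

    The default 12 shapes at 500 spectra each give the 6000-spectrum
    study scale.  Each spectrum's seed is derived from
    ``(master_seed, shape_index, i)``, so the dataset is reproducible
    and any single spectrum can be regenerated alone.
    """
    if shapes is None:
        shapes = all_simple_shapes()
    if n_per_shape < 1:
        raise ValueError("n_per_shape must be >= 1")
    spectra = []
    for shape_index, label in enumerate(shapes):
        for i in range(n_per_shape):
            seed = _spectrum_seed(master_seed, shape_index, i)
            spec = SyntheticShapeSpec.from_label(
                label,
                n_points=n_points,
                wavenumber_range=wavenumber_range,
                rng_seed=seed,
            )
            spectra.append(generate_spectrum(spec, spectrum_id=f"{label}_{i:04d}"))
    return Dataset(
        spectra,
        meta={
            "master_seed": int(master_seed),
            "shapes": list(shapes),
            "n_per_shape": int(n_per_shape),
            "n_points": int(n_points),
            "wavenumber_range": [float(wavenumber_range[0]), float(wavenumber_range[1])],
        },
    )


def add_noise(spectrum: Spectrum, noise: NoiseSpec) -> Spectrum:
    """Add zero-mean Gaussian noise at the target SNR.

    ``noise_std = max(true_signal) / snr``; the true decomposition is
    preserved so ``intensities - true_signal - true_baseline`` recovers
    the noise draw exactly.
    """
    if spectrum.true_signal is None:
        raise ValueError("add_noise requires a spectrum with true_signal (SNR is referenced to the signal)")
    sigma = float(np.max(spectrum.true_signal)) / noise.snr
    rng = _role_rng(noise.rng_seed, _ROLE_NOISE, noise.replicate_index)
    draw = rng.normal(0.0, sigma, size=spectrum.n)
    out = spectrum.with_intensities(
        spectrum.intensities + draw, noise_sigma=sigma, replicate_index=noise.replicate_index
    )
    out.snr = float(noise.snr)
    return out
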