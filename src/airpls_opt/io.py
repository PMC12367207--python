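"""Reading and writing spectra, datasets, configs and result tables.

Formats (all plain text, '.' decimal, UTF-8):

- single spectrum: two-column delimited file (wavenumber, intensity);
  delimiter autodetected among comma/tab/whitespace, header optional;
- dataset: a directory with wide matrix CSVs (first column the
  wavenumber grid, one column per spectrum) for intensities and, when
  present, true baselines and true signals, plus ``manifest.json``
  carrying per-spectrum metadata (shape label, seed, SNR);
- configs: JSON round-trips of the dataclasses used by the CLI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import Spectrum
from .simulate import Dataset

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_dataset",
    "write_dataset",
    "read_matrix",
]


def read_spectrum(path: str | Path, spectrum_id: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text file."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    # drop a header row if the first row is not numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    # astype(float) goes through Python's exact string conversion, so
    # full-precision payloads round-trip bit-identically
    df = df.astype(float)
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 columns in {path}, found {df.shape[1]}")
    return Spectrum(
        wavenumbers=df.iloc[:, 0].to_numpy(),
        intensities=df.iloc[:, 1].to_numpy(),
        spectrum_id=spectrum_id or Path(path).stem,
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV with a header line."""
    df = pd.DataFrame(
        {"wavenumber": spectrum.wavenumbers, "intensity": spectrum.intensities}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _ids(dataset: Dataset) -> list[str]:
    return [s.spectrum_id or f"spectrum_{i:05d}" for i, s in enumerate(dataset)]


def _write_matrix(path: Path, grid: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame({"wavenumber": grid, **columns})
    df.to_csv(path, index=False, float_format="%.17g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a wide matrix CSV: (grid, {spectrum_id: values})."""
    df = pd.read_csv(path, float_precision="round_trip")
    grid = df.iloc[:, 0].to_numpy(dtype=float)
    cols = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return grid, cols


def write_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    """Persist a dataset as matrix CSVs plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = _ids(dataset)
    grid = dataset.wavenumbers
    _write_matrix(
        out / "intensities.csv",
        grid,
        {i: s.intensities for i, s in zip(ids, dataset)},
    )
    if all(s.true_baseline is not None for s in dataset):
        _write_matrix(
            out / "baselines.csv",
            grid,
            {i: s.true_baseline for i, s in zip(ids, dataset)},
        )
    if all(s.true_signal is not None for s in dataset):
        _write_matrix(
            out / "signals.csv",
            grid,
            {i: s.true_signal for i, s in zip(ids, dataset)},
        )
    manifest = {
        "meta": dataset.meta,
        "spectra": {
            i: {"shape_label": s.shape_label, "snr": s.snr, **s.meta}
            for i, s in zip(ids, dataset)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(in_dir: str | Path) -> Dataset:
    """Load a dataset written by :func:`write_dataset`."""
    src = Path(in_dir)
    grid, intens = read_matrix(src / "intensities.csv")
    baselines: dict[str, np.ndarray] = {}
    signals: dict[str, np.ndarray] = {}
    if (src / "baselines.csv").exists():
        _, baselines = read_matrix(src / "baselines.csv")
    if (src / "signals.csv").exists():
        _, signals = read_matrix(src / "signals.csv")
    manifest = {"meta": {}, "spectra": {}}
    if (src / "manifest.json").exists():
        manifest = json.loads((src / "manifest.json").read_text())
    if len(set(intens)) != len(intens):
        raise ValueError("duplicate spectrum ids in dataset")
    spectra = []
    for sid, y in intens.items():
        info = manifest["spectra"].get(sid, {})
        meta = {
            k: v for k, v in info.items() if k not in ("shape_label", "snr")
        }
        spectra.append(
            Spectrum(
                wavenumbers=grid,
                intensities=y,
                true_baseline=baselines.get(sid),
                true_signal=signals.get(sid),
                shape_label=info.get("shape_label"),
                snr=info.get("snr"),
                spectrum_id=sid,
                meta=meta,
            )
        )
    return Dataset(spectra, meta=manifest.get("meta", {}))
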