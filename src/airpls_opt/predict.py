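"""Machine-learned prediction of optimal airPLS parameters (PCA-RF).

Grid-searched optimal parameters are expensive (they need both compute
and a known true baseline).  This module learns the mapping

    spectrum intensities  ->  (log10 lam*, log10 tau*)

with a principal-component projection followed by a 100-tree random
forest regressing both targets jointly.  Targets live in log space,
where the optimal parameters of all spectral shapes cluster along a
diagonal band.

Includes a stratified 8:1:1 train/validation/test splitter, model
persistence, outlier flagging and per-shape evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from .baseline import AirPLSParams, Spectrum, airpls_baseline
from .metrics import (
    EvaluationRecord,
    mae,
    pct_above,
    percentage_improvement,
    records_to_frame,
)
from .optimize import DP_PARAMS
from .preprocess import resample_to_grid
from .simulate import Dataset

__all__ = [
    "SplitSpec",
    "PredictorConfig",
    "ParamPredictor",
    "split_dataset",
    "train",
    "predict_params",
    "evaluate_model",
    "is_outlier",
]

TAU_CLAMP = (1e-12, 0.5)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test split specification."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    stratify_by: str = "shape_label"

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if any(r < 0 for r in self.ratios):
            raise ValueError("split ratios must be nonnegative")


@dataclass(frozen=True)
class PredictorConfig:
    """PCA-RF hyperparameters.

    The component count is the smallest explaining ``pca_variance`` of
    the training variance, capped at ``max_components`` (spectra are
    smooth and low-rank, so few components suffice).
    """

    n_trees: int = 100
    pca_variance: float = 0.995
    max_components: int = 50
    seed: int = 0


def split_dataset(
    dataset: Dataset, spec: SplitSpec = SplitSpec()
) -> tuple[Dataset, Dataset, Dataset]:
    """Split per shape with exact floor counts (remainder goes to train).

    With 500 spectra per shape at 8:1:1 this yields 400/50/50.
    Deterministic under ``spec.seed``; membership is disjoint.
    """
    labels = [s.shape_label for s in dataset]
    if any(l is None for l in labels):
        raise ValueError("split requires shape labels on every spectrum")
    groups: dict[str, list[int]] = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, []).append(i)
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    for label in sorted(groups):
        idx = np.array(groups[label])
        if idx.size < 10:
            raise ValueError(f"shape {label} has {idx.size} spectra; need >= 10 to split")
        perm = rng.permutation(idx.size)
        n_val = int(np.floor(idx.size * spec.ratios[1]))
        n_test = int(np.floor(idx.size * spec.ratios[2]))
        n_train = idx.size - n_val - n_test
        shuffled = idx[perm]
        train_idx.extend(shuffled[:n_train])
        val_idx.extend(shuffled[n_train : n_train + n_val])
        test_idx.extend(shuffled[n_train + n_val :])
    return (
        dataset.subset(sorted(train_idx)),
        dataset.subset(sorted(val_idx)),
        dataset.subset(sorted(test_idx)),
    )


@dataclass
class ParamPredictor:
    """Fitted PCA + random-forest parameter predictor."""

    pca: PCA
    n_components: int
    forest: RandomForestRegressor
    grid: np.ndarray
    config: PredictorConfig
    metadata: dict = field(default_factory=dict)

    def transform(self, intensities: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(intensities, dtype=float))
        return self.pca.transform(X)[:, : self.n_components]

    def predict_log(self, intensities: np.ndarray) -> np.ndarray:
        """(log10 lam, log10 tau) predictions, one row per spectrum."""
        return np.atleast_2d(self.forest.predict(self.transform(intensities)))

    def save(self, path: str | Path) -> None:
        """Persist the model plus a JSON sidecar of its configuration."""
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "n_components": int(self.n_components),
            "n_trees": int(self.config.n_trees),
            "seed": int(self.config.seed),
            "grid_length": int(self.grid.size),
            "grid_range": [float(self.grid[0]), float(self.grid[-1])],
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ParamPredictor":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a ParamPredictor")
        return model


def _labels_to_array(train_set: Dataset, labels) -> np.ndarray:
    """Coerce labels (mapping id->(lam, tau) or array-like) to (n, 2)."""
    if isinstance(labels, dict):
        arr = np.array([labels[s.spectrum_id] for s in train_set], dtype=float)
    elif isinstance(labels, pd.DataFrame):
        lookup = labels.set_index("spectrum_id")[["lam_star", "tau_star"]]
        arr = lookup.loc[[s.spectrum_id for s in train_set]].to_numpy(dtype=float)
    else:
        arr = np.asarray(labels, dtype=float)
    if arr.shape != (len(train_set), 2):
        raise ValueError(f"expected {(len(train_set), 2)} label array, got {arr.shape}")
    if np.any(arr <= 0):
        raise ValueError("parameter labels must be positive")
    return arr


def train(
    train_set: Dataset, labels, config: PredictorConfig = PredictorConfig()
) -> ParamPredictor:
    """Fit the PCA-RF model on training spectra and their (lam*, tau*)."""
    if len(train_set) == 0:
        raise ValueError("empty training set")
    y = np.log10(_labels_to_array(train_set, labels))
    X = train_set.intensity_matrix()
    cap = min(config.max_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=cap, svd_solver="full", random_state=config.seed)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cum, config.pca_variance) + 1)
    n_components = min(n_components, cap)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    forest.fit(scores[:, :n_components], y)
    shapes = sorted({s.shape_label for s in train_set if s.shape_label})
    return ParamPredictor(
        pca=pca,
        n_components=n_components,
        forest=forest,
        grid=train_set.wavenumbers.copy(),
        config=config,
        metadata={"n_train": len(train_set), "shapes": shapes},
    )


def predict_params(model: ParamPredictor, spectrum: Spectrum) -> tuple[float, float]:
    """Predict (lam, tau) for one spectrum.

    Spectra on a different grid are linearly resampled onto the model's
    grid first (an error if the model grid is not covered).  tau is
    clamped into (1e-12, 0.5).
    """
    if spectrum.n != model.grid.size or not np.allclose(
        spectrum.wavenumbers, model.grid
    ):
        spectrum = resample_to_grid(spectrum, model.grid)
    log_lam, log_tau = model.predict_log(spectrum.intensities)[0]
    lam = float(10.0**log_lam)
    tau = float(np.clip(10.0**log_tau, *TAU_CLAMP))
    return lam, tau


def is_outlier(pi_ml: float, mae_ml: float, mae_op: float | None = None) -> bool:
    """Outlier predicate for a prediction: degraded versus the default
    fit, or an order of magnitude worse than the grid-search optimum."""
    if pi_ml < 0:
        return True
    if mae_op is not None and mae_op > 0 and mae_ml > 10.0 * mae_op:
        return True
    return False


def evaluate_model(
    model: ParamPredictor,
    test_set: Dataset,
    mae_op: dict[str, float] | None = None,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-spectrum and per-shape evaluation of predicted parameters.

    For each test spectrum: fit the baseline at the predicted (lam, tau)
    with ``p=2``, compute MAE against the true baseline, the signed
    improvement over the default-parameter fit, and the outlier flag
    (using grid-search MAEs when supplied as ``mae_op``).

    Returns ``(records, per_shape_summary)``.  The summary carries the
    mean/std improvement with and without outliers and the percent of
    spectra clearing the 70% and 80% improvement thresholds.
    """
    records = []
    for s in test_set:
        if s.true_baseline is None:
            raise ValueError("evaluation requires true baselines")
        lam, tau = predict_params(model, s)
        fit = airpls_baseline(
            s.intensities, AirPLSParams.optimized(lam, tau, max_iter=max_iter)
        )
        mae_ml = mae(fit.baseline, s.true_baseline)
        dp = airpls_baseline(s.intensities, DP_PARAMS)
        mae_dp = mae(dp.baseline, s.true_baseline)
        pi_ml = percentage_improvement(mae_dp, mae_ml)
        op = mae_op.get(s.spectrum_id) if mae_op else None
        records.append(
            EvaluationRecord(
                spectrum_id=s.spectrum_id,
                shape_label=s.shape_label,
                mae_dp=mae_dp,
                mae_ml=mae_ml,
                pi_ml=pi_ml,
                extras={
                    "lam_hat": lam,
                    "tau_hat": tau,
                    "mae_op": op,
                    "outlier": is_outlier(pi_ml, mae_ml, op),
                },
            )
        )
    frame = records_to_frame(records)
    rows = []
    for label, grp in frame.groupby("shape_label"):
        keep = grp[~grp.outlier]
        rows.append(
            {
                "shape_label": label,
                "n": len(grp),
                "pi_ml_mean": grp.pi_ml.mean(),
                "pi_ml_std": grp.pi_ml.std(),
                "pi_ml_mean_no_outliers": keep.pi_ml.mean() if len(keep) else np.nan,
                "pi_ml_std_no_outliers": keep.pi_ml.std() if len(keep) else np.nan,
                "pct_ge_70": pct_above(grp.pi_ml, 70.0),
                "pct_ge_80": pct_above(grp.pi_ml, 80.0),
                "outlier_fraction": grp.outlier.mean(),
            }
        )
    return frame, pd.DataFrame(rows)
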