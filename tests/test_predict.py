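"""Tests of the stratified splitter and the PCA-RF parameter predictor."""

import numpy as np
import pandas as pd
import pytest

from airpls_opt.metrics import mae
from airpls_opt.baseline import AirPLSParams, airpls_fit
from airpls_opt.predict import (
    ParamPredictor,
    PredictorConfig,
    SplitSpec,
    evaluate_model,
    is_outlier,
    predict_params,
    split_dataset,
    train,
)
from airpls_opt.simulate import generate_dataset

CFG = PredictorConfig(n_trees=25, seed=0)  # small forest for unit tests


@pytest.fixture(scope="module")
def small_dataset():
    return generate_dataset(
        ["C&G", "D&P", "B&E"], n_per_shape=10, master_seed=21, n_points=256
    )


@pytest.fixture(scope="module")
def trained(small_dataset):
    tr, va, te = split_dataset(small_dataset, SplitSpec(seed=3))
    # synthetic but realistic labels: one tight cluster per shape
    centers = {"C&G": (2.0, -7.0), "D&P": (1.0, -8.0), "B&E": (4.0, -5.0)}
    rng = np.random.default_rng(0)
    labels = np.array(
        [
            (
                10.0 ** (centers[s.shape_label][0] + rng.normal(0, 0.05)),
                10.0 ** (centers[s.shape_label][1] + rng.normal(0, 0.05)),
            )
            for s in tr
        ]
    )
    return train(tr, labels, CFG), tr, te, centers


class TestSplit:
    def test_exact_stratified_counts(self, small_dataset):
        tr, va, te = split_dataset(small_dataset, SplitSpec(seed=1))
        assert len(tr) == 24 and len(va) == 3 and len(te) == 3
        for part, n in ((tr, 8), (va, 1), (te, 1)):
            counts = pd.Series([s.shape_label for s in part]).value_counts()
            assert (counts == n).all()

    def test_deterministic_and_disjoint(self, small_dataset):
        a = split_dataset(small_dataset, SplitSpec(seed=5))
        b = split_dataset(small_dataset, SplitSpec(seed=5))
        ids = lambda d: [s.spectrum_id for s in d]
        assert all(ids(x) == ids(y) for x, y in zip(a, b))
        all_ids = ids(a[0]) + ids(a[1]) + ids(a[2])
        assert len(all_ids) == len(set(all_ids)) == len(small_dataset)

    def test_seed_changes_membership(self, small_dataset):
        a = split_dataset(small_dataset, SplitSpec(seed=1))
        b = split_dataset(small_dataset, SplitSpec(seed=2))
        assert [s.spectrum_id for s in a[2]] != [s.spectrum_id for s in b[2]]

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(ratios=(0.5, 0.2, 0.2))

    def test_too_few_per_shape_rejected(self):
        ds = generate_dataset(["C&G"], n_per_shape=5, master_seed=0, n_points=128)
        with pytest.raises(ValueError, match="need >= 10"):
            split_dataset(ds)


class TestTrainPredict:
    def test_constant_labels_give_constant_predictions(self, small_dataset):
        tr, _, te = split_dataset(small_dataset, SplitSpec(seed=3))
        labels = np.tile([1e3, 1e-5], (len(tr), 1))
        model = train(tr, labels, CFG)
        for s in te:
            lam, tau = predict_params(model, s)
            assert lam == pytest.approx(1e3, rel=1e-9)
            assert tau == pytest.approx(1e-5, rel=1e-9)

    def test_prediction_deterministic(self, trained):
        model, _, te, _ = trained
        p1 = predict_params(model, te[0])
        p2 = predict_params(model, te[0])
        assert p1 == p2

    def test_predictions_near_shape_cluster(self, trained):
        # held-out spectra of a trained shape should land close to that
        # shape's label cluster in log space
        model, _, te, centers = trained
        for s in te:
            lam, tau = predict_params(model, s)
            c = centers[s.shape_label]
            assert abs(np.log10(lam) - c[0]) < 1.0
            assert abs(np.log10(tau) - c[1]) < 1.0

    def test_train_fit_better_than_test_fit(self, trained, small_dataset):
        model, tr, te, centers = trained
        def log_err(ds):
            errs = []
            for s in ds:
                lam, tau = predict_params(model, s)
                c = centers[s.shape_label]
                errs.append(abs(np.log10(lam) - c[0]) + abs(np.log10(tau) - c[1]))
            return np.median(errs)
        assert log_err(tr) <= log_err(te) + 1e-12

    def test_tau_clamped(self, small_dataset):
        tr, _, te = split_dataset(small_dataset, SplitSpec(seed=3))
        labels = np.tile([1e3, 0.9], (len(tr), 1))  # tau label beyond clamp
        model = train(tr, labels, CFG)
        _, tau = predict_params(model, te[0])
        assert tau <= 0.5

    def test_bad_labels_rejected(self, small_dataset):
        tr, _, _ = split_dataset(small_dataset, SplitSpec(seed=3))
        with pytest.raises(ValueError):
            train(tr, np.ones((len(tr), 3)), CFG)
        with pytest.raises(ValueError):
            train(tr, -np.ones((len(tr), 2)), CFG)

    def test_round_trip_persistence(self, trained, tmp_path):
        model, _, te, _ = trained
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = ParamPredictor.load(path)
        assert predict_params(loaded, te[0]) == predict_params(model, te[0])
        assert (tmp_path / "model.joblib.json").exists()

    def test_resamples_foreign_grid(self, trained):
        from airpls_opt.preprocess import resample_to_grid

        model, _, te, _ = trained
        s = te[0]
        dense = np.linspace(s.wavenumbers[0], s.wavenumbers[-1], 2 * s.n)
        s_dense = resample_to_grid(s, dense)
        lam_a, tau_a = predict_params(model, s)
        lam_b, tau_b = predict_params(model, s_dense)
        assert np.log10(lam_b) == pytest.approx(np.log10(lam_a), abs=0.3)
        assert np.log10(tau_b) == pytest.approx(np.log10(tau_a), abs=0.3)


class TestOutlierRule:
    def test_negative_improvement_is_outlier(self):
        assert is_outlier(-5.0, 1.0, 1.0)

    def test_large_excess_over_optimum_is_outlier(self):
        assert is_outlier(50.0, 11.0, 1.0)
        assert not is_outlier(50.0, 9.0, 1.0)

    def test_good_prediction_is_not(self):
        assert not is_outlier(95.0, 0.01, 0.009)


class TestEvaluateModel:
    def test_oracle_model_matches_grid_search(self, small_dataset):
        # a model trained on per-spectrum grid-search optima and
        # evaluated on its own training spectra: when it emits the true
        # per-spectrum optimum, PI_ML equals PI_OP
        from airpls_opt.optimize import GridSearchConfig, optimize_dataset

        sub = small_dataset.subset(range(0, 4))  # few spectra for speed
        cfg = GridSearchConfig(max_refinements=8, patience=3)
        results, records = optimize_dataset(sub, cfg)

        class Oracle:
            grid = sub.wavenumbers

            def predict_log(self, intensities):
                i = next(
                    j
                    for j, s in enumerate(sub)
                    if np.array_equal(s.intensities, np.atleast_2d(intensities)[0])
                )
                return np.array(
                    [[np.log10(results[i].lam_star), np.log10(results[i].tau_star)]]
                )

        frame, _ = evaluate_model(Oracle(), sub)
        for rec, opt in zip(frame.itertuples(), records):
            assert rec.pi_ml == pytest.approx(opt.pi, abs=1e-9)

    def test_oracle_sandwich(self, small_dataset):
        # MAE at any predicted parameters >= grid-searched optimum MAE
        # (up to grid resolution slack)
        from airpls_opt.optimize import GridSearchConfig, optimize_dataset

        sub = small_dataset.subset(range(10, 13))
        results, _ = optimize_dataset(sub, GridSearchConfig(max_refinements=10, patience=3))
        for s, res in zip(sub, results):
            fit = airpls_fit(s, AirPLSParams.optimized(res.lam_star * 2, res.tau_star))
            assert mae(fit.baseline, s.true_baseline) >= res.mae_star * 0.95

    def test_requires_true_baselines(self, trained):
        model, _, te, _ = trained
        s = te[0]
        import copy

        bare = copy.deepcopy(s)
        bare.true_baseline = None
        from airpls_opt.simulate import Dataset

        with pytest.raises(ValueError):
            evaluate_model(model, Dataset([bare]))
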