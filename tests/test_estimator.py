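"""Class weighting, patient-separated splits, median-of-folds ensemble."""

import numpy as np
import pandas as pd
import pytest

from icpflow.estimator import (
    IcpEnsembleRegressor,
    ModelConfig,
    compute_class_weights,
    make_patient_splits,
    predict_eicp,
    train_ensemble,
)
from icpflow.pipeline import process_cohort, split_feature_table
from icpflow.simulate import CohortConfig, simulate_cohort_recordings


class TestClassWeights:
    def test_inverse_frequency_ratio_from_population_counts(self):
        # a 10,982 / 622 low/high split gives a weight ratio of ~17.66
        y = np.concatenate([np.full(10_982, 10.0), np.full(622, 25.0)])
        w = compute_class_weights(y)
        ratio = w[y >= 20][0] / w[y < 20][0]
        assert ratio == pytest.approx(10_982 / 622, rel=1e-12)
        assert ratio == pytest.approx(17.66, abs=0.01)

    def test_balanced_classes_unit_weights(self):
        y = np.array([10.0, 30.0, 15.0, 25.0])
        assert np.allclose(compute_class_weights(y), 1.0)

    def test_mean_weight_is_one(self, rng):
        y = rng.uniform(0, 40, 501)
        assert np.mean(compute_class_weights(y)) == pytest.approx(1.0, rel=1e-12)

    def test_single_class_warns_uniform(self):
        with pytest.warns(UserWarning):
            w = compute_class_weights(np.full(10, 5.0))
        assert np.allclose(w, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(np.array([]))


class TestSplits:
    def test_eighty_twenty_patient_allocation(self):
        plan = make_patient_splits([f"p{i}" for i in range(10)], seed=0)
        assert len(plan) == 10
        for train, test in plan:
            assert len(train) == 8 and len(test) == 2

    def test_no_patient_on_both_sides(self):
        plan = make_patient_splits([f"p{i}" for i in range(13)], seed=3)
        for train, test in plan:
            assert not set(train) & set(test)

    def test_every_patient_tested_somewhere(self):
        plan = make_patient_splits([f"p{i}" for i in range(12)], seed=5)
        tested = set().union(*(set(te) for _, te in plan))
        assert tested == {f"p{i}" for i in range(12)}

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(9)]
        assert make_patient_splits(ids, seed=7) == make_patient_splits(ids, seed=7)

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_patient_splits(["a", "b", "c"], seed=0)

    def test_strict_group_kfold_partitions(self):
        plan = make_patient_splits([f"p{i}" for i in range(10)], n_splits=10,
                                   seed=0, strict_group_kfold=True)
        tested = [p for _, te in plan for p in te]
        assert sorted(tested) == [f"p{i}" for i in range(10)]


@pytest.fixture(scope="module")
def small_cohort_features():
    recs = simulate_cohort_recordings(8, CohortConfig(duration_s=300.0), seed=5)
    feats, _, _ = process_cohort(recs)
    return feats


@pytest.fixture(scope="module")
def fitted_bundle(small_cohort_features):
    X, y, groups = split_feature_table(small_cohort_features)
    cfg = ModelConfig(n_trees=200, min_samples_leaf=20, seed=1)
    return train_ensemble(X, y, groups, cfg), X, y, groups


class TestEnsemble:
    def test_ten_fold_models_with_default_layout(self, fitted_bundle):
        bundle, X, y, groups = fitted_bundle
        assert len(bundle.estimator.fold_models_) == 10
        assert len(bundle.estimator.fold_selections_) == 10

    def test_default_hyperparameters(self):
        cfg = ModelConfig()
        assert (cfg.n_trees, cfg.max_depth) == (4000, 15)
        assert cfg.l2_regularization == 0.5
        assert cfg.max_leaf_nodes == 50
        assert cfg.min_samples_leaf == 80
        assert cfg.learning_rate == 0.005
        assert cfg.n_histogram_bins == 255
        assert cfg.n_splits == 10 and cfg.train_fraction == 0.8

    def test_median_of_fold_predictions(self, fitted_bundle):
        bundle, X, y, groups = fitted_bundle
        est = bundle.estimator
        folds = est.predict_folds(X.head(20))
        eicp = est.predict(X.head(20))
        assert np.allclose(eicp, np.median(folds, axis=1))
        assert np.all(eicp >= folds.min(axis=1)) and np.all(eicp <= folds.max(axis=1))

    def test_median_handles_even_fold_count(self):
        folds = np.arange(1, 11, dtype=float)[None, :]
        assert np.median(folds, axis=1)[0] == 5.5

    def test_fold_permutation_invariance(self, fitted_bundle):
        bundle, X, y, groups = fitted_bundle
        est = bundle.estimator
        base = est.predict(X.head(30))
        order = np.random.default_rng(0).permutation(10)
        est.fold_models_ = [est.fold_models_[i] for i in order]
        est.fold_embeddings_ = [est.fold_embeddings_[i] for i in order]
        est.fold_selections_ = [est.fold_selections_[i] for i in order]
        assert np.allclose(est.predict(X.head(30)), base)

    def test_split_plan_has_no_leakage(self, fitted_bundle):
        bundle, X, y, groups = fitted_bundle
        for train, test in bundle.estimator.split_plan_:
            assert not set(train) & set(test)

    def test_signature_mismatch_rejected(self, fitted_bundle):
        bundle, X, y, groups = fitted_bundle
        with pytest.raises(ValueError):
            bundle.estimator.predict_folds(X.iloc[:5, :-3])

    def test_nonfinite_features_named(self, small_cohort_features):
        X, y, groups = split_feature_table(small_cohort_features)
        X = X.copy()
        X.loc[X.index[0], "p2p1"] = np.nan
        est = IcpEnsembleRegressor(n_trees=50)
        with pytest.raises(ValueError, match="p2p1"):
            est.fit(X, y, groups=groups)

    def test_bundle_roundtrip(self, fitted_bundle, tmp_path):
        from icpflow.estimator import ModelBundle

        bundle, X, y, groups = fitted_bundle
        path = tmp_path / "model.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        assert np.allclose(loaded.estimator.predict(X.head(10)),
                           bundle.estimator.predict(X.head(10)))
        assert path.with_suffix(".joblib.json").exists()

    def test_prediction_records_schema(self, fitted_bundle):
        bundle, X, y, groups = fitted_bundle
        preds = predict_eicp(bundle, X, reference_icp=y)
        assert {"eicp_mmHg", "reference_icp_mmHg", "fold_1", "fold_10"} <= set(preds.columns)
        folds = preds[[f"fold_{i}" for i in range(1, 11)]].to_numpy()
        assert np.allclose(preds["eicp_mmHg"], np.median(folds, axis=1))


class TestLearning:
    def test_noise_free_recovery(self):
        """With eps_sd = 0 and morphology carrying the signal, held-out
        predictions rank-correlate strongly with true ICP."""
        from icpflow.metrics import spearman_correlation
        from icpflow.simulate import IcpLawParams

        cohort = CohortConfig(
            duration_s=300.0,
            law=IcpLawParams(eps_sd=0.0),
            u_patient_sd=0.0,
            artifact_rate_per_min=0.0,
        )
        recs = simulate_cohort_recordings(12, cohort, seed=21)
        feats, _, _ = process_cohort(recs)
        X, y, groups = split_feature_table(feats)
        cfg = ModelConfig(n_trees=300, min_samples_leaf=20, seed=2)
        bundle = train_ensemble(X, y, groups, cfg)
        est = bundle.estimator
        folds = est.predict_folds(X)
        held_y, held_pred = [], []
        for i, (_, test_ids) in enumerate(est.split_plan_):
            mask = np.isin(groups, test_ids)
            held_y.append(y[mask])
            held_pred.append(folds[mask, i])
        rho, _ = spearman_correlation(np.concatenate(held_y), np.concatenate(held_pred))
        assert rho >= 0.9

    def test_class_weighting_helps_high_icp_windows(self):
        """Up-weighting the rare >= 20 mmHg class reduces MAE on that class
        relative to unweighted training (directional, stochastic)."""
        recs = simulate_cohort_recordings(12, CohortConfig(duration_s=300.0), seed=33)
        feats, _, _ = process_cohort(recs)
        X, y, groups = split_feature_table(feats)
        if (y >= 20).sum() < 10:
            pytest.skip("too few high-ICP windows in this draw")
        maes = {}
        for weighted in (True, False):
            est = IcpEnsembleRegressor(
                n_trees=200, min_samples_leaf=20, random_state=3,
                class_weighting=weighted,
            )
            est.fit(X, y, groups=groups)
            folds = est.predict_folds(X)
            errs = []
            for i, (_, test_ids) in enumerate(est.split_plan_):
                mask = np.isin(groups, test_ids) & (y >= 20)
                if mask.sum():
                    errs.append(np.mean(np.abs(folds[mask, i] - y[mask])))
            maes[weighted] = np.mean(errs)
        assert maes[True] < maes[False]

    def test_grid_search_picks_from_grid(self, small_cohort_features):
        X, y, groups = split_feature_table(small_cohort_features)
        cfg = ModelConfig(n_trees=100, min_samples_leaf=20, seed=4,
                          grid_n_trees=(50, 100), grid_max_depth=(3, 6),
                          n_splits=3)
        bundle = train_ensemble(X, y, groups, cfg, do_grid_search=True)
        est = bundle.estimator
        assert est.best_params_ in {(a, b) for a in (50, 100) for b in (3, 6)}
        assert len(est.grid_results_) == 4
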