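"""Prediction harness: splits, folds, leakage-safe preprocessing, models,
metrics, bootstrap inference, Shapley attributions, subgroups."""

import numpy as np
import pandas as pd
import pytest

from speechcog import metrics as mx
from speechcog.evaluation import (FoldPreprocessor, ModelConfig,
                                  cross_validate_predictions, fit_predict,
                                  make_cv_folds, make_holdout_split,
                                  preprocess_fold_features, subgroup_metrics)
from speechcog.shapley import mean_abs_importance, shapley_attributions


def _demo(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.normal(65, 5, n),
        "gender": rng.choice(["female", "male"], n),
        "education": rng.choice(["high", "low"], n),
        "country": rng.choice(["UK", "USA"], n),
    }, index=[f"P{i:04d}" for i in range(n)])


class TestHoldoutSplit:
    def test_exact_788_197_sizes(self):
        demo = _demo(985, seed=1)
        comp = pd.Series(np.random.default_rng(2).normal(0, 1, 985),
                         index=demo.index)
        plan = make_holdout_split(demo, comp, frac=0.8, seed=0)
        assert len(plan.dev_ids) == 788
        assert len(plan.holdout_ids) == 197
        assert not set(plan.dev_ids) & set(plan.holdout_ids)

    def test_missing_stratification_rows_excluded(self):
        demo = _demo(100, seed=3)
        demo.loc[demo.index[:4], "age"] = np.nan
        plan = make_holdout_split(demo, seed=0)
        assert len(plan.excluded_ids) == 4
        assert len(plan.dev_ids) + len(plan.holdout_ids) == 96

    def test_per_stratum_fraction_audit(self):
        demo = _demo(985, seed=4)
        comp = pd.Series(np.random.default_rng(5).normal(0, 1, 985),
                         index=demo.index)
        for seed in range(3):
            plan = make_holdout_split(demo, comp, frac=0.8, seed=seed)
            dev = set(plan.dev_ids)
            strata = pd.Series(plan.strata)
            for label, ids in strata.groupby(strata).groups.items():
                n_s = len(ids)
                d_s = sum(i in dev for i in ids)
                # integer apportionment: within one participant of 0.8 n_s
                assert abs(d_s - 0.8 * n_s) <= 1.0, label

    def test_deterministic_given_seed(self):
        demo = _demo(300, seed=6)
        a = make_holdout_split(demo, seed=9)
        b = make_holdout_split(demo, seed=9)
        assert a.dev_ids == b.dev_ids and a.holdout_ids == b.holdout_ids


class TestCvFolds:
    def test_fold_sizes_for_788(self):
        demo = _demo(788, seed=7)
        plan = make_holdout_split(demo, frac=1.0, seed=0)
        folds = make_cv_folds(plan.dev_ids, plan.strata, k=10, seed=0)
        sizes = pd.Series(folds).value_counts()
        assert set(sizes) <= {78, 79}
        assert sizes.sum() == 788

    def test_union_and_disjointness(self):
        demo = _demo(97, seed=8)
        plan = make_holdout_split(demo, frac=1.0, seed=0)
        folds = make_cv_folds(plan.dev_ids, plan.strata, k=5, seed=1)
        assert set(folds) == set(plan.dev_ids)

    def test_deterministic(self):
        demo = _demo(50, seed=9)
        plan = make_holdout_split(demo, frac=1.0, seed=0)
        a = make_cv_folds(plan.dev_ids, plan.strata, k=5, seed=2)
        b = make_cv_folds(plan.dev_ids, plan.strata, k=5, seed=2)
        assert a == b

    def test_more_folds_than_ids_rejected(self):
        with pytest.raises(ValueError):
            make_cv_folds(["a", "b"], {"a": "s", "b": "s"}, k=3)


class TestFoldPreprocessing:
    def _frames(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        train = pd.DataFrame({"x": rng.normal(10, 2, n),
                              "y": rng.normal(0, 1, n)})
        apply_to = pd.DataFrame({"x": rng.normal(10, 2, 30),
                                 "y": rng.normal(0, 1, 30)})
        return train, apply_to

    def test_train_statistics_standardize_apply_rows(self):
        train = pd.DataFrame({"x": [8.0, 10.0, 12.0] * 10})
        apply_to = pd.DataFrame({"x": [14.0]})
        tr_t, ap_t, _ = preprocess_fold_features(train, apply_to)
        sd = train["x"].std(ddof=0)
        assert ap_t["x"].iloc[0] == pytest.approx((14 - 10) / sd)

    def test_transformed_train_is_standardized(self):
        train, apply_to = self._frames()
        tr_t, _, _ = preprocess_fold_features(train, apply_to)
        assert np.allclose(tr_t.mean(), 0, atol=1e-10)
        assert np.allclose(tr_t.std(ddof=0), 1, atol=1e-10)

    def test_apply_rows_never_influence_transform(self):
        train, apply_to = self._frames(seed=1)
        _, _, p1 = preprocess_fold_features(train, apply_to)
        shuffled = apply_to.sample(frac=1.0, random_state=3) * 100.0
        _, _, p2 = preprocess_fold_features(train, shuffled)
        assert np.allclose(p1.out_mean_, p2.out_mean_)
        assert np.allclose(p1.raw_mean_, p2.raw_mean_)
        t1 = p1.transform(train)
        t2 = p2.transform(train)
        assert np.allclose(t1, t2, atol=0)

    def test_constant_feature_dropped_with_warning(self):
        train, apply_to = self._frames(seed=2)
        train["c"] = 1.0
        apply_to["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            tr_t, ap_t, _ = preprocess_fold_features(train, apply_to)
        assert "c" not in tr_t.columns

    def test_extreme_train_cells_are_masked_and_imputed(self):
        rng = np.random.default_rng(4)
        train = pd.DataFrame({"x": rng.normal(0, 1, 200),
                              "y": rng.normal(0, 1, 200)})
        train.loc[0, "x"] = 50.0
        tr_t, _, _ = preprocess_fold_features(train,
                                              train.iloc[:5], z_cap=4.0)
        # the 50-sigma cell must not survive as an extreme standardized value
        assert abs(tr_t["x"].iloc[0]) < 5.0


class TestModels:
    def test_dummy_mean(self):
        cfg = ModelConfig(kind="dummy_mean")
        pred, _ = fit_predict(cfg, pd.DataFrame({"x": [0, 0, 0]}),
                              [1.0, 2.0, 3.0], pd.DataFrame({"x": [0, 0]}))
        assert np.allclose(pred, 2.0)

    def test_dummy_random_support(self):
        cfg = ModelConfig(kind="dummy_random", seed=5)
        y = [1.0, 4.0, 9.0]
        pred, _ = fit_predict(cfg, pd.DataFrame({"x": np.zeros(3)}), y,
                              pd.DataFrame({"x": np.zeros(50)}))
        assert set(pred) <= set(y)

    def test_svr_learns_noiseless_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-2, 2, 200)
        X = pd.DataFrame({"x": x})
        Xte = pd.DataFrame({"x": rng.uniform(-2, 2, 100)})
        cfg = ModelConfig(kind="svr", C=10.0, epsilon=0.01)
        pred, _ = fit_predict(cfg, X, x, Xte)
        assert mx.r_squared(Xte["x"], pred) > 0.95

    def test_nan_features_rejected(self):
        cfg = ModelConfig(kind="svr")
        X = pd.DataFrame({"x": [1.0, np.nan]})
        with pytest.raises(ValueError):
            fit_predict(cfg, X, [1, 2], X)


class TestMetrics:
    def test_identity_predictions(self):
        ms = mx.evaluate_predictions([1, 2, 3, 4], [1, 2, 3, 4])
        assert ms.r_squared == 1.0
        assert ms.spearman_rho == 1.0
        assert ms.mae == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        ms = mx.evaluate_predictions(c, np.full(4, c.mean()))
        assert ms.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        ms = mx.evaluate_predictions([1, 2, 3, 4], [2, 2, 3, 3])
        assert ms.r_squared == pytest.approx(0.6)
        assert ms.mae == pytest.approx(0.5)

    def test_constant_truth_flagged(self):
        ms = mx.evaluate_predictions([1, 1, 1], [1, 2, 3])
        assert not ms.valid


class TestBootstrap:
    def test_perfect_predictions_ci_is_degenerate(self):
        c = np.arange(20.0)
        lo, hi, lvl = mx.bootstrap_metric_ci(c, c, mx.r_squared, seed=0)
        assert lo == hi == 1.0

    def test_same_seed_same_ci(self):
        rng = np.random.default_rng(1)
        c = rng.normal(0, 1, 50)
        p = c + rng.normal(0, 0.5, 50)
        a = mx.bootstrap_metric_ci(c, p, mx.r_squared, seed=7)
        b = mx.bootstrap_metric_ci(c, p, mx.r_squared, seed=7)
        assert a == b

    def test_superiority_identical_models_not_significant(self):
        rng = np.random.default_rng(2)
        c = rng.normal(0, 1, 200)
        p = c + rng.normal(0, 0.7, 200)
        frac, sig = mx.bootstrap_superiority_test(c, p, p.copy(), seed=0)
        assert not sig

    def test_superiority_detects_planted_improvement(self):
        rng = np.random.default_rng(3)
        c = rng.normal(0, 1, 500)
        good = c * 0.7 + rng.normal(0, 0.5, 500)   # R^2 ~ 0.5
        bad = np.full(500, c.mean())               # R^2 ~ 0
        frac, sig = mx.bootstrap_superiority_test(c, good, bad, seed=1)
        assert sig

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            mx.bootstrap_superiority_test([1, 2, 3], [1, 2], [1, 2, 3])


class TestShapley:
    def test_local_accuracy_exact_mode(self):
        from sklearn.svm import SVR
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 5))
        y = X[:, 0] * 2 - X[:, 2] + rng.normal(0, 0.1, 60)
        model = SVR().fit(X, y)
        phi, base = shapley_attributions(model, X[:20], X[:8])
        preds = model.predict(X[:8])
        assert np.allclose(base + phi.sum(axis=1), preds, atol=1e-6)

    def test_linear_model_closed_form(self):
        class Lin:
            def predict(self, X):
                return 2.0 * np.asarray(X)[:, 0]

        rng = np.random.default_rng(1)
        bg = rng.normal(0, 1, (200, 3))
        bg -= bg.mean(axis=0)  # zero-mean background
        X = np.array([[1.5, 0.3, -0.7], [-0.5, 1.0, 0.2]])
        phi, base = shapley_attributions(Lin(), bg, X)
        assert np.allclose(phi[:, 0], 2.0 * X[:, 0], atol=1e-10)
        assert np.allclose(base, 0.0, atol=1e-10)

    def test_unused_feature_gets_zero_attribution(self):
        class Lin:
            def predict(self, X):
                return np.asarray(X)[:, 0] ** 2

        rng = np.random.default_rng(2)
        bg = rng.normal(0, 1, (50, 4))
        X = rng.normal(0, 1, (5, 4))
        phi, _ = shapley_attributions(Lin(), bg, X)
        assert np.allclose(phi[:, 1:], 0.0, atol=1e-10)
        imp = mean_abs_importance(phi)
        assert imp[0] > 0 and np.allclose(imp[1:], 0.0)


class TestSubgroups:
    def test_single_group_equals_overall(self):
        rng = np.random.default_rng(0)
        idx = [f"P{i}" for i in range(40)]
        c = pd.Series(rng.normal(0, 1, 40), index=idx)
        p = c + rng.normal(0, 0.5, 40)
        groups = pd.Series("all", index=idx)
        out = subgroup_metrics(c, p, groups)
        overall = mx.evaluate_predictions(c, p)
        assert out["all"].r_squared == pytest.approx(overall.r_squared)

    def test_group_sizes_sum_to_total(self):
        rng = np.random.default_rng(1)
        idx = [f"P{i}" for i in range(60)]
        c = pd.Series(rng.normal(0, 1, 60), index=idx)
        p = c + rng.normal(0, 0.5, 60)
        groups = pd.Series(rng.choice(["a", "b"], 60), index=idx)
        out = subgroup_metrics(c, p, groups)
        assert sum(m.n for m in out.values()) == 60

    def test_balanced_quality_gives_similar_group_r2(self):
        rng = np.random.default_rng(2)
        idx = [f"P{i}" for i in range(4000)]
        c = pd.Series(rng.normal(0, 1, 4000), index=idx)
        p = c * 0.6 + rng.normal(0, 0.8, 4000)
        groups = pd.Series(rng.choice(["a", "b"], 4000), index=idx)
        out = subgroup_metrics(c, p, groups)
        assert abs(out["a"].r_squared - out["b"].r_squared) < 0.07


class TestCrossValidation:
    def test_pooled_predictions_cover_dev_once(self):
        rng = np.random.default_rng(0)
        n = 60
        idx = [f"P{i:03d}" for i in range(n)]
        X = pd.DataFrame({"x": rng.normal(0, 1, n)}, index=idx)
        y = pd.Series(X["x"] * 0.5 + rng.normal(0, 0.5, n), index=idx)
        folds = {pid: i % 5 for i, pid in enumerate(idx)}
        cfg = ModelConfig(kind="svr", folds=5)
        out = cross_validate_predictions(X, y, folds, cfg)
        assert sorted(out.index) == sorted(idx)
        assert out.index.is_unique
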