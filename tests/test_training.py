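import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopycalib import (
    ModelConfig,
    compare_general_specific,
    evaluate_metrics,
    split_train_test,
    train_model,
)
from canopycalib.training import default_grid


def _frame(seed, n=100, strata=4):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "experiment": np.repeat([f"E{i}" for i in range(strata)], n // strata),
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "x3": rng.normal(size=n),
    })
    df["y"] = 100 + 30 * df["x1"] - 20 * df["x2"] + rng.normal(0, 5, n)
    return df


class TestSplit:
    def test_partition_and_stratum_fractions(self):
        df = _frame(0)
        train, test = split_train_test(df, 0.8, strata="experiment", seed=1)
        assert len(train) + len(test) == len(df)
        assert set(train.index).isdisjoint(test.index)
        per = train.groupby("experiment").size()
        assert ((per - 20).abs() <= 1).all()

    def test_deterministic(self):
        df = _frame(1)
        a = split_train_test(df, seed=3)[0]
        b = split_train_test(df, seed=3)[0]
        assert a.index.equals(b.index)

    def test_singleton_stratum_rejected(self):
        df = _frame(0).iloc[:26]  # last stratum has 1 row
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(df, strata="experiment", seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        m = evaluate_metrics(obs, obs)
        assert (m["r2"], m["rmse"], m["rrmse"]) == (1.0, 0.0, 0.0)

    def test_null_model_r2_zero(self):
        obs = np.array([100.0, 200.0, 300.0])
        m = evaluate_metrics(obs, np.full(3, 200.0))
        assert m["r2"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        m = evaluate_metrics([100.0, 200.0, 300.0], [110.0, 190.0, 310.0])
        assert m["rmse"] == pytest.approx(10.0)
        assert m["rrmse"] == pytest.approx(0.05)

    def test_as_printed_forms(self):
        obs = np.array([100.0, 200.0, 300.0])
        pred = np.array([110.0, 190.0, 310.0])
        printed = evaluate_metrics(obs, pred, as_printed=True)
        standard = evaluate_metrics(obs, pred)
        assert printed["r2"] == pytest.approx(1 - standard["r2"])
        assert printed["rmse"] == pytest.approx(standard["rmse"] * np.sqrt(3))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_identity_r2_vs_rmse(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(100, 20, 30)
        pred = obs + rng.normal(0, 10, 30)
        m = evaluate_metrics(obs, pred)
        sst = np.sum((obs - obs.mean()) ** 2)
        assert m["r2"] == pytest.approx(1 - m["rmse"] ** 2 * len(obs) / sst)

    def test_zero_mean_obs_rejected(self):
        with pytest.raises(ValueError, match="rRMSE"):
            evaluate_metrics([-1.0, 1.0], [0.0, 0.0])


class TestGrids:
    def test_grids_within_tuning_ranges(self):
        for g in default_grid("svm_poly", 5):
            assert g["degree"] in (1, 2)
            assert 100 <= g["C"] <= 1000
            assert 1e-4 <= g["gamma"] <= 1e-2
        for g in default_grid("xgboost", 5):
            assert 20 <= g["n_estimators"] <= 40
            assert 9 <= g["max_depth"] <= 10
            assert 0.1 <= g["learning_rate"] <= 0.3
            assert 0.7 <= g["gamma"] <= 0.9
            assert 0.7 <= g["colsample_bytree"] <= 1.0
        assert default_grid("plsr", 4) == [{"n_components": k} for k in (1, 2, 3, 4)]
        assert [g["max_features"] for g in default_grid("rf", 5)] == [1, 2, 3, 4, 5]

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            default_grid("deep_net", 3)


class TestTrainModel:
    def test_noiseless_linear_recovered_by_plsr(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        y = 50 + 10 * X["a"] - 5 * X["b"] + 2 * X["c"]
        cfg = ModelConfig(learner="plsr", cv_folds=5, cv_repeats=2, seed=0)
        fit = train_model(X, y, cfg)
        assert fit.cv_metrics["r2"] > 0.999
        assert fit.best_params["n_components"] == 3

    def test_deterministic_given_seed(self):
        df = _frame(3)
        cfg = ModelConfig(learner="rf", cv_folds=4, cv_repeats=2, seed=5, rf_trees=30)
        a = train_model(df[["x1", "x2", "x3"]], df["y"], cfg)
        b = train_model(df[["x1", "x2", "x3"]], df["y"], cfg)
        assert a.best_params == b.best_params
        assert a.cv_metrics == b.cv_metrics

    def test_fold_repeat_bookkeeping(self):
        df = _frame(4)
        cfg = ModelConfig(learner="plsr", cv_folds=10, cv_repeats=10, seed=1)
        fit = train_model(df[["x1", "x2", "x3"]], df["y"], cfg)
        assert len(fit.fold_metrics) == 100

    def test_pure_noise_response_gives_no_skill(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(200, 5)),
                             columns=[f"x{i}" for i in range(5)])
            y = rng.normal(100, 10, 200)
            cfg = ModelConfig(learner="plsr", cv_folds=5, cv_repeats=2, seed=seed)
            fit = train_model(X, y, cfg)
            assert fit.cv_metrics["r2"] <= 0.1

    def test_degenerate_response_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)),
                         columns=["a", "b"])
        with pytest.raises(ValueError, match="degenerate"):
            train_model(X, np.ones(20), ModelConfig(learner="plsr", cv_folds=2,
                                                    cv_repeats=1))

    def test_test_set_evaluation(self):
        df = _frame(5)
        train, test = split_train_test(df, seed=1)
        cfg = ModelConfig(learner="plsr", cv_folds=5, cv_repeats=1, seed=1)
        fit = train_model(train[["x1", "x2", "x3"]], train["y"], cfg,
                          X_test=test[["x1", "x2", "x3"]], y_test=test["y"])
        assert fit.test_metrics["r2"] > 0.9
        assert len(fit.test_predictions) == len(test)


def test_selection_leakage_inflates_cv_but_not_test():
    """Choosing features on pooled data (using the response) must look
    better in CV than honest within-fold behaviour, and the advantage must
    vanish on held-out data — the leakage detector."""
    rng = np.random.default_rng(8)
    n, p = 60, 200
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    y = pd.Series(rng.normal(0, 1, n))  # pure noise: any skill is leakage
    X_new = pd.DataFrame(rng.normal(size=(n, p)), columns=X.columns)
    y_new = rng.normal(0, 1, n)

    corr = X.apply(lambda c: abs(np.corrcoef(c, y)[0, 1]))
    leaky_cols = list(corr.sort_values(ascending=False).index[:5])
    honest_cols = list(X.columns[:5])

    cfg = ModelConfig(learner="plsr", cv_folds=5, cv_repeats=2, seed=0)
    leaky = train_model(X[leaky_cols], y, cfg, X_test=X_new[leaky_cols], y_test=y_new)
    honest = train_model(X[honest_cols], y, cfg, X_test=X_new[honest_cols], y_test=y_new)
    assert leaky.cv_metrics["rmse"] < honest.cv_metrics["rmse"] * 0.9
    assert leaky.test_metrics["r2"] < 0.2  # no real generalization


class TestGeneralSpecific:
    def test_bookkeeping_one_row_per_level(self):
        df = _frame(6, n=120, strata=3)
        cfg = ModelConfig(learner="plsr", cv_folds=4, cv_repeats=1, seed=0)
        table = compare_general_specific(df, ["x1", "x2", "x3"], "y",
                                         axis="experiment", config=cfg, seed=1)
        assert len(table) == 3
        assert {"rmse_general", "rmse_specific", "rmse_diff"} <= set(table.columns)

    def test_shifted_level_favours_specific_model(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = _frame(seed, n=160, strata=4)
            # one level gets a different trait -> biomass mapping
            shifted = df["experiment"] == "E0"
            df.loc[shifted, "y"] = (100 - 30 * df.loc[shifted, "x1"]
                                    + rng.normal(0, 5, int(shifted.sum())))
            cfg = ModelConfig(learner="plsr", cv_folds=4, cv_repeats=1, seed=seed)
            table = compare_general_specific(df, ["x1", "x2", "x3"], "y",
                                             axis="experiment", config=cfg, seed=seed)
            row = table[table["experiment"] == "E0"].iloc[0]
            wins += row["rmse_specific"] < row["rmse_general"]
        assert wins >= 9

    def test_exchangeable_levels_similar_accuracy(self):
        df = _frame(7, n=200, strata=4)
        cfg = ModelConfig(learner="plsr", cv_folds=4, cv_repeats=1, seed=0)
        table = compare_general_specific(df, ["x1", "x2", "x3"], "y",
                                         axis="experiment", config=cfg, seed=2)
        rel = (table["rmse_diff"].abs() / table["rmse_general"]).median()
        assert rel < 0.5
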