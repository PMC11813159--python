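import numpy as np
import pandas as pd
import pytest

from fruitspec.models import (
    MODEL_FAMILIES,
    ModelSpec,
    SRIRegressor,
    default_grid,
    evaluate,
    grid_search_fit,
    results_frame,
    run_trait_models,
    select_inputs,
    split_data,
)

SMALL_GRIDS = {
    "ann": {"hidden_layer_sizes": [(4,), (4, 4)], "activation": ["relu", "identity"],
            "max_iter": [500]},
    "rf": {"n_estimators": [5, 10], "max_depth": [2, 4],
           "criterion": ["squared_error"]},
    "dt": {"max_depth": [1, 2, 3, 4], "criterion": ["squared_error"]},
}


class TestSplit:
    def test_stated_rounding_rule_75_samples(self):
        X, y = np.zeros((75, 2)), np.zeros(75)
        Xtr, Xte, *_ = split_data(X, y, 0.7, seed=0)
        assert Xtr.shape[0] == 52 and Xte.shape[0] == 23

    def test_same_seed_identical_partition(self):
        X = np.arange(40, dtype=float).reshape(20, 2)
        y = np.arange(20, dtype=float)
        a = split_data(X, y, 0.7, seed=5)
        b = split_data(X, y, 0.7, seed=5)
        assert np.array_equal(a[4], b[4]) and np.array_equal(a[5], b[5])

    def test_partition_disjoint_and_exhaustive(self):
        X, y = np.zeros((45, 1)), np.zeros(45)
        *_, itr, ite = split_data(X, y, 0.7, seed=0)
        assert set(itr) | set(ite) == set(range(45))
        assert set(itr) & set(ite) == set()

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            split_data(np.zeros((20, 1)), np.zeros(20), frac, seed=0)


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.mse, m.mae, m.r2) == (0.0, 0.0, 1.0)

    def test_mean_predictor_gives_zero_r2(self):
        m = evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.mse == pytest.approx(2 / 3)
        assert m.mae == pytest.approx(2 / 3)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_case(self):
        # SS_res = 1, SS_tot = 2 about the actual mean: R2 = 1 - 1/2
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.mse == pytest.approx(1 / 3)
        assert m.mae == pytest.approx(1 / 3)
        assert m.r2 == pytest.approx(0.5)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        ya, yp = rng.normal(size=50), rng.normal(size=50)
        m = evaluate(ya, yp)
        mse = sum((a - p) ** 2 for a, p in zip(ya, yp)) / 50
        mae = sum(abs(a - p) for a, p in zip(ya, yp)) / 50
        ss_res = sum((a - p) ** 2 for a, p in zip(ya, yp))
        ss_tot = sum((a - ya.mean()) ** 2 for a in ya)
        assert m.mse == pytest.approx(mse, abs=1e-12)
        assert m.mae == pytest.approx(mae, abs=1e-12)
        assert m.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_zero_variance_actual_r2_missing(self):
        m = evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(m.r2) and m.mse > 0


class TestSelectInputs:
    def test_threshold_zero_retains_all(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        y = rng.normal(size=30)
        names, sub = select_inputs(df, y, threshold=0.0)
        assert set(names) == set("abcde")
        assert sub.shape == (30, 5)

    def test_collinear_feature_alone_survives_high_threshold(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        df = pd.DataFrame({"noise1": rng.normal(size=30),
                           "perfect": 2 * y + 1,
                           "noise2": rng.normal(size=30)})
        names, _ = select_inputs(df, y, threshold=0.99)
        assert names == ["perfect"]

    def test_ordering_descending_r2(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        df = pd.DataFrame({
            "weak": y + rng.normal(0, 2, 200),
            "strong": y + rng.normal(0, 0.1, 200),
            "mid": y + rng.normal(0, 0.7, 200),
        })
        names, _ = select_inputs(df, y, threshold=0.0)
        assert names[0] == "strong" and names[-1] == "weak"

    def test_nothing_retained_raises_helpfully(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="lower the threshold"):
            select_inputs(df, y, threshold=0.999)


class TestGridSearch:
    def test_single_point_grid_chosen(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        spec = ModelSpec("dt", {"max_depth": [3], "criterion": ["squared_error"]})
        reg = grid_search_fit(spec, X, y, folds=5, seed=0)
        assert reg.best_params_ == {"max_depth": 3, "criterion": "squared_error"}

    def test_dt_depth_resolves_plateau_target(self):
        """A noiseless 3-plateau step function needs depth >= 2; CV MSE at the
        chosen depth must not exceed that of shallower depths."""
        x = np.linspace(0, 1, 60)
        y = np.where(x < 1 / 3, 0.0, np.where(x < 2 / 3, 1.0, 2.0))
        X = x[:, None]
        spec = ModelSpec("dt", {"max_depth": [1, 2, 3, 4], "criterion": ["squared_error"]})
        reg = grid_search_fit(spec, X, y, folds=5, seed=0)
        assert reg.best_params_["max_depth"] >= 2
        cv = pd.DataFrame(reg.search_.cv_results_)
        chosen = -cv.loc[cv["rank_test_score"] == 1, "mean_test_score"].iloc[0]
        shallower = cv[cv["param_max_depth"] < reg.best_params_["max_depth"]]
        assert np.all(chosen <= -shallower["mean_test_score"] + 1e-12)

    def test_determinism_same_seed_same_choice(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.3, 40)
        spec = ModelSpec("rf", SMALL_GRIDS["rf"])
        p1 = grid_search_fit(spec, X, y, seed=7).best_params_
        p2 = grid_search_fit(spec, X, y, seed=7).best_params_
        assert p1 == p2

    def test_chosen_hyperparameters_within_grid(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + rng.normal(0, 0.2, 40)
        for fam in MODEL_FAMILIES:
            spec = ModelSpec(fam, SMALL_GRIDS[fam])
            reg = grid_search_fit(spec, X, y, seed=0)
            for key, val in reg.best_params_.items():
                assert val in spec.hyper_grid[key], (fam, key)

    def test_default_grids_match_protocol(self):
        ann = default_grid("ann")
        assert set(ann["activation"]) == {"tanh", "logistic", "relu", "identity"}
        assert ann["max_iter"] == [500, 600, 700, 800, 900, 1000]
        sizes = ann["hidden_layer_sizes"]
        assert all(len(s) in (1, 2, 3) and set(s) <= set(range(2, 11)) for s in sizes)
        assert len(sizes) == 27
        rf = default_grid("rf")
        assert rf["n_estimators"] == list(range(1, 21))
        assert rf["max_depth"] == list(range(1, 11))
        assert set(rf["criterion"]) == {"squared_error", "absolute_error"}
        assert default_grid("dt")["max_depth"] == list(range(1, 11))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        reg = SRIRegressor(family="dt", param_grid=SMALL_GRIDS["dt"], random_state=3)
        cl = clone(reg)
        assert cl.get_params()["family"] == "dt"
        assert cl.get_params()["random_state"] == 3


class TestRunTraitModels:
    def test_report_schema_and_recovery(self, mango_dataset):
        results = run_trait_models(
            mango_dataset.spectra, mango_dataset.traits, "SPAD",
            families=("rf", "dt"), threshold=0.3, seed=0, grids=SMALL_GRIDS,
        )
        report = results_frame(results)
        assert list(report["model"]) == ["RF", "DT"]
        assert {"train_R2", "train_MSE", "train_MAE",
                "test_R2", "test_MSE", "test_MAE"} <= set(report.columns)
        assert (report["test_MSE"] >= 0).all() and (report["test_MAE"] >= 0).all()
        assert (report["train_R2"] <= 1).all()
        # SPAD has a strong designed red-region driver: both trees recover it
        assert (report["test_R2"] > 0.8).all()

    def test_unknown_family_rejected(self, mango_dataset):
        with pytest.raises(ValueError, match="unknown model family"):
            run_trait_models(mango_dataset.spectra, mango_dataset.traits, "SPAD",
                             families=("svm",))

    def test_ann_family_runs_with_scaling(self, mango_dataset):
        results = run_trait_models(
            mango_dataset.spectra, mango_dataset.traits, "SPAD",
            families=("ann",), threshold=0.3, seed=0,
            grids={"ann": {"hidden_layer_sizes": [(5,)], "activation": ["identity"],
                           "max_iter": [500]}},
        )
        assert results[0].family == "ann"
        assert results[0].test.r2 > 0.5

    def test_selection_on_all_uses_every_sample(self, mango_dataset):
        r_train = run_trait_models(mango_dataset.spectra, mango_dataset.traits, "TSS",
                                   families=("dt",), threshold=0.5, seed=0,
                                   grids=SMALL_GRIDS, selection_on="train")
        r_all = run_trait_models(mango_dataset.spectra, mango_dataset.traits, "TSS",
                                 families=("dt",), threshold=0.5, seed=0,
                                 grids=SMALL_GRIDS, selection_on="all")
        assert isinstance(r_train[0].input_names, list)
        assert isinstance(r_all[0].input_names, list)
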