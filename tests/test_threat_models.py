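import numpy as np
import pandas as pd
import pytest

from archorisk import threat_models as tm
from archorisk.simulate import (StatusGenConfig, simulate_ranges,
                                simulate_species_table)
from archorisk.trees import to_arrays

from conftest import tree_with_tips


@pytest.fixture(scope="module")
def synth():
    """Moderate synthetic dataset shared by the model-fitting tests."""
    tree, arr, _ = tree_with_tips(170, 240, 31, lam=0.09, crown_age=60.0)
    occ, cent, areas = simulate_ranges(arr.n_tips, grid_dims=(30, 50),
                                       mean_cells=30, seed=7)
    tab = simulate_species_table(tree, cent, areas, StatusGenConfig(), seed=8)
    return tree, arr, tab


class TestStatusCodes:
    def test_round_trip(self):
        assert tm.status_to_code("LC") == 1 and tm.status_to_code("EX") == 6
        assert np.isnan(tm.status_to_code("DD"))
        assert np.isnan(tm.status_to_code("UA"))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            tm.status_to_code("XYZ")

    @pytest.mark.parametrize("value,expect", [
        (3.0, "VU"), (3.49, "VU"), (3.5, "EN"),  # half-up toward threat
        (0.2, "LC"), (9.0, "EX"),
    ])
    def test_rounding_half_up(self, value, expect):
        assert tm.code_to_status(value) == expect


class TestEncoding:
    def test_one_hot_blocks_sum_to_one(self, synth):
        _, _, tab = synth
        X, enc = tm.encode_predictors(tab, scheme="pglm")
        for col in tm.CATEGORICAL:
            block = [c for c in X.columns if c.startswith(col + "=")]
            np.testing.assert_allclose(X[block].sum(axis=1), 1.0)

    def test_z_scheme_moments(self, synth):
        _, _, tab = synth
        X, _ = tm.encode_predictors(tab, scheme="pglm")
        for col in tm.CONTINUOUS:
            assert X[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert X[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_minmax_column_example(self, synth):
        _, _, tab = synth
        raw = tab.copy()
        raw.loc[raw.index[:3], "hei"] = [2.0, 4.0, 6.0]
        sub = raw.iloc[:3]
        X, _ = tm.encode_predictors(sub, scheme="minmax")
        np.testing.assert_allclose(X["hei"], [0.0, 0.5, 1.0])
        assert X.to_numpy().min() >= 0 and X.to_numpy().max() <= 1

    def test_non_positive_log_rejected(self, synth):
        _, _, tab = synth
        bad = tab.copy()
        bad.loc[bad.index[0], "range_area"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            tm.encode_predictors(bad, scheme="pglm")

    def test_unseen_level_at_predict_rejected(self, synth):
        _, _, tab = synth
        X, enc = tm.encode_predictors(tab, scheme="pglm")
        new = tab.iloc[:2].copy()
        new.loc[new.index[0], "microhabitat"] = "lunar"
        with pytest.raises(ValueError, match="unseen"):
            enc.transform(new)

    def test_design_has_32_predictors(self, synth):
        tree, _, tab = synth
        X, _ = tm.build_design(tab, tree)
        assert X.shape[1] == 32


class TestPCoA:
    def test_collinear_points_recover_line(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        ax = tm.pcoa_axes(D, k=2)
        order = np.argsort(ax[:, 0])
        assert list(order) in ([0, 1, 2], [2, 1, 0])
        assert np.allclose(ax[:, 1], 0.0, atol=1e-8)

    def test_planar_distances_self_consistent(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, (12, 2))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        ax = tm.pcoa_axes(D, k=2)
        D2 = squareform(pdist(ax))
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_identical_points_zero_coords(self):
        D = np.zeros((5, 5))
        assert np.allclose(tm.pcoa_axes(D, k=2), 0.0)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            tm.pcoa_axes(D)


class TestPGLM:
    def test_ols_reduction_exact_recovery(self, synth):
        tree, _, tab = synth
        X, _ = tm.build_design(tab, tree)
        n = len(X)
        y = pd.Series(2.0 - 1.3 * X["range_area"].to_numpy(), index=X.index)
        eye = np.eye(n)
        res = tm.fit_pglm(X, y, eye, eye, n_select=15)
        assert res.coef["range_area"] == pytest.approx(-1.3, abs=1e-8)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_identical_predictions(self, synth):
        tree, _, tab = synth
        X, _ = tm.build_design(tab, tree)
        y = tab["status"].map(tm.status_to_code)
        n = len(X)
        eye = np.eye(n)
        res = tm.fit_pglm(X, y, eye, eye)
        pred = res.predict(pd.concat([X.iloc[[0]], X.iloc[[0]]]))
        assert pred.iloc[0] == pred.iloc[1]

    def test_singular_design_reports_condition_number(self, synth):
        tree, _, tab = synth
        X, _ = tm.build_design(tab, tree)
        X = X.copy()
        X["dup"] = X["range_area"]
        y = tab["status"].map(tm.status_to_code)
        n = len(X)
        with pytest.raises(ValueError, match="condition number"):
            tm.fit_pglm(X, y, np.eye(n), np.eye(n))

    def test_area_dominates_importance(self, synth):
        tree, _, tab = synth
        X, _ = tm.build_design(tab, tree)
        y = tab["status"].map(tm.status_to_code)
        n = len(X)
        res = tm.fit_pglm(X, y, np.eye(n), np.eye(n))
        assert res.importance.idxmax() == "range_area"


class TestRF:
    def test_pure_noise_oob_near_chance(self, synth):
        tree, _, tab = synth
        X = tm._raw_design(tab, tree)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.integers(1, 7, len(X)).astype(float), index=X.index)
        res = tm.fit_rf(X, y, n_trees=300, seed=1)
        # regression OOB R^2 on noise should hover near (or below) zero
        assert res.tuning["oob_r2"] < 0.15

    def test_area_ranks_first(self, synth):
        tree, _, tab = synth
        X = tm._raw_design(tab, tree)
        y = tab["status"].map(tm.status_to_code)
        res = tm.fit_rf(X, y, seed=2)
        assert res.importance.idxmax() == "range_area"

    def test_training_row_duplicate_close_prediction(self, synth):
        tree, _, tab = synth
        X = tm._raw_design(tab, tree)
        y = tab["status"].map(tm.status_to_code)
        res = tm.fit_rf(X, y, seed=3)
        known = y.notna()
        i = X[known].index[0]
        pred = res.predict(X.loc[[i]])
        assert abs(pred.iloc[0] - y[i]) <= 0.5

    def test_invalid_n_trees(self, synth):
        tree, _, tab = synth
        X = tm._raw_design(tab, tree)
        y = tab["status"].map(tm.status_to_code)
        with pytest.raises(ValueError):
            tm.fit_rf(X, y, n_trees=0)


class TestANN:
    def test_linear_toy_capacity(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(0, 1, (200, 2)), columns=["u", "v"])
        y = pd.Series(1.0 + 4.0 * X["u"] + 0.5 * X["v"], index=X.index)
        res = tm.fit_ann(X, y, hidden_sizes_grid=(8,), weight_decay_grid=(1e-4,),
                         k_folds=4, repeats=1, seed=5)
        rmse = float(np.sqrt(np.mean((res.predict(X) - np.clip(y, 1, 6)) ** 2)))
        assert rmse < 0.1

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.uniform(0, 1, (80, 3)), columns=list("abc"))
        y = pd.Series(rng.uniform(1, 6, 80), index=X.index)
        kw = dict(hidden_sizes_grid=(4,), weight_decay_grid=(1e-3,),
                  k_folds=4, repeats=1, seed=11)
        p1 = tm.fit_ann(X, y, **kw).predict(X)
        p2 = tm.fit_ann(X, y, **kw).predict(X)
        assert np.allclose(p1, p2)

    def test_zero_hidden_rejected(self):
        X = pd.DataFrame({"a": [0.1, 0.5]})
        y = pd.Series([1.0, 2.0], index=X.index)
        with pytest.raises(ValueError, match="neuron"):
            tm.fit_ann(X, y, hidden_sizes_grid=(0,))

    def test_unscaled_input_rejected(self):
        X = pd.DataFrame({"a": [0.0, 5.0]})
        y = pd.Series([1.0, 2.0], index=X.index)
        with pytest.raises(ValueError, match="min-max"):
            tm.fit_ann(X, y)


class _ConstModel:
    def __init__(self, v):
        self.v = v

    def predict(self, X):
        return pd.Series(self.v, index=X.index)


class _OracleModel:
    def __init__(self, y):
        self.y = y

    def predict(self, X):
        return self.y.reindex(X.index).astype(float)


class TestCrossValidation:
    def _data(self, n_per_class=6):
        y = pd.Series(np.repeat(np.arange(1, 7), n_per_class).astype(float))
        X = pd.DataFrame({"f": np.arange(len(y), dtype=float)})
        y.index = X.index
        return X, y

    def test_perfect_predictor_identity_confusion(self):
        X, y = self._data()
        out = tm.crossvalidate(lambda Xt, yt: _OracleModel(y), X, y,
                               scheme="loocv")
        assert out["accuracy"] == 1.0
        conf = out["confusion"].to_numpy()
        assert np.trace(conf) == conf.sum()

    def test_uniform_random_predictor_near_chance(self):
        X, y = self._data(n_per_class=40)
        rng = np.random.default_rng(9)

        class _Rand:
            def predict(self, Xt):
                return pd.Series(rng.integers(1, 7, len(Xt)).astype(float),
                                 index=Xt.index)

        out = tm.crossvalidate(lambda Xt, yt: _Rand(), X, y, scheme="loocv")
        n = len(y)
        ci = 3 * np.sqrt((1 / 6) * (5 / 6) / n)
        assert abs(out["accuracy"] - 1 / 6) < ci

    def test_constant_predictor_sensitivity_pattern(self):
        X, y = self._data()
        out = tm.crossvalidate(lambda Xt, yt: _ConstModel(3.0), X, y,
                               scheme="loocv")
        assert out["accuracy"] == pytest.approx(1 / 6)
        assert out["sensitivity"][3] == 1.0
        assert all(out["sensitivity"][c] == 0.0 for c in (1, 2, 4, 5, 6))

    def test_loocv_missing_class_warning(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        X = pd.DataFrame({"f": np.arange(6.0)})
        out = tm.crossvalidate(lambda Xt, yt: _ConstModel(1.0), X, y,
                               scheme="loocv")
        assert len(out["warnings"]) == 6  # each left-out class vanishes


class TestPooling:
    def test_mean_and_category(self):
        mean, code = tm.pool_predictions(2.0, 3.0, 4.0)
        assert mean == pytest.approx(3.0) and code == 3

    def test_identity_on_agreement(self):
        mean, code = tm.pool_predictions(3.0, 3.0, 3.0)
        assert mean == 3.0 and code == 3

    def test_clamp_then_mean(self):
        mean, code = tm.pool_predictions(1.0, 1.0, 6.9)
        assert mean == pytest.approx(8.0 / 3.0)
        assert code == 3

    def test_permutation_invariant(self):
        a = tm.pool_predictions(1.2, 3.4, 5.6)
        b = tm.pool_predictions(5.6, 1.2, 3.4)
        assert a[0] == pytest.approx(b[0]) and a[1] == b[1]

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            tm.pool_predictions(1.0, np.nan, 2.0)


class TestConcordance:
    def test_full_agreement(self):
        cats = pd.DataFrame({"a": [2] * 10, "b": [2] * 10, "c": [2] * 10})
        out = tm.concordance(cats)
        assert out["n_all_identical"] == 10
        assert out["pct_identical"] == 100.0

    def test_114_species_gives_342_comparisons(self):
        rng = np.random.default_rng(1)
        cats = pd.DataFrame(rng.integers(1, 7, (114, 3)), columns=list("abc"))
        out = tm.concordance(cats)
        assert out["total_pairwise"] == 342

    def test_single_species_enumeration(self):
        cats = pd.DataFrame({"a": [1], "b": [2], "c": [3]})
        out = tm.concordance(cats)
        assert out["pairwise_identical"] == 0
        assert out["pairwise_adjacent"] == 2
        assert out["n_all_identical"] == 0 and out["n_two_agree"] == 0

    def test_two_agree_counting(self):
        cats = pd.DataFrame({"a": [2], "b": [2], "c": [5]})
        out = tm.concordance(cats)
        assert out["n_two_agree"] == 1 and out["n_all_identical"] == 0

    def test_unequal_lengths_rejected(self):
        cats = pd.DataFrame({"a": [1, 2], "b": [1, 2], "c": [1, np.nan]})
        with pytest.raises(ValueError):
            tm.concordance(cats)
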