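"""Tree Shapley attributions: exact-enumeration agreement and axioms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

import voripk as vp
from voripk.shapley import Tree, TreeEnsemble, ensemble_from, expected_value
from voripk.structural import DataError


def brute_force_phi(tree: Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Shapley values by coalition enumeration with the tree's cover-weighted
    marginal expectation as the value function."""
    feats = sorted(set(tree.feature[tree.feature >= 0]))

    def value(S):
        mask = np.zeros(n_features, dtype=bool)
        mask[list(S)] = True
        return tree.expectation(x, mask)

    phi = np.zeros(n_features)
    F = len(feats)
    for f in feats:
        others = [g for g in feats if g != f]
        for r in range(F):
            for S in itertools.combinations(others, r):
                w = math.factorial(r) * math.factorial(F - r - 1) / math.factorial(F)
                phi[f] += w * (value(set(S) | {f}) - value(S))
    return phi


def fitted_small_trees(n_trials=20, depth=3, p=4):
    rng = np.random.default_rng(0)
    for trial in range(n_trials):
        X = rng.standard_normal((60, p))
        y = 2 * X[:, 0] + np.sin(X[:, 1]) + X[:, 2] * X[:, 3] \
            + 0.3 * rng.standard_normal(60)
        model = DecisionTreeRegressor(max_depth=depth, random_state=trial).fit(X, y)
        yield model, X


class TestExactAgreement:
    def test_matches_enumeration_on_small_trees(self):
        for model, X in fitted_small_trees():
            ens = ensemble_from(model)
            Xdf = pd.DataFrame(X[:4], columns=[f"x{i}" for i in range(X.shape[1])])
            attr = vp.shap_values(ens, Xdf, feature_names=list(Xdf.columns))
            for r in range(len(Xdf)):
                ref = brute_force_phi(ens.trees[0], X[r], X.shape[1])
                assert np.abs(attr.phi.iloc[r].to_numpy() - ref).max() < 1e-8

    def test_symmetry_for_identical_features(self):
        # a hand-built tree symmetric in features 0 and 1, applied to a row
        # where both take the same value, must credit them equally
        tree = Tree(
            feature=np.array([0, 1, 1, -1, -1, -1, -1]),
            threshold=np.array([0.0, 0.0, 0.0, 0, 0, 0, 0], dtype=float),
            left=np.array([1, 3, 5, -1, -1, -1, -1]),
            right=np.array([2, 4, 6, -1, -1, -1, -1]),
            value=np.array([0, 0, 0, 0.0, 1.0, 1.0, 2.0]),
            cover=np.array([4.0, 2, 2, 1, 1, 1, 1]),
        )
        ens = TreeEnsemble([tree], 0.0, 2)
        X = pd.DataFrame({"a": [1.0, -1.0], "b": [1.0, -1.0]})
        attr = vp.shap_values(ens, X, feature_names=["a", "b"])
        assert np.allclose(attr.phi["a"], attr.phi["b"])


class TestAxioms:
    def test_constant_model_gives_zero_phi(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        model = DecisionTreeRegressor(max_depth=2).fit(X, np.full(5, 7.0))
        attr = vp.shap_values(model, X, feature_names=["a"])
        assert np.allclose(attr.phi, 0.0)
        assert attr.base_value == pytest.approx(7.0)

    def test_unused_feature_gets_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"used": rng.standard_normal(80),
                          "unused": rng.standard_normal(80)})
        y = 3 * X["used"]
        model = DecisionTreeRegressor(max_depth=2).fit(X, y)
        attr = vp.shap_values(model, X.iloc[:10], feature_names=["used", "unused"])
        assert np.allclose(attr.phi["unused"], 0.0)

    @pytest.mark.parametrize("name", ["XGBoost", "LightGBM", "GBDT", "RF"])
    def test_additivity_on_fitted_ensembles(self, trained_models, ml_split, name):
        model = trained_models[name]
        _, val = ml_split
        X = val[model.feature_names_].iloc[:12]
        attr = vp.shap_values(model, X)
        total = attr.base_value + attr.phi.sum(axis=1).to_numpy()
        assert np.abs(total - attr.prediction).max() < 1e-6
        own = np.asarray(model.predict(X))
        assert np.abs(own - attr.prediction).max() < 1e-4

    def test_adaboost_rejected(self, trained_models):
        with pytest.raises(DataError):
            ensemble_from(trained_models["AdaBoost"])


class TestBackground:
    def test_background_sets_base_value_to_its_mean_prediction(self, trained_models,
                                                               ml_split):
        model = trained_models["GBDT"]
        train, val = ml_split
        bg = train.iloc[:50]
        attr = vp.shap_values(model, val[model.feature_names_].iloc[:5],
                              background=bg)
        mean_pred = float(np.mean(model.predict(bg[model.feature_names_])))
        assert attr.base_value == pytest.approx(mean_pred, abs=1e-8)
        total = attr.base_value + attr.phi.sum(axis=1).to_numpy()
        assert np.abs(total - attr.prediction).max() < 1e-6


class TestRankingAndWaterfall:
    def test_all_zero_phi_ranks_alphabetically(self):
        attr = vp.ShapAttribution(
            base_value=1.0,
            phi=pd.DataFrame({"b": [0.0], "a": [0.0]}),
            prediction=np.array([1.0]),
        )
        assert [f for f, _ in vp.rank_features(attr)] == ["a", "b"]

    def test_single_feature_ranks_first(self):
        attr = vp.ShapAttribution(
            base_value=0.0,
            phi=pd.DataFrame({"only": [0.3, -0.5]}),
            prediction=np.array([0.3, -0.5]),
        )
        assert vp.rank_features(attr)[0][0] == "only"

    def test_waterfall_ledger_sums_to_prediction(self, trained_models, ml_split):
        model = trained_models["XGBoost"]
        _, val = ml_split
        attr = vp.shap_values(model, val[model.feature_names_].iloc[:6])
        for row in range(6):
            led = vp.waterfall(attr, row)
            total = led["base_value"] + sum(v for _, v in led["steps"])
            assert total == pytest.approx(led["prediction"], abs=1e-6)
            mags = [abs(v) for _, v in led["steps"]]
            assert mags == sorted(mags, reverse=True)

    def test_invalid_row_rejected(self):
        attr = vp.ShapAttribution(
            base_value=0.0, phi=pd.DataFrame({"a": [0.1]}),
            prediction=np.array([0.1]))
        with pytest.raises(DataError):
            vp.waterfall(attr, 5)


def test_expected_value_is_cover_weighted_leaf_mean():
    tree = Tree(
        feature=np.array([0, -1, -1]),
        threshold=np.array([0.0, 0.0, 0.0]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        value=np.array([0.0, 1.0, 3.0]),
        cover=np.array([4.0, 3.0, 1.0]),
    )
    ens = TreeEnsemble([tree], intercept=0.5, n_features=1)
    assert expected_value(ens) == pytest.approx(0.5 + (3 * 1.0 + 1 * 3.0) / 4)
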