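"""Shapley attributions for tree-ensemble regressors, implemented directly.

Uses the path-dependent formulation: the value function of a coalition S
is the tree-conditional expectation obtained by following x on features in
S and averaging children by their training cover everywhere else.  The
polynomial-time path algorithm computes, per tree and per row, the exact
Shapley values of that value function; summed over trees (plus the
ensemble intercept) they satisfy local accuracy:

    base_value + sum_f phi[row, f] == prediction[row].

Supported ensembles: sklearn decision trees, random forests and gradient
boosting, XGBoost and LightGBM regressors.  AdaBoost's weighted-median
aggregation is not additive over trees and is rejected.  An optional
background matrix re-derives node covers by routing those rows through
each tree, making the expectation (and hence base_value) refer to that
set instead of the training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structural import DataError

__all__ = ["Tree", "TreeEnsemble", "ShapAttribution", "ensemble_from",
           "shap_values", "expected_value", "rank_features", "waterfall"]


@dataclass
class Tree:
    """One regression tree in left/right-array form.

    ``op`` is the comparison sending a row to the left child: 'le' (x <=
    threshold, sklearn/LightGBM) or 'lt' (x < threshold, XGBoost).  Leaves
    have feature == -1 and carry their value in ``value``; ``cover`` is
    the (training or background) sample weight reaching each node.
    """

    feature: np.ndarray  # int, -1 at leaves
    threshold: np.ndarray
    left: np.ndarray  # int child index, -1 at leaves
    right: np.ndarray
    value: np.ndarray
    cover: np.ndarray
    op: str = "le"

    def goes_left(self, xval: float, node: int) -> bool:
        t = self.threshold[node]
        if self.op == "le":
            return xval <= t
        # XGBoost evaluates x < t in float32
        return np.float32(xval) < np.float32(t)

    def predict_row(self, x: np.ndarray) -> float:
        j = 0
        while self.feature[j] >= 0:
            j = self.left[j] if self.goes_left(x[self.feature[j]], j) else self.right[j]
        return float(self.value[j])

    def expectation(self, x: np.ndarray, in_coalition: np.ndarray,
                    node: int = 0) -> float:
        """Cover-weighted conditional expectation: follow x on coalition
        features, average children by cover elsewhere."""
        f = self.feature[node]
        if f < 0:
            return float(self.value[node])
        if in_coalition[f]:
            child = self.left[node] if self.goes_left(x[f], node) else self.right[node]
            return self.expectation(x, in_coalition, child)
        lo, hi = self.left[node], self.right[node]
        w = self.cover[lo] + self.cover[hi]
        return (
            self.cover[lo] * self.expectation(x, in_coalition, lo)
            + self.cover[hi] * self.expectation(x, in_coalition, hi)
        ) / w


@dataclass
class TreeEnsemble:
    trees: list[Tree]
    intercept: float
    n_features: int

    def predict_row(self, x: np.ndarray) -> float:
        return self.intercept + sum(t.predict_row(x) for t in self.trees)

    def with_background(self, X: np.ndarray) -> "TreeEnsemble":
        """Recompute node covers by routing background rows through each tree.

        Subtrees no background row reaches are pruned (the node collapses
        onto its populated child) so the expectation refers exactly to the
        background distribution.
        """
        if len(X) == 0:
            raise DataError("background set is empty")
        trees = []
        for t in self.trees:
            cover = np.zeros(len(t.feature))
            for x in X:
                j = 0
                cover[j] += 1
                while t.feature[j] >= 0:
                    j = t.left[j] if t.goes_left(x[t.feature[j]], j) else t.right[j]
                    cover[j] += 1

            nodes: list[tuple] = []

            def build(j: int) -> int:
                if t.feature[j] < 0:
                    nodes.append((-1, 0.0, -1, -1, t.value[j], cover[j]))
                    return len(nodes) - 1
                lo, hi = t.left[j], t.right[j]
                if cover[lo] == 0:
                    return build(hi)
                if cover[hi] == 0:
                    return build(lo)
                k = len(nodes)
                nodes.append(None)
                kl = build(lo)
                kr = build(hi)
                nodes[k] = (t.feature[j], t.threshold[j], kl, kr, 0.0, cover[j])
                return k

            build(0)
            arr = list(zip(*nodes))
            trees.append(Tree(
                feature=np.array(arr[0], dtype=int),
                threshold=np.array(arr[1], dtype=float),
                left=np.array(arr[2], dtype=int),
                right=np.array(arr[3], dtype=int),
                value=np.array(arr[4], dtype=float),
                cover=np.array(arr[5], dtype=float),
                op=t.op,
            ))
        return TreeEnsemble(trees, self.intercept, self.n_features)


@dataclass
class ShapAttribution:
    """Per-row additive feature attributions (mg/L) for a model."""

    base_value: float
    phi: pd.DataFrame  # rows x features
    prediction: np.ndarray

    def global_importance(self) -> pd.Series:
        return self.phi.abs().mean().sort_values(ascending=False)


# -- the path algorithm ----------------------------------------------------


def _extend(path: list[list], pz: float, po: float, pi: int) -> list[list]:
    """Grow the unique path by one split; elements are [feature, zero_frac,
    one_frac, pweight]."""
    d = len(path)
    out = [e.copy() for e in path]
    out.append([pi, pz, po, 1.0 if d == 0 else 0.0])
    for i in range(d - 1, -1, -1):
        out[i + 1][3] += po * out[i][3] * (i + 1) / (d + 1)
        out[i][3] = pz * out[i][3] * (d - i) / (d + 1)
    return out


def _unwind(path: list[list], i: int) -> list[list]:
    d = len(path) - 1
    pz, po = path[i][1], path[i][2]
    out = [e.copy() for e in path]
    nxt = out[d][3]
    for j in range(d - 1, -1, -1):
        if po != 0:
            tmp = out[j][3]
            out[j][3] = nxt * (d + 1) / ((j + 1) * po)
            nxt = tmp - out[j][3] * pz * (d - j) / (d + 1)
        else:
            out[j][3] = out[j][3] * (d + 1) / (pz * (d - j))
    for j in range(i, d):
        out[j][0], out[j][1], out[j][2] = out[j + 1][0], out[j + 1][1], out[j + 1][2]
    return out[:-1]


def _unwound_sum(path: list[list], i: int) -> float:
    d = len(path) - 1
    pz, po = path[i][1], path[i][2]
    nxt = path[d][3]
    total = 0.0
    for j in range(d - 1, -1, -1):
        if po != 0:
            tmp = nxt * (d + 1) / ((j + 1) * po)
            total += tmp
            nxt = path[j][3] - tmp * pz * (d - j) / (d + 1)
        else:
            total += path[j][3] * (d + 1) / (pz * (d - j))
    return total


def _tree_shap(tree: Tree, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(node: int, path: list[list], pz: float, po: float, pi: int):
        path = _extend(path, pz, po, pi)
        f = tree.feature[node]
        if f < 0:
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[path[i][0]] += w * (path[i][2] - path[i][1]) * tree.value[node]
            return
        lo, hi = tree.left[node], tree.right[node]
        hot, cold = (lo, hi) if tree.goes_left(x[f], node) else (hi, lo)
        cover = tree.cover[node]
        iz = io = 1.0
        k = next((i for i in range(1, len(path)) if path[i][0] == f), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            path = _unwind(path, k)
        recurse(hot, path, iz * tree.cover[hot] / cover, io, f)
        recurse(cold, path, iz * tree.cover[cold] / cover, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


# -- model conversion ------------------------------------------------------


def _from_sklearn_tree(t, scale: float = 1.0) -> Tree:
    tr = t.tree_
    return Tree(
        feature=tr.feature.copy(),
        threshold=tr.threshold.copy(),
        left=tr.children_left.copy(),
        right=tr.children_right.copy(),
        value=tr.value.reshape(-1) * scale,
        cover=tr.weighted_n_node_samples.copy(),
        op="le",
    )


def _from_xgboost(model) -> TreeEnsemble:
    booster = model.get_booster()
    cfg = json.loads(booster.save_config())
    base = float(cfg["learner"]["learner_model_param"]["base_score"])
    df = booster.trees_to_dataframe()
    trees = []
    for _, grp in df.groupby("Tree"):
        grp = grp.set_index("ID")
        ids = list(grp.index)
        pos = {i: k for k, i in enumerate(ids)}
        n = len(ids)
        feat = np.full(n, -1, dtype=int)
        thr = np.zeros(n)
        left = np.full(n, -1, dtype=int)
        right = np.full(n, -1, dtype=int)
        val = np.zeros(n)
        cov = np.zeros(n)
        for i in ids:
            row = grp.loc[i]
            k = pos[i]
            cov[k] = row["Cover"]
            if row["Feature"] == "Leaf":
                val[k] = row["Gain"]
            else:
                name = row["Feature"]
                feat[k] = int(name[1:]) if name.startswith("f") and name[1:].isdigit() \
                    else list(model.feature_names_in_).index(name)
                thr[k] = row["Split"]
                left[k] = pos[row["Yes"]]
                right[k] = pos[row["No"]]
        trees.append(Tree(feat, thr, left, right, val, cov, op="lt"))
    return TreeEnsemble(trees, base, model.n_features_in_)


def _from_lightgbm(model) -> TreeEnsemble:
    dump = model.booster_.dump_model()
    trees = []
    for info in dump["tree_info"]:
        nodes: list[dict] = []

        def walk(node) -> int:
            k = len(nodes)
            nodes.append({})
            if "split_feature" in node:
                nodes[k] = {
                    "feature": node["split_feature"],
                    "threshold": node["threshold"],
                    "cover": node["internal_count"],
                }
                nodes[k]["left"] = walk(node["left_child"])
                nodes[k]["right"] = walk(node["right_child"])
            else:
                nodes[k] = {"feature": -1, "threshold": 0.0,
                            "value": node["leaf_value"],
                            "cover": node.get("leaf_count", 1),
                            "left": -1, "right": -1}
            return k

        walk(info["tree_structure"])
        n = len(nodes)
        trees.append(Tree(
            feature=np.array([d["feature"] for d in nodes], dtype=int),
            threshold=np.array([d["threshold"] for d in nodes], dtype=float),
            left=np.array([d["left"] for d in nodes], dtype=int),
            right=np.array([d["right"] for d in nodes], dtype=int),
            value=np.array([d.get("value", 0.0) for d in nodes], dtype=float),
            cover=np.array([d["cover"] for d in nodes], dtype=float),
            op="le",
        ))
    return TreeEnsemble(trees, 0.0, model.n_features_in_)


def ensemble_from(model) -> TreeEnsemble:
    """Convert a fitted tree model to the internal ensemble form.

    The conversion is validated by comparing the reassembled prediction
    (sum of trees + intercept) against the model's own predict on a probe;
    any constant offset the backend keeps outside its trees is folded into
    the intercept.
    """
    name = type(model).__name__
    if name == "DecisionTreeRegressor":
        ens = TreeEnsemble([_from_sklearn_tree(model)], 0.0, model.n_features_in_)
    elif name == "RandomForestRegressor":
        k = len(model.estimators_)
        ens = TreeEnsemble([_from_sklearn_tree(t, 1.0 / k) for t in model.estimators_],
                           0.0, model.n_features_in_)
    elif name == "GradientBoostingRegressor":
        ens = TreeEnsemble(
            [_from_sklearn_tree(t[0], model.learning_rate)
             for t in model.estimators_],
            0.0, model.n_features_in_)
    elif name == "XGBRegressor":
        ens = _from_xgboost(model)
    elif name == "LGBMRegressor":
        ens = _from_lightgbm(model)
    elif name in ("AdaBoostRegressor", "CatBoostRegressor"):
        raise DataError(f"{name} is not supported for tree Shapley attribution")
    else:
        raise DataError(f"unrecognized tree model: {name}")

    probe = np.zeros((1, ens.n_features))
    own = float(model.predict(probe)[0])
    mine = ens.predict_row(probe[0])
    ens.intercept += own - mine
    return ens


# -- public API ------------------------------------------------------------


def expected_value(ens: TreeEnsemble) -> float:
    """Cover-weighted mean prediction (the empty-coalition expectation)."""
    x = np.zeros(ens.n_features)
    none = np.zeros(ens.n_features, dtype=bool)
    return ens.intercept + sum(t.expectation(x, none) for t in ens.trees)


def shap_values(model, X: pd.DataFrame, background: pd.DataFrame | None = None,
                feature_names: list[str] | None = None) -> ShapAttribution:
    """Per-row Shapley attributions for a fitted tree-ensemble model.

    ``background`` (default: the covers stored at fit time, i.e. the
    training set) defines the reference distribution; base_value is its
    expected prediction.  Additivity holds row-wise to ~1e-6.
    """
    ens = model if isinstance(model, TreeEnsemble) else ensemble_from(model)
    if feature_names is None:
        feature_names = getattr(model, "feature_names_", None) or list(X.columns)
    if list(X.columns) != list(feature_names):
        missing = [c for c in feature_names if c not in X.columns]
        if missing:
            raise DataError("feature matrix missing columns: " + ", ".join(missing))
        X = X[feature_names]
    Xv = X.to_numpy(dtype=float)
    if Xv.shape[1] != ens.n_features:
        raise DataError(
            f"matrix has {Xv.shape[1]} features, model expects {ens.n_features}")
    if background is not None:
        ens = ens.with_background(background[feature_names].to_numpy(dtype=float))
    base = expected_value(ens)
    phi = np.zeros((len(Xv), ens.n_features))
    for r, x in enumerate(Xv):
        for t in ens.trees:
            _tree_shap(t, x, phi[r])
    pred = np.array([ens.predict_row(x) for x in Xv])
    return ShapAttribution(
        base_value=base,
        phi=pd.DataFrame(phi, columns=feature_names, index=X.index),
        prediction=pred,
    )


def rank_features(attr: ShapAttribution) -> list[tuple[str, float]]:
    """Features by descending mean |phi|; ties broken alphabetically."""
    if attr.phi.empty:
        raise DataError("empty attribution")
    mean_abs = attr.phi.abs().mean()
    order = sorted(mean_abs.index, key=lambda f: (-mean_abs[f], f))
    return [(f, float(mean_abs[f])) for f in order]


def waterfall(attr: ShapAttribution, row: int) -> dict:
    """Ordered contribution ledger for one row: base -> steps -> prediction."""
    if not (0 <= row < len(attr.phi)):
        raise DataError(f"row {row} out of range")
    contribs = attr.phi.iloc[row]
    steps = sorted(contribs.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return {
        "base_value": attr.base_value,
        "steps": [(f, float(v)) for f, v in steps],
        "prediction": float(attr.prediction[row]),
    }
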