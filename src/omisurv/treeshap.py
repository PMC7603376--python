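"""Exact path-dependent Shapley values for gradient-boosted tree ensembles.

Implements the polynomial-time TreeSHAP recursion (tracking, per decision
path, the fraction of one/zero subsets and their Shapley weights) so that
for every sample the attributions satisfy local accuracy exactly:

    base_value + sum_i phi_i(x) = raw margin f(x)

where base_value is the cover-weighted expectation of the ensemble output.
Works on the two scikit-learn gradient-boosting families used as the
package's GBDT presets; each tree is first converted to a flat node-array
form (children, split feature, threshold, leaf value, cover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FlatTree:
    """One regression tree in flat-array form; leaf values include shrinkage."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray  # node sample weights, consistent parent = sum(children)

    def expected_value(self) -> float:
        leaves = self.children_left < 0
        return float(
            np.sum(self.value[leaves] * self.cover[leaves]) / self.cover[0]
        )


def _extend(d, z, o, w, pz, po, pi):
    l = len(d)
    d.append(pi)
    z.append(pz)
    o.append(po)
    w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / (l + 1)
        w[i] = pz * w[i] * (l - i) / (l + 1)


def _unwind(d, z, o, w, k):
    length = len(d)
    n = w[length - 1]
    zi, oi = z[k], o[k]
    for j in range(length - 2, -1, -1):
        if oi != 0:
            t = w[j]
            w[j] = n * length / ((j + 1) * oi)
            n = t - w[j] * zi * (length - 1 - j) / length
        else:
            w[j] = w[j] * length / (zi * (length - 1 - j))
    for j in range(k, length - 1):
        d[j], z[j], o[j] = d[j + 1], z[j + 1], o[j + 1]
    d.pop(), z.pop(), o.pop(), w.pop()


def _unwound_sum(d, z, o, w, k):
    length = len(d)
    n = w[length - 1]
    zi, oi = z[k], o[k]
    total = 0.0
    for j in range(length - 2, -1, -1):
        if oi != 0:
            tmp = n * length / ((j + 1) * oi)
            total += tmp
            n = w[j] - tmp * zi * (length - 1 - j) / length
        else:
            total += w[j] * length / (zi * (length - 1 - j))
    return total


def _tree_shap_recurse(tree: FlatTree, x, phi, node, d, z, o, w, pz, po, pi):
    d, z, o, w = list(d), list(z), list(o), list(w)
    _extend(d, z, o, w, pz, po, pi)
    left = tree.children_left[node]
    if left < 0:  # leaf
        v = tree.value[node]
        for k in range(1, len(d)):
            s = _unwound_sum(d, z, o, w, k)
            phi[d[k]] += s * (o[k] - z[k]) * v
        return
    right = tree.children_right[node]
    f = tree.feature[node]
    hot, cold = (left, right) if x[f] <= tree.threshold[node] else (right, left)
    iz = io = 1.0
    k = next((i for i in range(len(d)) if d[i] == f), None)
    if k is not None:
        iz, io = z[k], o[k]
        _unwind(d, z, o, w, k)
    rj = tree.cover[node]
    _tree_shap_recurse(
        tree, x, phi, hot, d, z, o, w, iz * tree.cover[hot] / rj, io, f
    )
    _tree_shap_recurse(
        tree, x, phi, cold, d, z, o, w, iz * tree.cover[cold] / rj, 0.0, f
    )


def tree_shap_values(trees: list[FlatTree], X: np.ndarray):
    """Per-sample, per-feature Shapley values of the summed tree outputs.

    Returns ``(phi, base_value)`` with ``phi`` of shape (n_samples,
    n_features); base_value is the cover-weighted expected ensemble output.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    phi = np.zeros((n, m))
    for tree in trees:
        for i in range(n):
            _tree_shap_recurse(
                tree, X[i], phi[i], 0, [], [], [], [], 1.0, 1.0, -1
            )
    base = float(sum(t.expected_value() for t in trees))
    return phi, base


def flatten_gradient_boosting(model) -> tuple[list[FlatTree], float]:
    """Flatten a binary sklearn GradientBoostingClassifier.

    Returns the trees (leaf values scaled by the learning rate) and the raw
    prior offset, so that offset + sum of tree outputs = decision_function.
    """
    trees = []
    for est in model.estimators_[:, 0]:
        t = est.tree_
        trees.append(
            FlatTree(
                children_left=t.children_left.copy(),
                children_right=t.children_right.copy(),
                feature=t.feature.copy(),
                threshold=t.threshold.copy(),
                value=model.learning_rate * t.value[:, 0, 0].copy(),
                cover=t.weighted_n_node_samples.copy(),
            )
        )
    # prior log-odds of the init estimator
    p = np.clip(model.init_.class_prior_[1], 1e-12, 1 - 1e-12)
    offset = float(np.log(p / (1.0 - p)))
    return trees, offset


def flatten_hist_gradient_boosting(model) -> tuple[list[FlatTree], float]:
    """Flatten a binary sklearn HistGradientBoostingClassifier.

    Predictor node values already include shrinkage; the raw offset is the
    model's baseline prediction.
    """
    trees = []
    for (predictor,) in model._predictors:
        nodes = predictor.nodes
        is_leaf = nodes["is_leaf"].astype(bool)
        trees.append(
            FlatTree(
                children_left=np.where(is_leaf, -1, nodes["left"].astype(np.int64)),
                children_right=np.where(is_leaf, -1, nodes["right"].astype(np.int64)),
                feature=np.where(is_leaf, -2, nodes["feature_idx"].astype(np.int64)),
                threshold=nodes["num_threshold"].astype(float),
                value=nodes["value"].astype(float),
                cover=nodes["count"].astype(float),
            )
        )
    offset = float(np.ravel(model._baseline_prediction)[0])
    return trees, offset
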