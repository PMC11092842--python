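"""Shapley-value feature attributions and their plot exports.

For tree models (decision trees and averaging forests) attributions are
computed exactly under the interventional value function: for a foreground
row x and a background row z, the payoff of a feature coalition S is the
tree output when features in S take x's values and the rest take z's. For a
single (x, z) pair this game decomposes over leaves into conjunction games
whose Shapley values have a closed form, so the per-pair attribution is
exact and the average over a background set satisfies local accuracy to
floating-point precision: base value + sum of attributions = model output.

For arbitrary models a seeded permutation-sampling estimator is provided;
it enumerates all permutations exactly when the feature count is small and
uses antithetic sampling otherwise. Each walked permutation telescopes to
f(x) - f(z), so local accuracy holds for the sampled estimator too.

Beeswarm and force plots are exported as static images, always accompanied
by a machine-readable TSV twin holding the plotted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations
from math import factorial
from pathlib import Path
from typing import Callable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

TREE_EXACT_TYPES = (DecisionTreeClassifier, RandomForestClassifier, ExtraTreesClassifier)


@dataclass
class AttributionMatrix:
    """Per-class Shapley values for a batch of explained rows.

    ``values[class][i, j]`` is feature j's contribution to moving row i's
    model output for that class away from ``base_values[class]`` (the mean
    model output over the background set).
    """

    values: dict[str, np.ndarray]  # class -> (n_rows, n_features)
    base_values: dict[str, float]
    feature_names: list[str]
    row_ids: list[str]
    model_output: dict[str, np.ndarray]  # class -> (n_rows,) raw outputs f(x)

    @property
    def classes(self) -> list[str]:
        return list(self.values)

    def local_accuracy_error(self, class_name: str) -> np.ndarray:
        """|base + sum(attributions) - f(x)| per row for one class."""
        total = self.base_values[class_name] + self.values[class_name].sum(axis=1)
        return np.abs(total - self.model_output[class_name])

    def ranking(self, class_name: str) -> list[str]:
        """Feature names ordered by mean |attribution|, descending (stable)."""
        mean_abs = np.abs(self.values[class_name]).mean(axis=0)
        order = np.argsort(-mean_abs, kind="stable")
        return [self.feature_names[i] for i in order]


# ---------------------------------------------------------------------------
# exact interventional Shapley values for trees
# ---------------------------------------------------------------------------

def _pair_tree_shap(tree, x: np.ndarray, z: np.ndarray, n_outputs: int) -> np.ndarray:
    """Exact Shapley values of the (x, z) interventional game for one tree.

    Walks only the leaves reachable under some x/z feature assignment. At a
    leaf reached with feature sets A (forced to x's side) and B (forced to
    z's side), the conjunction game 1[A subset S, B disjoint S] has Shapley
    value (|A|-1)!|B|!/(|A|+|B|)! for members of A and -|A|!(|B|-1)!/(|A|+|B|)!
    for members of B; all other features are null players.
    """
    feature = tree.feature
    threshold = tree.threshold
    left, right = tree.children_left, tree.children_right
    leaf_values = tree.value.reshape(tree.node_count, -1)  # normalized probs per class
    phi = np.zeros((x.shape[0], n_outputs))

    def recurse(node: int, A: frozenset, B: frozenset) -> None:
        if left[node] == -1:  # leaf
            a, b = len(A), len(B)
            d = a + b
            if d == 0:
                return  # reached by both x and z: no attribution
            v = leaf_values[node]
            if a:
                w = factorial(a - 1) * factorial(b) / factorial(d)
                for i in A:
                    phi[i] += w * v
            if b:
                w = factorial(a) * factorial(b - 1) / factorial(d)
                for i in B:
                    phi[i] -= w * v
            return
        f = feature[node]
        x_child = left[node] if x[f] <= threshold[node] else right[node]
        z_child = left[node] if z[f] <= threshold[node] else right[node]
        if f in A:
            recurse(x_child, A, B)
        elif f in B:
            recurse(z_child, A, B)
        elif x_child == z_child:
            recurse(x_child, A, B)
        else:
            recurse(x_child, A | {f}, B)
            recurse(z_child, A, B | {f})

    recurse(0, frozenset(), frozenset())
    return phi


def _tree_outputs(estimator):
    """Yield (tree_, weight) pairs for a supported tree model."""
    if isinstance(estimator, DecisionTreeClassifier):
        yield estimator.tree_, 1.0
    else:  # averaging forest
        n = len(estimator.estimators_)
        for member in estimator.estimators_:
            yield member.tree_, 1.0 / n


def tree_shap_values(
    estimator, X: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values for a tree classifier.

    Returns ``(phi, base)`` with ``phi`` of shape (n_rows, n_features,
    n_classes) and ``base`` the mean predicted probability per class over the
    background set. Satisfies base + phi.sum(features) = predict_proba(X).
    """
    if not isinstance(estimator, TREE_EXACT_TYPES):
        raise TypeError(
            f"tree-exact attribution supports {[t.__name__ for t in TREE_EXACT_TYPES]}; "
            f"got {type(estimator).__name__}. Use method='permutation-sampled'."
        )
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n_classes = len(estimator.classes_)
    phi = np.zeros((X.shape[0], X.shape[1], n_classes))
    for tree_obj, weight in _tree_outputs(estimator):
        # sklearn stores class counts at leaves; normalize to probabilities
        raw = tree_obj.value.reshape(tree_obj.node_count, -1)
        norm = raw / np.maximum(raw.sum(axis=1, keepdims=True), 1e-300)

        class _View:
            feature = tree_obj.feature
            threshold = tree_obj.threshold
            children_left = tree_obj.children_left
            children_right = tree_obj.children_right
            value = norm
            node_count = tree_obj.node_count

        for i, x in enumerate(X):
            for z in background:
                phi[i] += weight * _pair_tree_shap(_View, x, z, n_classes)
    phi /= len(background)
    base = estimator.predict_proba(background).mean(axis=0)
    return phi, base


# ---------------------------------------------------------------------------
# permutation-sampling estimator for arbitrary models
# ---------------------------------------------------------------------------

def permutation_shap_values(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 256,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Shapley values for any vector-output model function.

    When d! <= n_permutations every permutation is walked once (exact
    Shapley values); otherwise permutations are drawn with a seeded RNG in
    antithetic pairs (each sampled order is also walked reversed), which
    halves the variance of the estimate. Local accuracy holds in both modes.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    d = X.shape[1]
    out0 = np.atleast_2d(predict(background[:1]))
    n_outputs = out0.shape[1]
    rng = np.random.default_rng(seed)
    if factorial(d) <= n_permutations:
        perms = [np.array(p) for p in iter_permutations(range(d))]
    else:
        perms = []
        for _ in range(max(1, n_permutations // 2)):
            p = rng.permutation(d)
            perms.append(p)
            perms.append(p[::-1])
    phi = np.zeros((X.shape[0], d, n_outputs))
    for i, x in enumerate(X):
        for z in background:
            for perm in perms:
                current = z.copy()
                prev = np.atleast_2d(predict(current[None, :]))[0]
                for f in perm:
                    current[f] = x[f]
                    val = np.atleast_2d(predict(current[None, :]))[0]
                    phi[i, f] += val - prev
                    prev = val
    phi /= len(background) * len(perms)
    base = np.atleast_2d(predict(background)).mean(axis=0)
    return phi, base


# ---------------------------------------------------------------------------
# high-level interface
# ---------------------------------------------------------------------------

def attribute(
    model,
    X: pd.DataFrame,
    method: str = "tree-exact",
    seed: int = 0,
    background: pd.DataFrame | np.ndarray | None = None,
    n_permutations: int = 256,
    max_background: int = 64,
) -> AttributionMatrix:
    """Shapley attributions for each row of ``X``.

    ``model`` may be a :class:`~cnvsig.classifier.TrainedModel` (the
    pre-calibration estimator is attributed, on transformer-scaled
    features), a fitted sklearn classifier, or — for the permutation method
    — any callable mapping a feature matrix to an output matrix. The
    background defaults to a seeded subsample of ``X`` itself.
    """
    from cnvsig.classifier import TrainedModel  # local import to avoid a cycle

    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    row_ids = [str(i) for i in X.index] if isinstance(X, pd.DataFrame) else [
        str(i) for i in range(np.asarray(X).shape[0])
    ]

    if isinstance(model, TrainedModel):
        Xv = np.asarray(model.transformer.transform(X[model.feature_names]), dtype=float)
        estimator = model.base_estimator
        class_names = [str(c) for c in estimator.classes_]
        feature_names = list(model.feature_names)  # columns follow the model's order
    else:
        Xv = np.asarray(X, dtype=float)
        estimator = model
        class_names = (
            [str(c) for c in estimator.classes_] if hasattr(estimator, "classes_") else None
        )

    if background is None:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(Xv), size=min(max_background, len(Xv)), replace=False)
        bg = Xv[np.sort(idx)]
    else:
        if isinstance(background, pd.DataFrame):
            if isinstance(model, TrainedModel):
                background = model.transformer.transform(background[model.feature_names])
            background = np.asarray(background, dtype=float)
        bg = np.asarray(background, dtype=float)

    if method == "tree-exact":
        phi, base = tree_shap_values(estimator, Xv, bg)
        outputs = estimator.predict_proba(Xv)
    elif method == "permutation-sampled":
        if callable(estimator) and not hasattr(estimator, "predict_proba"):
            predict = estimator
        else:
            predict = estimator.predict_proba
        phi, base = permutation_shap_values(predict, Xv, bg, n_permutations, seed)
        outputs = np.atleast_2d(predict(Xv))
    else:
        raise ValueError(f"unknown method {method!r}; use 'tree-exact' or 'permutation-sampled'")

    if class_names is None or len(class_names) != phi.shape[2]:
        class_names = [f"output_{j}" for j in range(phi.shape[2])]
    values = {cls: phi[:, :, j] for j, cls in enumerate(class_names)}
    bases = {cls: float(base[j]) for j, cls in enumerate(class_names)}
    model_out = {cls: outputs[:, j] for j, cls in enumerate(class_names)}
    return AttributionMatrix(values, bases, feature_names, row_ids, model_out)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def _tsv_twin(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(".tsv")


def export_beeswarm(
    attr: AttributionMatrix,
    class_name: str,
    path: str | Path,
    feature_values: pd.DataFrame | None = None,
    seed: int = 0,
) -> Path:
    """Write a beeswarm plot (PNG/SVG by extension) plus a TSV of plotted values.

    Features are ordered by mean |attribution| descending; point colour
    encodes the (min-max scaled) feature value when ``feature_values`` is
    given. Returns the TSV twin path.
    """
    if class_name not in attr.values:
        raise KeyError(f"unknown class {class_name!r}; have {attr.classes}")
    values = attr.values[class_name]
    ranked = attr.ranking(class_name)
    col_of = {name: i for i, name in enumerate(attr.feature_names)}

    rows = []
    for rank, feat in enumerate(ranked, start=1):
        j = col_of[feat]
        for i, rid in enumerate(attr.row_ids):
            fv = float(feature_values.iloc[i][feat]) if feature_values is not None else float("nan")
            rows.append((feat, rank, rid, float(values[i, j]), fv))
    table = pd.DataFrame(
        rows, columns=["feature", "rank", "row_id", "shap_value", "feature_value"]
    )
    tsv = _tsv_twin(path)
    table.to_csv(tsv, sep="\t", index=False, float_format="%.10g")

    rng = np.random.default_rng(seed)
    n_show = min(len(ranked), 20)
    fig, ax = plt.subplots(figsize=(8, 0.4 * n_show + 1.5))
    for rank, feat in enumerate(ranked[:n_show], start=1):
        j = col_of[feat]
        ys = (n_show - rank) + rng.uniform(-0.25, 0.25, size=values.shape[0])
        if feature_values is not None:
            fv = feature_values[feat].to_numpy(dtype=float)
            span = fv.max() - fv.min()
            colors = (fv - fv.min()) / span if span > 0 else np.full_like(fv, 0.5)
        else:
            colors = np.full(values.shape[0], 0.5)
        ax.scatter(values[:, j], ys, c=colors, cmap="coolwarm", s=12, vmin=0, vmax=1)
    ax.set_yticks([n_show - r for r in range(1, n_show + 1)])
    ax.set_yticklabels(ranked[:n_show])
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(f"Shapley value (class: {class_name})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return tsv


def export_force(
    attr: AttributionMatrix,
    row_id: str,
    class_name: str,
    path: str | Path,
) -> Path:
    """Write a per-variant force plot plus its TSV twin; returns the TSV path."""
    if class_name not in attr.values:
        raise KeyError(f"unknown class {class_name!r}; have {attr.classes}")
    try:
        i = attr.row_ids.index(str(row_id))
    except ValueError:
        raise KeyError(f"unknown row id {row_id!r}") from None
    phi = attr.values[class_name][i]
    order = np.argsort(-np.abs(phi), kind="stable")
    table = pd.DataFrame(
        {
            "feature": [attr.feature_names[j] for j in order],
            "shap_value": phi[order],
        }
    )
    table.insert(0, "row_id", str(row_id))
    tsv = _tsv_twin(path)
    table.to_csv(tsv, sep="\t", index=False, float_format="%.10g")

    n_show = min(len(order), 15)
    fig, ax = plt.subplots(figsize=(7, 0.35 * n_show + 1.5))
    shown = order[:n_show][::-1]
    colors = ["#d62728" if phi[j] > 0 else "#1f77b4" for j in shown]
    ax.barh([attr.feature_names[j] for j in shown], phi[shown], color=colors)
    ax.axvline(0.0, color="grey", lw=0.8)
    base = attr.base_values[class_name]
    out = base + phi.sum()
    ax.set_title(f"{row_id} — {class_name}: base {base:.3f} → output {out:.3f}")
    ax.set_xlabel("Shapley value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return tsv
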