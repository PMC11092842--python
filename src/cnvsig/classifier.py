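"""Per-CNV-type model training, calibration and three-class prediction.

Deletions and duplications get independently trained multi-class models.
Training proceeds in three seeded, stratified 5-fold stages: (1) rank a
roster of common architectures by mean macro F1, (2) random-search
hyperparameters for the winner, (3) fit the final estimator on all training
rows and calibrate its probabilities with per-class isotonic regressions on
out-of-fold predictions (one-vs-rest, renormalized to the simplex). The
prediction contract is three probabilities (benign, VUS, pathogenic) plus an
argmax label with a clinically conservative tie-break
(pathogenic > VUS > benign).
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterSampler, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from cnvsig.features import FeatureTransformer

CLASS_ORDER = ("benign", "VUS", "pathogenic")
#: argmax tie-break priority, most conservative first
TIE_PRIORITY = ("pathogenic", "VUS", "benign")


def _architecture_factories(seed: int) -> dict[str, Callable[[], object]]:
    return {
        "random_forest": lambda: RandomForestClassifier(n_estimators=200, random_state=seed),
        "extra_trees": lambda: ExtraTreesClassifier(n_estimators=200, random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "hist_gradient_boosting": lambda: HistGradientBoostingClassifier(random_state=seed),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "gaussian_nb": lambda: GaussianNB(),
    }


DEFAULT_ROSTER = tuple(_architecture_factories(0))


def make_estimator(architecture: str, seed: int, hyperparameters: Mapping | None = None):
    """Instantiate a roster architecture, optionally with tuned hyperparameters."""
    factories = _architecture_factories(seed)
    if architecture not in factories:
        raise ValueError(f"unknown architecture {architecture!r}; roster: {sorted(factories)}")
    est = factories[architecture]()
    if hyperparameters:
        est.set_params(**hyperparameters)
    return est


def load_hyperparameter_spaces() -> dict[str, dict[str, list]]:
    """The shipped randomized-search spaces (one list of settings per knob)."""
    with resources.files("cnvsig.data").joinpath("hyperparameter_spaces.yaml").open() as fh:
        return yaml.safe_load(fh)


def _check_class_counts(y: np.ndarray, k: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds; use a smaller k"
        )


def _cv(k: int, seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def select_architecture(
    X: np.ndarray,
    y: np.ndarray,
    roster: Sequence[str] = DEFAULT_ROSTER,
    k: int = 5,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Rank roster architectures by mean macro F1 under stratified k-fold CV.

    Returns (architecture, mean macro F1) pairs sorted best-first; ties keep
    roster order. Deterministic for a fixed seed.
    """
    if not roster:
        raise ValueError("architecture roster must be non-empty")
    X, y = np.asarray(X, dtype=float), np.asarray(y)
    _check_class_counts(y, k)
    scores = []
    for name in roster:
        est = make_estimator(name, seed)
        cv_scores = cross_val_score(est, X, y, cv=_cv(k, seed), scoring="f1_macro")
        scores.append((name, float(np.mean(cv_scores))))
    return sorted(scores, key=lambda item: -item[1])


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    architecture: str,
    n_draws: int = 50,
    space: Mapping[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, float]:
    """Randomized hyperparameter search scored by k-fold macro F1.

    ``n_draws`` parameter settings are sampled with a fixed seed and the best
    mean score wins; ties are broken by draw order. An empty or missing space
    returns the architecture defaults with score NaN.
    """
    X, y = np.asarray(X, dtype=float), np.asarray(y)
    _check_class_counts(y, k)
    if space is None:
        space = load_hyperparameter_spaces().get(architecture, {})
    if not space:
        return {}, float("nan")
    sampler = ParameterSampler(dict(space), n_iter=n_draws, random_state=seed)
    best_params, best_score = {}, -np.inf
    for params in sampler:
        est = make_estimator(architecture, seed, params)
        score = float(np.mean(cross_val_score(est, X, y, cv=_cv(k, seed), scoring="f1_macro")))
        if score > best_score:  # strictly greater: ties keep the earlier draw
            best_params, best_score = params, score
    return best_params, best_score


@dataclass
class PredictionResult:
    """Calibrated class probabilities and the argmax significance label."""

    id: str
    pr_benign: float
    pr_vus: float
    pr_pathogenic: float
    label: str

    @property
    def probabilities(self) -> tuple[float, float, float]:
        return (self.pr_benign, self.pr_vus, self.pr_pathogenic)


def label_from_probabilities(probs: Sequence[float]) -> str:
    """Argmax over (benign, VUS, pathogenic) with conservative tie-break."""
    by_class = dict(zip(CLASS_ORDER, probs))
    best = max(by_class.values())
    for cls in TIE_PRIORITY:
        if by_class[cls] == best:
            return cls
    raise AssertionError("unreachable")


@dataclass
class TrainedModel:
    """A calibrated per-type classifier plus its fitted feature transformer."""

    cnv_type: str
    architecture: str
    hyperparameters: dict
    transformer: FeatureTransformer
    estimator: CalibratedClassifierCV
    feature_names: list[str]
    seed: int
    cv_summary: dict = field(default_factory=dict)
    class_order: tuple[str, ...] = CLASS_ORDER

    @property
    def base_estimator(self):
        """The uncalibrated final estimator (fitted on all training rows)."""
        return self.estimator.calibrated_classifiers_[0].estimator

    def _proba(self, X_transformed: pd.DataFrame | np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X_transformed, dtype=float))
        # map sklearn's lexical class order back to (benign, VUS, pathogenic)
        cols = {cls: i for i, cls in enumerate(self.estimator.classes_)}
        proba = proba[:, [cols[c] for c in self.class_order]]
        return proba / proba.sum(axis=1, keepdims=True)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Calibrated (benign, VUS, pathogenic) probabilities from raw features."""
        return self._proba(self.transformer.transform(features[self.feature_names]))

    def predict(self, features: pd.DataFrame) -> list[PredictionResult]:
        proba = self.predict_proba(features)
        results = []
        for rid, p in zip(features.index, proba):
            results.append(
                PredictionResult(str(rid), float(p[0]), float(p[1]), float(p[2]),
                                 label_from_probabilities(p))
            )
        return results

    # -- persistence ----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a model bundle: JSON metadata + transformer + pickled estimator."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "cnv_type": self.cnv_type,
            "architecture": self.architecture,
            "hyperparameters": self.hyperparameters,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "cv_summary": self.cv_summary,
            "class_order": list(self.class_order),
            "transformer": self.transformer.to_dict(),
        }
        with open(directory / "model.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(directory / "estimator.pkl", "wb") as fh:
            pickle.dump(self.estimator, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        with open(directory / "model.json") as fh:
            meta = json.load(fh)
        with open(directory / "estimator.pkl", "rb") as fh:
            estimator = pickle.load(fh)
        return cls(
            cnv_type=meta["cnv_type"],
            architecture=meta["architecture"],
            hyperparameters=meta["hyperparameters"],
            transformer=FeatureTransformer.from_dict(meta["transformer"]),
            estimator=estimator,
            feature_names=meta["feature_names"],
            seed=meta["seed"],
            cv_summary=meta["cv_summary"],
            class_order=tuple(meta["class_order"]),
        )


def calibrate_and_fit(
    X: pd.DataFrame,
    y: Sequence[str],
    cnv_type: str,
    architecture: str,
    hyperparameters: Mapping | None = None,
    transformer: FeatureTransformer | None = None,
    k: int = 5,
    seed: int = 0,
    cv_summary: Mapping | None = None,
) -> TrainedModel:
    """Fit the final estimator and isotonic calibration on training rows.

    ``X`` holds raw (untransformed) features; the transformer is fitted here
    on exactly these rows. Calibration uses out-of-fold predictions from a
    stratified k-fold split (``ensemble=False``), i.e. one final estimator
    fitted on all rows with per-class isotonic maps learned out-of-fold.
    """
    y = np.asarray(y)
    _check_class_counts(y, k)
    transformer = transformer or FeatureTransformer()
    Xt = transformer.fit_transform(X)
    base = make_estimator(architecture, seed, dict(hyperparameters or {}))
    calibrated = CalibratedClassifierCV(base, method="isotonic", cv=_cv(k, seed), ensemble=False)
    calibrated.fit(np.asarray(Xt, dtype=float), y)
    return TrainedModel(
        cnv_type=cnv_type,
        architecture=architecture,
        hyperparameters=dict(hyperparameters or {}),
        transformer=transformer,
        estimator=calibrated,
        feature_names=list(X.columns),
        seed=seed,
        cv_summary=dict(cv_summary or {}),
    )


def train_model(
    X: pd.DataFrame,
    y: Sequence[str],
    cnv_type: str,
    roster: Sequence[str] = DEFAULT_ROSTER,
    k: int = 5,
    n_draws: int = 50,
    seed: int = 0,
    spaces: Mapping[str, Mapping] | None = None,
) -> TrainedModel:
    """Full training protocol: architecture selection, tuning, calibration.

    All three stages share the transformed training matrix; the transformer
    is fitted on the same rows as the estimator.
    """
    y = np.asarray(y)
    transformer = FeatureTransformer()
    Xt = transformer.fit_transform(X)
    ranking = select_architecture(np.asarray(Xt), y, roster=roster, k=k, seed=seed)
    best_arch = ranking[0][0]
    space = (spaces or load_hyperparameter_spaces()).get(best_arch, {})
    params, tuned_score = tune_hyperparameters(
        np.asarray(Xt), y, best_arch, n_draws=n_draws, space=space, k=k, seed=seed
    )
    cv_summary = {
        "architecture_ranking": [[name, score] for name, score in ranking],
        "tuned_macro_f1": tuned_score,
        "n_draws": n_draws,
        "folds": k,
    }
    return calibrate_and_fit(
        X, y, cnv_type, best_arch, params, transformer=transformer, k=k, seed=seed,
        cv_summary=cv_summary,
    )
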