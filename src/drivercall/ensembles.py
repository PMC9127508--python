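"""Ensemble classifiers for heavily imbalanced driver-gene labels.

Each base estimator trains on a class-balanced bootstrap: the majority
classes are under-sampled to the minority class count, with replacement
within each class, independently per estimator. Three variants are
provided — bagged trees, a balanced random forest (per-tree feature
subsampling), and an easy ensemble of boosted stumps — all exposing the
scikit-learn estimator API so they drop into grid-search tooling.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

ALGORITHMS = ("balanced_bagging", "balanced_random_forest", "easy_ensemble")


def balanced_bootstrap(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced bootstrap of ``labels``.

    Every class present in ``labels`` contributes exactly ``m`` draws with
    replacement from its own members, where ``m`` is the minority class
    count. Order is deterministic given the generator state.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    m = int(counts.min())
    parts = []
    for cls in classes:
        members = np.flatnonzero(labels == cls)
        parts.append(rng.choice(members, size=m, replace=True))
    return np.concatenate(parts)


class _BalancedEnsemble(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the three balanced ensembles."""

    def __init__(self, n_estimators=50, max_depth=None, min_samples_leaf=1, random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _base_estimator(self, seed: int):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31 - 1, size=self.n_estimators)
        self.estimators_ = []
        self.estimators_samples_ = []
        for seed in seeds:
            idx = balanced_bootstrap(y, np.random.default_rng(int(seed)))
            est = self._base_estimator(int(seed))
            est.fit(X[idx], y[idx])
            self.estimators_.append(est)
            self.estimators_samples_.append(idx)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for est in self.estimators_:
            p = est.predict_proba(X)
            cols = {c: i for i, c in enumerate(est.classes_)}
            for j, c in enumerate(self.classes_):
                if c in cols:
                    proba[:, j] += p[:, cols[c]]
        proba /= len(self.estimators_)
        return proba

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def feature_importances_(self) -> np.ndarray:
        imps = np.mean([est.feature_importances_ for est in self.estimators_], axis=0)
        total = imps.sum()
        return imps / total if total > 0 else imps


class BalancedBaggingClassifier(_BalancedEnsemble):
    """Bagged decision trees, one balanced bootstrap per tree."""

    def _base_estimator(self, seed: int):
        return DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=seed,
        )


class BalancedRandomForestClassifier(_BalancedEnsemble):
    """Random forest whose per-tree bootstraps are class-balanced."""

    def _base_estimator(self, seed: int):
        return DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            max_features="sqrt",
            random_state=seed,
        )


class EasyEnsembleClassifier(_BalancedEnsemble):
    """Ensemble of AdaBoost learners, each on its own balanced resample."""

    def _base_estimator(self, seed: int):
        stump_depth = 1 if self.max_depth is None else min(self.max_depth, 2)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=stump_depth, min_samples_leaf=self.min_samples_leaf
            ),
            n_estimators=10,
            random_state=seed,
        )


def make_classifier(algorithm: str, **params) -> _BalancedEnsemble:
    if algorithm == "balanced_bagging":
        return BalancedBaggingClassifier(**params)
    if algorithm == "balanced_random_forest":
        return BalancedRandomForestClassifier(**params)
    if algorithm == "easy_ensemble":
        return EasyEnsembleClassifier(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
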