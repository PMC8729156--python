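"""Imbalance-aware classifiers behind a single sklearn-style surface.

The workhorse is ``BalancedBaggedTrees``: a bagging ensemble in which every
member tree is trained on an independent balanced resample (bootstrap of the
minority class plus an equal-size undersample of the majority class). This
is the balanced-random-forest idea, implemented here directly on top of
scikit-learn decision trees. ``EasyEnsemble`` bags AdaBoost members the same
way. Gradient boosting (XGBoost, CatBoost) has no internal balancing; the
evaluation engine undersamples its training sets instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

#: Algorithms with internal per-member balancing (no external undersampling
#: needed before fit).
BALANCED_ALGORITHMS = {"balanced-bagged-trees", "balanced-random-forest", "easy-ensemble"}
ALGORITHMS = BALANCED_ALGORITHMS | {"gradient-boosting-xgb", "gradient-boosting-cat"}


@dataclass(frozen=True)
class ClassifierSpec:
    """Named algorithm plus a hyperparameter grid (name -> candidate values).

    Grid configurations are enumerated in insertion order with the last
    parameter varying fastest; ties in model selection resolve to the
    earliest configuration.
    """

    algorithm: str
    grid: Mapping[str, Sequence[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {sorted(ALGORITHMS)}")

    @property
    def handles_imbalance_internally(self) -> bool:
        return self.algorithm in BALANCED_ALGORITHMS

    def configurations(self) -> list[dict[str, Any]]:
        if not self.grid:
            return [{}]
        names = list(self.grid)
        return [dict(zip(names, combo)) for combo in itertools.product(*(self.grid[n] for n in names))]


class _BalancedBagging(BaseEstimator, ClassifierMixin):
    """Bagging where each member sees an independent balanced resample."""

    def __init__(self, base_estimator=None, n_estimators: int = 100, random_state: int | None = None):
        self.base_estimator = base_estimator
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _make_member(self, seed: int):
        member = clone(self.base_estimator)
        if "random_state" in member.get_params():
            member.set_params(random_state=seed)
        return member

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        counts = np.bincount(y_enc)
        minority = int(np.argmin(counts))
        min_idx = np.flatnonzero(y_enc == minority)
        maj_idx = np.flatnonzero(y_enc != minority)
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            boot_min = rng.choice(min_idx, size=len(min_idx), replace=True)
            sub_maj = rng.choice(maj_idx, size=min(len(min_idx), len(maj_idx)), replace=False)
            idx = np.concatenate([boot_min, sub_maj])
            member = self._make_member(int(rng.integers(0, 2**31 - 1)))
            member.fit(X[idx], y_enc[idx])
            self.estimators_.append(member)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        probs = np.zeros((X.shape[0], 2))
        for member in self.estimators_:
            p = member.predict_proba(X)
            # members may have seen a single class in tiny resamples
            for k, cls in enumerate(member.classes_):
                probs[:, cls] += p[:, k]
        return probs / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    @property
    def feature_importances_(self):
        imps = [m.feature_importances_ for m in self.estimators_ if hasattr(m, "feature_importances_")]
        if not imps:
            raise AttributeError("members expose no impurity importances")
        return np.mean(imps, axis=0)


def make_classifier(spec: ClassifierSpec, params: Mapping[str, Any], seed: int):
    """Instantiate an unfitted estimator for one grid configuration."""
    params = dict(params)
    algo = spec.algorithm
    if algo in {"balanced-bagged-trees", "balanced-random-forest"}:
        n_estimators = params.pop("n_estimators", 100)
        tree = DecisionTreeClassifier(max_features="sqrt", **params)
        return _BalancedBagging(base_estimator=tree, n_estimators=n_estimators, random_state=seed)
    if algo == "easy-ensemble":
        n_estimators = params.pop("n_estimators", 10)
        base = AdaBoostClassifier(**params)
        return _BalancedBagging(base_estimator=base, n_estimators=n_estimators, random_state=seed)
    if algo == "gradient-boosting-xgb":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:  # pragma: no cover
            raise ImportError("install the 'boost' extra for XGBoost support") from exc
        defaults = dict(n_estimators=100, eval_metric="logloss", verbosity=0)
        defaults.update(params)
        return XGBClassifier(random_state=seed, **defaults)
    if algo == "gradient-boosting-cat":
        try:
            from catboost import CatBoostClassifier
        except ImportError as exc:  # pragma: no cover
            raise ImportError("CatBoost is not installed") from exc
        defaults = dict(verbose=0)
        defaults.update(params)
        return CatBoostClassifier(random_state=seed, **defaults)
    raise ValueError(f"unknown algorithm {algo!r}")  # pragma: no cover
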