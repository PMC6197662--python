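"""Learner presets behind a uniform train/predict contract.

K-nearest-neighbour prediction is implemented natively so its behaviour —
including distance and vote tie-breaking — is fully deterministic and can be
verified against a brute-force oracle. The remaining learners (linear SVM,
random forest, AdaBoost over regression trees, Gaussian naive Bayes) are
configured scikit-learn estimators behind the same surface.

Preset hyperparameters: 1-NN for halo classification and 5-NN for activity
regression (uniform weights, Euclidean distance); linear-kernel SVM; a
30-tree random forest classifier deciding by majority vote over the
individual trees; a 10-tree random forest regressor with unlimited depth and
all features considered at each split; AdaBoost fusing 50 regression trees
with at least 2 instances per leaf, 5 per internal node, maximum depth 100.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.ensemble import (
    AdaBoostRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import ModelError, NotFittedError, ParameterError

CLASSIFIER_FAMILIES = frozenset(
    {"knn_classifier", "svm_classifier", "random_forest_classifier", "naive_bayes"}
)
REGRESSOR_FAMILIES = frozenset(
    {"knn_regressor", "svm_regressor", "random_forest_regressor", "adaboost_regressor"}
)

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """One learner family plus its complete hyperparameter set."""

    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int | None = None
    standardize: bool = False

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES | REGRESSOR_FAMILIES:
            raise ParameterError(f"unknown model family {self.family!r}")

    @property
    def is_classifier(self) -> bool:
        return self.family in CLASSIFIER_FAMILIES

    def with_seed(self, seed: int | None) -> "ModelConfig":
        return ModelConfig(self.family, dict(self.hyperparameters), seed,
                           self.standardize)


def paper_presets() -> dict[str, ModelConfig]:
    """The study's learner configurations, keyed by short preset name."""
    return {
        "knn_classifier": ModelConfig(
            "knn_classifier", {"n_neighbors": 1, "weights": "uniform",
                               "metric": "euclidean"}),
        "knn_regressor": ModelConfig(
            "knn_regressor", {"n_neighbors": 5, "weights": "uniform",
                              "metric": "euclidean"}),
        "svm_classifier": ModelConfig(
            "svm_classifier", {"kernel": "linear", "C": 1.0, "probability": True}),
        "svm_regressor": ModelConfig(
            "svm_regressor", {"kernel": "linear", "C": 1.0, "epsilon": 0.1}),
        "rf_classifier": ModelConfig(
            "random_forest_classifier", {"n_estimators": 30}),
        "rf_regressor": ModelConfig(
            "random_forest_regressor",
            {"n_estimators": 10, "max_depth": None, "max_features": None}),
        "adaboost_regressor": ModelConfig(
            "adaboost_regressor",
            {"n_estimators": 50, "min_samples_leaf": 2, "min_samples_split": 5,
             "max_depth": 100}),
        "naive_bayes": ModelConfig("naive_bayes", {}),
    }


class _KNNBase(BaseEstimator):
    """Shared machinery: exact Euclidean neighbours with index tie-breaking.

    Among equidistant training points, the one with the smaller training-row
    index ranks first; this makes every prediction deterministic.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ParameterError("X must be 2-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ParameterError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries")
        if X.shape[0] == 0:
            raise ModelError("cannot fit a nearest-neighbour model on zero rows")
        if self.n_neighbors > X.shape[0]:
            raise ParameterError(
                f"n_neighbors={self.n_neighbors} exceeds n_train={X.shape[0]}")
        self.X_, self.y_ = X, y
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "X_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")

    def _neighbor_order(self, x: np.ndarray) -> np.ndarray:
        d = np.sqrt(((self.X_ - x) ** 2).sum(axis=1))
        return np.argsort(d, kind="stable")  # stable sort: ties by row index

    def _kneighbors(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ParameterError(
                f"query has {X.shape[1]} features, model has {self.n_features_in_}")
        return np.vstack([self._neighbor_order(x)[: self.n_neighbors] for x in X])


class KNNRegressor(RegressorMixin, _KNNBase):
    """Exact K-nearest-neighbour regression: unweighted mean of the K
    nearest targets under Euclidean distance."""

    def predict(self, X) -> np.ndarray:
        nn = self._kneighbors(X)
        return np.asarray(self.y_, float)[nn].mean(axis=1)


class KNNClassifier(ClassifierMixin, _KNNBase):
    """Exact K-nearest-neighbour classification by majority vote.

    A vote tie is broken in favour of the tied class whose member appears
    first in the neighbour ranking (i.e. the class of the nearest neighbour
    among the tied classes).
    """

    def fit(self, X, y):
        super().fit(X, y)
        self.classes_ = np.unique(self.y_)
        return self

    def _vote(self, ranked: np.ndarray) -> Any:
        labels = self.y_[ranked]
        uniq, counts = np.unique(labels, return_counts=True)
        top = counts.max()
        tied = set(uniq[counts == top])
        if len(tied) == 1:
            return tied.pop()
        for lab in labels:  # neighbour order: nearest tied class wins
            if lab in tied:
                return lab
        raise ModelError("unreachable: no tied class found")  # pragma: no cover

    def predict(self, X) -> np.ndarray:
        nn = self._kneighbors(X)
        return np.array([self._vote(row) for row in nn])

    def predict_proba(self, X) -> np.ndarray:
        """Per-class neighbour-vote fractions (rows sum to 1)."""
        nn = self._kneighbors(X)
        out = np.zeros((nn.shape[0], len(self.classes_)))
        class_pos = {c: j for j, c in enumerate(self.classes_)}
        for i, row in enumerate(nn):
            for lab in self.y_[row]:
                out[i, class_pos[lab]] += 1
        return out / self.n_neighbors


class VotingForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest deciding by hard majority vote over its trees.

    scikit-learn's forest averages per-tree class probabilities; here the
    target class is the one most trees predict, and ``predict_proba`` returns
    the per-class vote fractions (used as ranking scores for AUC). Vote ties
    go to the earlier class in sorted label order.
    """

    def __init__(self, n_estimators: int = 30, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        return self

    def _vote_fractions(self, X) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise NotFittedError("VotingForestClassifier is not fitted")
        X = np.asarray(X, float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.forest_.estimators_:
            pred = tree.predict(X).astype(int)  # tree predicts class indices
            votes[np.arange(X.shape[0]), pred] += 1
        return votes / self.n_estimators

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._vote_fractions(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        return self._vote_fractions(X)


def build_estimator(config: ModelConfig) -> BaseEstimator:
    """Instantiate the (unfitted) estimator a config describes."""
    hp = dict(config.hyperparameters)
    fam = config.family
    if fam == "knn_classifier":
        est = KNNClassifier(n_neighbors=hp.get("n_neighbors", 1))
    elif fam == "knn_regressor":
        est = KNNRegressor(n_neighbors=hp.get("n_neighbors", 5))
    elif fam == "svm_classifier":
        est = SVC(kernel=hp.get("kernel", "linear"), C=hp.get("C", 1.0),
                  probability=hp.get("probability", True),
                  random_state=config.seed)
    elif fam == "svm_regressor":
        est = SVR(kernel=hp.get("kernel", "linear"), C=hp.get("C", 1.0),
                  epsilon=hp.get("epsilon", 0.1))
    elif fam == "random_forest_classifier":
        est = VotingForestClassifier(n_estimators=hp.get("n_estimators", 30),
                                     random_state=config.seed)
    elif fam == "random_forest_regressor":
        est = RandomForestRegressor(n_estimators=hp.get("n_estimators", 10),
                                    max_depth=hp.get("max_depth"),
                                    max_features=hp.get("max_features"),
                                    random_state=config.seed)
    elif fam == "adaboost_regressor":
        base = DecisionTreeRegressor(
            max_depth=hp.get("max_depth", 100),
            min_samples_leaf=hp.get("min_samples_leaf", 2),
            min_samples_split=hp.get("min_samples_split", 5),
            random_state=config.seed,
        )
        est = AdaBoostRegressor(estimator=base,
                                n_estimators=hp.get("n_estimators", 50),
                                random_state=config.seed)
    elif fam == "naive_bayes":
        est = GaussianNB()
    else:  # pragma: no cover - guarded by ModelConfig validation
        raise ParameterError(f"unknown family {fam!r}")
    if config.standardize:
        est = Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


@dataclass
class FittedModel:
    """A fitted estimator together with its config and training summary."""

    config: ModelConfig
    estimator: BaseEstimator
    n_samples: int
    n_features: int


@dataclass
class Prediction:
    """Predicted values; classifiers also carry per-class ranking scores."""

    values: np.ndarray
    classes: np.ndarray | None = None
    scores: np.ndarray | None = None


def fit(config: ModelConfig, X, y) -> FittedModel:
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ParameterError(
            f"inconsistent shapes: X {X.shape}, y {y.shape}")
    if np.isnan(X).any() or (y.dtype.kind == "f" and np.isnan(y.astype(float)).any()):
        raise ParameterError("missing values are not supported")
    est = build_estimator(config).fit(X, y)
    return FittedModel(config=config, estimator=est,
                       n_samples=X.shape[0], n_features=X.shape[1])


def predict(model: FittedModel, X) -> Prediction:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_features:
        raise ParameterError(
            f"query has {X.shape[1]} features, model was fitted on "
            f"{model.n_features}")
    est = model.estimator
    values = est.predict(X)
    if model.config.is_classifier:
        inner = est[-1] if isinstance(est, Pipeline) else est
        classes = inner.classes_
        if hasattr(est, "predict_proba"):
            scores = est.predict_proba(X)
        else:  # hard one-hot fallback
            scores = (values[:, None] == classes[None, :]).astype(float)
        return Prediction(values=values, classes=classes, scores=scores)
    return Prediction(values=np.asarray(values, float))


def knn_predict(train_X, train_y, query_x, k: int, task: str = "regress"):
    """Functional one-shot KNN: fit on (train_X, train_y), predict query_x.

    ``task`` is "regress" (mean of the K nearest targets) or "classify"
    (majority vote). Returns a scalar for a single query row.
    """
    if task not in ("regress", "classify"):
        raise ParameterError(f"task must be 'regress' or 'classify', got {task!r}")
    cls = KNNRegressor if task == "regress" else KNNClassifier
    est = cls(n_neighbors=k).fit(train_X, train_y)
    query = np.atleast_2d(np.asarray(query_x, float))
    out = est.predict(query)
    return out[0] if np.asarray(query_x).ndim == 1 else out


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model with a format version and its config echo."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "config": asdict(model.config),
        "n_samples": model.n_samples,
        "n_features": model.n_features,
        "estimator": model.estimator,
    }
    with Path(path).open("wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> FittedModel:
    with Path(path).open("rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ModelError(f"unsupported model format version {version!r}")
    cfg = payload["config"]
    config = ModelConfig(cfg["family"], cfg["hyperparameters"], cfg["seed"],
                         cfg.get("standardize", False))
    return FittedModel(config=config, estimator=payload["estimator"],
                       n_samples=payload["n_samples"],
                       n_features=payload["n_features"])


def config_to_json(config: ModelConfig) -> str:
    return json.dumps(asdict(config), sort_keys=True)
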