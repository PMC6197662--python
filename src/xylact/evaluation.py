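"""Cross-validation schemes and metric suites.

Two validation schemes are supported: stratified 10-fold cross-validation
(regression targets are continuous, so their k-fold splits are unstratified)
and the jackknife (leave-one-out). Metrics are always computed ONCE on the
pooled out-of-fold predictions, never averaged across folds; this is why a
leave-one-out regression can legitimately report a negative R^2 — each
held-out prediction is made without the held-out point, so pooled squared
error can exceed the total variance of the observed targets.

Classifier metrics: classification accuracy (CA), and support-weighted
precision / recall / F1 plus prevalence-weighted one-vs-rest ROC AUC for the
multiclass halo problem. Regression metrics: MSE, RMSE, MAE and
R^2 = 1 - SSE/SStot with SStot taken about the mean of the pooled true
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold

from .dataio import CONDITIONS, StudyDataset
from .errors import AlignmentError, ModelError, ParameterError
from .models import ModelConfig, Prediction, fit, paper_presets, predict


@dataclass(frozen=True)
class ValidationScheme:
    """How out-of-sample predictions are generated.

    kind : "stratified_kfold" or "jackknife"
    k : number of folds (ignored for the jackknife, where k = n)
    seed : shuffle seed for the k-fold split (the jackknife has no randomness)
    """

    kind: str = "stratified_kfold"
    k: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("stratified_kfold", "jackknife"):
            raise ParameterError(f"unknown scheme kind {self.kind!r}")


JACKKNIFE = ValidationScheme(kind="jackknife")


def make_folds(labels_or_n, scheme: ValidationScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition sample indices into (train, test) folds.

    ``labels_or_n`` is either an integer sample count (regression: plain
    shuffled k-fold) or a label vector (classification: stratified k-fold,
    every fold's class counts within one sample of proportionality). The
    jackknife returns n singleton test folds in index order.
    """
    if np.isscalar(labels_or_n):
        n, labels = int(labels_or_n), None
    else:
        labels = np.asarray(labels_or_n)
        n = len(labels)
    if scheme.kind == "jackknife":
        return [(tr, te) for tr, te in LeaveOneOut().split(np.empty((n, 1)))]
    if scheme.k > n:
        raise ParameterError(f"k={scheme.k} folds exceed n={n} samples")
    if labels is None:
        splitter = KFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        return list(splitter.split(np.empty((n, 1))))
    splitter = StratifiedKFold(n_splits=scheme.k, shuffle=True,
                               random_state=scheme.seed)
    return list(splitter.split(np.empty((n, 1)), labels))


def classification_metrics(
    y_true, y_pred, scores=None, classes=None
) -> dict[str, float]:
    """CA plus support-weighted F1/precision/recall and weighted OvR AUC.

    ``scores`` (n x n_classes, rows summing to 1) and ``classes`` (the column
    order of ``scores``) are required for AUC; without them AUC is omitted.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ParameterError("true/predicted vectors are not aligned")
    out = {
        "CA": float(skm.accuracy_score(y_true, y_pred)),
        "F1": float(skm.f1_score(y_true, y_pred, average="weighted",
                                 zero_division=0)),
        "precision": float(skm.precision_score(y_true, y_pred,
                                               average="weighted",
                                               zero_division=0)),
        "recall": float(skm.recall_score(y_true, y_pred, average="weighted",
                                         zero_division=0)),
    }
    if scores is not None:
        scores = np.asarray(scores, float)
        if classes is None:
            raise ModelError("scores supplied without their class order")
        classes = np.asarray(classes)
        present = np.unique(y_true)
        if not set(present) <= set(classes):
            raise ModelError(
                f"classes {sorted(set(present) - set(classes))} missing from scores")
        if len(present) < 2:
            raise ModelError("AUC undefined with a single observed class")
        # restrict score columns to the observed classes, in their order
        cols = [int(np.where(classes == c)[0][0]) for c in present]
        sub = scores[:, cols]
        if len(present) == 2:
            auc = skm.roc_auc_score((y_true == present[1]).astype(int), sub[:, 1])
        else:
            auc = skm.roc_auc_score(y_true, sub, multi_class="ovr",
                                    average="weighted", labels=present)
        out["AUC"] = float(auc)
    return out


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """MSE, RMSE, MAE and R^2 on pooled predictions.

    R^2 uses the mean of the pooled true values and may be negative. A
    zero-variance target leaves R^2 undefined and raises.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ParameterError("true/predicted vectors are not aligned")
    if y_true.size < 2:
        raise ParameterError("need at least two samples for regression metrics")
    if np.var(y_true) == 0:
        raise ModelError("R^2 undefined: true values have zero variance")
    mse = float(skm.mean_squared_error(y_true, y_pred))
    return {
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "MAE": float(skm.mean_absolute_error(y_true, y_pred)),
        "R2": float(skm.r2_score(y_true, y_pred)),
    }


@dataclass
class EvaluationReport:
    """Pooled out-of-fold predictions and the metric suite for one scheme."""

    scheme: ValidationScheme
    config: ModelConfig
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray | None
    classes: np.ndarray | None
    metrics: dict[str, float]
    context: dict[str, Any] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"true": self.y_true, "predicted": self.y_pred})


def cross_validate(
    X, y, config: ModelConfig, scheme: ValidationScheme
) -> EvaluationReport:
    """Out-of-fold evaluation of one learner under one validation scheme.

    Each fold's model is fitted on the training part only; the pooled
    held-out predictions (exactly one per sample) feed the metric suite.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    folds = make_folds(y if config.is_classifier else len(y), scheme)
    y_pred = np.empty(len(y), dtype=y.dtype if config.is_classifier else float)
    all_classes = np.unique(y) if config.is_classifier else None
    scores = (np.zeros((len(y), len(all_classes)))
              if config.is_classifier else None)
    seen = np.zeros(len(y), bool)
    for fold_no, (tr, te) in enumerate(folds):
        try:
            model = fit(config, X[tr], y[tr])
            pred: Prediction = predict(model, X[te])
        except Exception as exc:
            raise ModelError(f"fold {fold_no}: {exc}") from exc
        y_pred[te] = pred.values
        if scores is not None:
            # map fold-local class columns onto the global class order
            for j, c in enumerate(pred.classes):
                col = int(np.where(all_classes == c)[0][0])
                scores[te, col] = pred.scores[:, j]
        seen[te] = True
    if not seen.all():
        raise ModelError("some samples received no out-of-fold prediction")
    if config.is_classifier:
        metrics = classification_metrics(y, y_pred, scores, all_classes)
    else:
        metrics = regression_metrics(y, y_pred)
    return EvaluationReport(scheme=scheme, config=config, y_true=y,
                            y_pred=y_pred, scores=scores, classes=all_classes,
                            metrics=metrics)


# ---------------------------------------------------------------------------
# Study-table reproduction

_CLASSIFIER_ROWS = ("rf_classifier", "svm_classifier", "knn_classifier",
                    "naive_bayes")
_REGRESSOR_ROWS = ("svm_regressor", "knn_regressor", "adaboost_regressor",
                   "rf_regressor")
_CLS_METRICS = ("AUC", "CA", "F1", "precision", "recall")
_REG_METRICS = ("MSE", "RMSE", "MAE", "R2")


@dataclass
class TableReproduction:
    """Rendered analogues of the study's classification/regression tables.

    ``classification`` has one row per (model, scheme); ``regression`` one
    row per (condition, model, scheme). The ``exact`` column flags the cells
    that are deterministic reproductions (native KNN under the jackknife,
    where no seed or unstated hyperparameter can move the value); all other
    cells are approximate, since the original seeds and several
    hyperparameters are unstated.
    """

    classification: pd.DataFrame
    regression: pd.DataFrame
    seed: int
    feature_source: str

    def to_text(self) -> str:
        header = (f"# halo classification and activity regression report\n"
                  f"# seed={self.seed} feature_source={self.feature_source}\n")
        return (header
                + "\n== classification (41 strains, halo class) ==\n"
                + self.classification.to_string(index=False, float_format="%.3f")
                + "\n\n== regression (28 assayed strains, IU/ml) ==\n"
                + self.regression.to_string(index=False, float_format="%.3f")
                + "\n")


def _schemes(seed: int) -> dict[str, ValidationScheme]:
    return {
        "10fold": ValidationScheme("stratified_kfold", 10, seed),
        "jackknife": JACKKNIFE,
    }


def reproduce_tables(
    dataset: StudyDataset, features: pd.DataFrame | None = None, seed: int = 0,
    feature_source: str = "unspecified",
) -> TableReproduction:
    """Run every preset under both validation schemes on the study layout.

    ``features`` rows must be indexed by accession and cover every record;
    classification uses all strains and the printed halo classes, regression
    the assayed subset per condition. KNN jackknife cells are flagged exact;
    everything else approximate.
    """
    if features is not None:
        dataset = StudyDataset(records=dataset.records, features=features)
    if dataset.features is None:
        raise AlignmentError("a feature matrix is required")
    presets = paper_presets()
    X_all = np.asarray(dataset.aligned_features(), float)
    y_class = dataset.classes()
    cls_rows = []
    for name in _CLASSIFIER_ROWS:
        for scheme_name, scheme in _schemes(seed).items():
            cfg = presets[name].with_seed(seed)
            rep = cross_validate(X_all, y_class, cfg, scheme)
            exact = name == "knn_classifier" and scheme_name == "jackknife"
            cls_rows.append({"model": name, "scheme": scheme_name,
                             **{m: rep.metrics.get(m, np.nan) for m in _CLS_METRICS},
                             "exact": exact})
    assayed = dataset.assayed
    X_assay = np.asarray(dataset.aligned_features(assayed), float)
    reg_rows = []
    for cond in CONDITIONS:
        y = np.array([r.activity[cond] for r in assayed], float)
        for name in _REGRESSOR_ROWS:
            for scheme_name, scheme in _schemes(seed).items():
                cfg = presets[name].with_seed(seed)
                rep = cross_validate(X_assay, y, cfg, scheme)
                exact = name == "knn_regressor" and scheme_name == "jackknife"
                reg_rows.append({"condition": cond, "model": name,
                                 "scheme": scheme_name,
                                 **{m: rep.metrics[m] for m in _REG_METRICS},
                                 "exact": exact})
    return TableReproduction(
        classification=pd.DataFrame(cls_rows),
        regression=pd.DataFrame(reg_rows),
        seed=seed, feature_source=feature_source,
    )
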