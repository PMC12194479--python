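"""Spectral-descriptor activity models (regression and classification).

The modelling surface follows the Model/Results idiom: :class:`QSDARModel`
is built from a feature matrix and targets (or from a DataFrame), ``fit()``
returns a :class:`QSDARResults` carrying the fitted estimator, evaluation
metrics and a ``summary()`` table, and cross-validation / feature selection
hang off those objects.

Evaluation metrics (confusion-matrix statistics, R²/MAE/RMSE, rank-based ROC
AUC) are implemented here from their definitions rather than delegated, so
they can be cross-checked against independent library implementations in the
test suite.

Supported algorithms and their defaults:

====  ==============  =======================================================
algo  backend          defaults
====  ==============  =======================================================
rf    scikit-learn     1000 trees (regression and classification); OOB
                       estimation available
gbm   LightGBM         500 trees for regression, 1000 for classification
svm   scikit-learn     RBF kernel; epsilon-SVR for regression, probability-
                       enabled SVC for classification; C tunable
mlp   scikit-learn     4 hidden layers x 150 rectified-linear units, batch
                       128, Adam, 500 epochs
====  ==============  =======================================================
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np


@contextlib.contextmanager
def _quiet_feature_names():
    # LightGBM's sklearn wrapper warns about feature names when fitted and
    # queried with plain arrays; the package API is array-based throughout.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names")
        yield

__all__ = [
    "ModelConfig",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "RegressionMetrics",
    "ModelReport",
    "QSDARModel",
    "QSDARResults",
    "select_top_k",
    "fit_model",
    "cross_val_predictions",
    "cross_validate",
    "confusion_metrics",
    "regression_metrics",
    "roc_auc",
    "roc_curve_points",
]

_DEFAULT_TREES = {("rf", "regression"): 1000, ("rf", "classification"): 1000,
                  ("gbm", "regression"): 500, ("gbm", "classification"): 1000}


@dataclass(frozen=True)
class ModelConfig:
    """Algorithm + task + hyperparameters for one model."""

    algo: str = "gbm"  # rf | gbm | svm | mlp
    task: str = "classification"  # regression | classification
    n_trees: int | None = None  # None -> per-algo default
    tuned_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algo not in ("rf", "gbm", "svm", "mlp"):
            raise ValueError(f"unknown algo: {self.algo!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task: {self.task!r}")

    @property
    def effective_n_trees(self) -> int | None:
        if self.n_trees is not None:
            return self.n_trees
        return _DEFAULT_TREES.get((self.algo, self.task))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        t = np.asarray(y_true) == positive
        p = np.asarray(y_pred) == positive
        return cls(tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
                   fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)))


@dataclass(frozen=True)
class ClassificationMetrics:
    se: float  # sensitivity tp/(tp+fn)
    sp: float  # specificity tn/(tn+fp)
    q: float   # overall accuracy
    mcc: float
    auc: float | None = None


@dataclass(frozen=True)
class RegressionMetrics:
    r2: float | None  # None when the target is constant (undefined)
    mae: float
    rmse: float

    @property
    def r2_defined(self) -> bool:
        return self.r2 is not None


@dataclass(frozen=True)
class ModelReport:
    config: ModelConfig
    scheme: str  # oob | cv10 | external_test | training
    n: int
    metrics: ClassificationMetrics | RegressionMetrics
    confusion: ConfusionMatrix | None = None
    selected_feature_indices: tuple[int, ...] | None = None


# ---------------------------------------------------------------------------
# metrics (implemented from their definitions)

def confusion_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Sensitivity, specificity, overall accuracy and Matthews correlation.

    SE = TP/(TP+FN), SP = TN/(TN+FP), Q = (TP+TN)/N and
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero factor in
    the MCC denominator yields MCC = 0 by convention.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = (float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn))
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    q = (tp + tn) / cm.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return ClassificationMetrics(se=se, sp=sp, q=q, mcc=float(mcc))


def regression_metrics(y, yhat) -> RegressionMetrics:
    """R² = 1 − SS_res/SS_tot, mean absolute error, root mean squared error.

    For a constant target R² is undefined and reported as ``None``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y and yhat must be 1-D, equal length >= 2")
    resid = y - yhat
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(y) == 0.0:  # exactly constant target: R² undefined
        return RegressionMetrics(r2=None, mae=mae, rmse=rmse)
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return RegressionMetrics(r2=r2, mae=mae, rmse=rmse)


def roc_auc(scores, labels, positive=1) -> float:
    """Rank-statistic AUC: P(random positive outscores a random negative),
    ties counting one half (midrank / Mann-Whitney formulation)."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)  # average ranks on ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(scores, labels, positive=1):
    """(FPR, TPR) points of the empirical ROC curve, thresholds descending."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / max(int(y.sum()), 1)]
    fpr = np.r_[0.0, fps / max(int((~y).sum()), 1)]
    return fpr, tpr


def select_top_k(importances, k: int) -> np.ndarray:
    """Indices of the k largest importance scores, ties broken by lower index.

    Returned in ascending index order so downstream column slicing is stable.
    """
    imp = np.asarray(importances, dtype=float)
    if imp.ndim != 1:
        raise ValueError("importances must be 1-D")
    if not 1 <= k <= imp.size:
        raise ValueError(f"k must be in [1, {imp.size}], got {k}")
    order = np.argsort(-imp, kind="stable")  # stable: equal scores keep index order
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# estimator construction

def _make_estimator(config: ModelConfig, oob: bool = False):
    algo, task, seed = config.algo, config.task, config.seed
    params = dict(config.tuned_params)
    if algo == "rf":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(n_estimators=config.effective_n_trees, random_state=seed,
                   oob_score=oob, n_jobs=1, **params)
    if algo == "gbm":
        import lightgbm as lgb
        cls = lgb.LGBMRegressor if task == "regression" else lgb.LGBMClassifier
        return cls(n_estimators=config.effective_n_trees, random_state=seed,
                   deterministic=True, force_row_wise=True, n_jobs=1,
                   verbosity=-1, **params)
    if algo == "svm":
        from sklearn.svm import SVC, SVR
        if task == "regression":
            return SVR(kernel="rbf", **params)
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if algo == "mlp":
        from sklearn.neural_network import MLPClassifier, MLPRegressor
        defaults: dict[str, Any] = dict(
            hidden_layer_sizes=(150, 150, 150, 150), activation="relu",
            solver="adam", batch_size=128, max_iter=500, random_state=seed)
        defaults.update(params)
        cls = MLPRegressor if task == "regression" else MLPClassifier
        return cls(**defaults)
    raise ValueError(f"unknown algo: {algo!r}")  # pragma: no cover


def fit_model(X, y, config: ModelConfig):
    """Fit one estimator; returns an object with predict / predict_proba."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs y {y.shape}")
    if np.any(~np.isfinite(X)):
        raise ValueError("feature matrix contains NaN/inf")
    if config.task == "classification" and np.unique(y).size < 2:
        raise ValueError("classification requires at least two classes in y")
    est = _make_estimator(config)
    est.fit(X, y)
    return est


def cross_val_predictions(X, y, config: ModelConfig, scheme: str = "cv10",
                          n_folds: int = 10):
    """Per-row out-of-fold (cv10) or out-of-bag (oob) predictions.

    Returns ``(yhat, scores)``: each row is predicted exactly once by a model
    that never saw it.  ``scores`` is the positive-class probability for
    classification and ``None`` for regression.  OOB is only defined for the
    random forest (the one bagging algorithm here).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if scheme == "oob":
        if config.algo != "rf":
            raise ValueError(f"OOB estimation requires a bagging algo, not {config.algo!r}")
        est = _make_estimator(config, oob=True)
        est.fit(X, y)
        if config.task == "regression":
            return np.asarray(est.oob_prediction_, dtype=float), None
        proba = est.oob_decision_function_
        pos_col = int(np.flatnonzero(est.classes_ == _positive_label(est.classes_))[0])
        return est.classes_[np.argmax(proba, axis=1)], proba[:, pos_col]
    if scheme != "cv10":
        raise ValueError(f"unknown scheme: {scheme!r}")

    from sklearn.model_selection import KFold, StratifiedKFold

    if config.task == "classification":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=config.seed)
        split = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
        split = splitter.split(X)

    yhat = np.empty(n, dtype=y.dtype if config.task == "classification" else float)
    scores = np.empty(n, dtype=float)
    for train_idx, test_idx in split:
        est = fit_model(X[train_idx], y[train_idx], config)
        with _quiet_feature_names():
            yhat[test_idx] = est.predict(X[test_idx])
            if config.task == "classification":
                proba = est.predict_proba(X[test_idx])
                pos_col = int(np.flatnonzero(
                    est.classes_ == _positive_label(est.classes_))[0])
                scores[test_idx] = proba[:, pos_col]
    return yhat, (scores if config.task == "classification" else None)


def cross_validate(X, y, config: ModelConfig, scheme: str = "cv10",
                   n_folds: int = 10) -> ModelReport:
    """Out-of-fold (cv10) or out-of-bag (oob) evaluation report.

    Metrics are computed once on the pooled out-of-fold (or out-of-bag)
    prediction vector; classification folds are stratified.
    """
    y = np.asarray(y)
    yhat, scores = cross_val_predictions(X, y, config, scheme=scheme,
                                         n_folds=n_folds)
    if config.task == "regression":
        return ModelReport(config, scheme, len(y), regression_metrics(y, yhat))
    return _classification_report(config, scheme, y, yhat, scores)


def _positive_label(classes):
    """'active' when present, else the larger label: the screening positive."""
    classes = list(classes)
    if "active" in classes:
        return "active"
    return sorted(classes)[-1]


def _classification_report(config, scheme, y, yhat, scores) -> ModelReport:
    pos = _positive_label(np.unique(y))
    cm = ConfusionMatrix.from_predictions(y, yhat, positive=pos)
    m = confusion_metrics(cm)
    auc = roc_auc(scores, y, positive=pos)
    return ModelReport(config, scheme, len(np.asarray(y)),
                       ClassificationMetrics(m.se, m.sp, m.q, m.mcc, auc=auc),
                       confusion=cm)


# ---------------------------------------------------------------------------
# Model / Results objects

class QSDARModel:
    """A spectral-descriptor (or any feature-matrix) activity model.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix (spectral codes, fingerprints or descriptor blocks).
    y : (n,) array
        pIC50 values (regression) or class labels (classification).
    config : ModelConfig
    feature_names, ids : optional column / row labels carried into reports.
    """

    def __init__(self, X, y, config: ModelConfig | None = None,
                 feature_names=None, ids=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.config = config or ModelConfig()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"shape mismatch: X {self.X.shape} vs y {self.y.shape}")
        self.feature_names = (tuple(feature_names) if feature_names is not None
                              else tuple(f"x{i}" for i in range(self.X.shape[1])))
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")
        self.ids = tuple(ids) if ids is not None else None

    @classmethod
    def from_dataframe(cls, frame, target: str, config: ModelConfig | None = None,
                       id_column: str = "id"):
        """Build from a DataFrame; all non-target, non-id numeric columns are
        features."""
        cols = [c for c in frame.columns if c not in (target, id_column)]
        ids = frame[id_column].tolist() if id_column in frame.columns else None
        return cls(frame[cols].to_numpy(dtype=float), frame[target].to_numpy(),
                   config=config, feature_names=cols, ids=ids)

    def fit(self) -> "QSDARResults":
        est = fit_model(self.X, self.y, self.config)
        return QSDARResults(self, est)

    def cross_validate(self, scheme: str = "cv10", n_folds: int = 10) -> ModelReport:
        return cross_validate(self.X, self.y, self.config, scheme=scheme,
                              n_folds=n_folds)

    def select_features(self, k: int, selector_config: ModelConfig | None = None):
        """Top-k feature selection by random-forest impurity importance.

        Returns (indices, reduced QSDARModel).  The selector is a random
        forest regardless of the model's own algorithm, mirroring the
        RF-importance-then-train workflow.
        """
        sel_cfg = selector_config or ModelConfig(
            algo="rf", task=self.config.task, n_trees=200, seed=self.config.seed)
        if sel_cfg.algo != "rf":
            raise ValueError("feature selection uses random-forest importances")
        est = fit_model(self.X, self.y, sel_cfg)
        idx = select_top_k(est.feature_importances_, k)
        reduced = QSDARModel(self.X[:, idx], self.y, config=self.config,
                             feature_names=[self.feature_names[i] for i in idx],
                             ids=self.ids)
        return idx, reduced


class QSDARResults:
    """Fitted-model results: predictions, evaluation, summary table."""

    def __init__(self, model: QSDARModel, estimator):
        self.model = model
        self.estimator = estimator
        self._training_report: ModelReport | None = None

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def predict(self, X):
        with _quiet_feature_names():
            return self.estimator.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        if self.config.task != "classification":
            raise ValueError("probabilities are defined for classification only")
        with _quiet_feature_names():
            return self.estimator.predict_proba(np.asarray(X, dtype=float))

    def positive_proba(self, X):
        """Probability of the positive ('active') class."""
        proba = self.predict_proba(X)
        pos = _positive_label(self.estimator.classes_)
        col = int(np.flatnonzero(self.estimator.classes_ == pos)[0])
        return proba[:, col]

    def evaluate(self, X, y, scheme: str = "external_test") -> ModelReport:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.config.task == "regression":
            return ModelReport(self.config, scheme, len(y),
                               regression_metrics(y, self.predict(X)))
        return _classification_report(self.config, scheme, y, self.predict(X),
                                      self.positive_proba(X))

    def training_report(self) -> ModelReport:
        if self._training_report is None:
            self._training_report = self.evaluate(self.model.X, self.model.y,
                                                  scheme="training")
        return self._training_report

    def feature_importances(self):
        imp = getattr(self.estimator, "feature_importances_", None)
        if imp is None:
            raise AttributeError(
                f"{self.config.algo} does not expose feature importances")
        return np.asarray(imp, dtype=float)

    def summary(self, reports: list[ModelReport] | None = None) -> str:
        """Plain-text summary table of the fit and any evaluation reports."""
        lines = [
            "QSDAR model results",
            "=" * 55,
            f"algo: {self.config.algo}   task: {self.config.task}   "
            f"trees: {self.config.effective_n_trees}   seed: {self.config.seed}",
            f"n obs: {self.model.X.shape[0]}   n features: {self.model.X.shape[1]}",
            "-" * 55,
        ]
        for rep in (reports if reports is not None else [self.training_report()]):
            m = rep.metrics
            if isinstance(m, ClassificationMetrics):
                auc = f"{m.auc:.3f}" if m.auc is not None else "--"
                lines.append(
                    f"{rep.scheme:>13}  n={rep.n:<7d} SE={m.se:.3f} SP={m.sp:.3f} "
                    f"Q={m.q:.3f} MCC={m.mcc:.3f} AUC={auc}")
            else:
                r2 = f"{m.r2:.3f}" if m.r2_defined else "undef"
                lines.append(
                    f"{rep.scheme:>13}  n={rep.n:<7d} R2={r2} "
                    f"MAE={m.mae:.3f} RMSE={m.rmse:.3f}")
        lines.append("=" * 55)
        return "\n".join(lines)
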