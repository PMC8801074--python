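"""Leave-lot-out cross-validated potency classification and growth-rate regression.

The donor lot is the unit of generalisation: every fold of the
cross-validation holds out *all* samples (wells and FOV pseudo-samples) of
one lot, so replicate samples sharing a teacher signal never straddle the
train/test boundary.  Learners are exposed as scikit-learn style
estimators (:class:`PotencyClassifier`, :class:`GrowthRegressor`) that
standardise features with train-fold statistics and, for the L1 models,
pick the penalty by an inner lot-grouped 3-fold CV.

Classification label coding follows the study convention: 0 for High-risk
lots, 1 for Low-risk lots; Low-risk (1) is the positive class for
precision, and specificity is the recall of the High-risk class.  Metrics
are computed on the pooled held-out predictions of all folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .profiling import MorphProfile, subset_parameters, window

__all__ = [
    "DesignMatrix",
    "CVReport",
    "build_design_matrix",
    "leave_lot_out_splits",
    "standardize",
    "PotencyClassifier",
    "GrowthRegressor",
    "fit_predict_classifier",
    "fit_predict_regressor",
    "score_classification",
    "cross_validate_lots",
    "sweep",
    "lasso_report",
]

CLASSIFIER_METHODS = ("knn", "lasso", "rf")
REGRESSOR_METHODS = ("lasso", "rf")

_DEFAULT_C_GRID = tuple(np.logspace(-2, 2, 13))
_DEFAULT_ALPHA_GRID = tuple(np.logspace(-3, 0.5, 15))


@dataclass
class DesignMatrix:
    """Samples x (parameter x time) feature matrix with lot identity."""

    X: pd.DataFrame  # rows indexed by sample id strings
    y: np.ndarray
    lots: np.ndarray  # lot id per row

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.lots = np.asarray(self.lots)
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing entries")
        if not (len(self.X) == len(self.y) == len(self.lots)):
            raise ValueError("X, y and lots must align row-wise")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class CVReport:
    """Pooled leave-lot-out results for one (method, mode, window) cell."""

    task: str  # "classification" | "regression"
    method: str
    parameter_mode: str
    window_end_h: float
    fold_lots: list
    y_true: np.ndarray
    y_pred: np.ndarray
    sample_lots: np.ndarray
    metrics: dict
    hyper: dict = field(default_factory=dict)
    lasso_fold_coefs: list | None = None
    feature_names: list | None = None

    def to_dict(self) -> dict:
        d = {
            "task": self.task,
            "method": self.method,
            "parameter_mode": self.parameter_mode,
            "window_end_h": self.window_end_h,
            "fold_lots": [str(l) for l in self.fold_lots],
            "y_true": np.asarray(self.y_true).tolist(),
            "y_pred": np.asarray(self.y_pred).tolist(),
            "sample_lots": [str(l) for l in self.sample_lots],
            "metrics": {k: v for k, v in self.metrics.items() if k != "confusion"},
            "hyper": self.hyper,
        }
        if "confusion" in self.metrics:
            d["metrics"]["confusion"] = {
                k: int(v) for k, v in self.metrics["confusion"].items()
            }
        return d


def build_design_matrix(
    profiles: Sequence[MorphProfile],
    targets: Mapping,
    mode: str = "mean+SD",
    window_end: float | None = None,
) -> DesignMatrix:
    """Flatten profiles (after parameter subsetting and windowing) into a matrix.

    ``targets`` maps a sample key to its teacher signal; keys are resolved
    per profile as ``sample_id``, then ``(lot, well)``, then ``lot``.
    """
    rows, ys, lots, ids = [], [], [], []
    for p in profiles:
        q = subset_parameters(p, mode) if p.parameter_mode == "mean+SD" else p
        if window_end is not None:
            q = window(q, window_end)
        for key in (p.sample_id, p.sample_id[:2], p.lot):
            if key in targets:
                ys.append(targets[key])
                break
        else:
            raise KeyError(f"no target for sample {p.sample_id}")
        rows.append(q.flatten())
        lots.append(p.lot)
        ids.append("/".join(str(s) for s in p.sample_id if s is not None))
    X = pd.DataFrame(rows, index=ids)
    return DesignMatrix(X=X, y=np.asarray(ys), lots=np.asarray(lots))


def leave_lot_out_splits(dm: DesignMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per lot; all rows of the held-out lot form the test set."""
    lots = np.unique(dm.lots)
    if len(lots) < 2:
        raise ValueError("leave-lot-out needs >= 2 distinct lots")
    splits = []
    for lot in lots:
        test = np.flatnonzero(dm.lots == lot)
        train = np.flatnonzero(dm.lots != lot)
        splits.append((train, test))
    return splits


def standardize(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both matrices with mean/SD estimated on the training rows only.

    Zero-variance features pass through centred (divided by 1).
    """
    scaler = StandardScaler().fit(X_train)
    return scaler.transform(X_train), scaler.transform(X_test)


def _knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int
) -> np.ndarray:
    """k-nearest-neighbour majority vote (Euclidean distance).

    Distance ties are broken by the smaller training-row index (stable
    sort); vote ties by the label of the nearest neighbour among the tied
    classes.
    """
    d = cdist(X_test, X_train)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    preds = []
    for row in order:
        labels = y_train[row]
        classes, counts = np.unique(labels, return_counts=True)
        best = classes[counts == counts.max()]
        if len(best) == 1:
            preds.append(best[0])
        else:
            preds.append(labels[np.isin(labels, best).argmax()])
    return np.asarray(preds)


def _inner_groups_cv(n_groups: int, inner_splits: int) -> GroupKFold:
    return GroupKFold(n_splits=min(inner_splits, n_groups))


class PotencyClassifier(BaseEstimator, ClassifierMixin):
    """Risk-class predictor from flattened morphological profiles.

    Parameters
    ----------
    method : {"knn", "lasso", "rf"}
        kNN majority vote (default k = 5), L1-penalised logistic
        regression with the penalty chosen by an inner lot-grouped 3-fold
        CV, or a random forest (500 trees, sqrt(p) features per split).
    """

    def __init__(
        self,
        method: str = "knn",
        k: int = 5,
        n_trees: int = 500,
        c_grid: tuple = _DEFAULT_C_GRID,
        inner_splits: int = 3,
        random_state: int = 0,
    ):
        self.method = method
        self.k = k
        self.n_trees = n_trees
        self.c_grid = c_grid
        self.inner_splits = inner_splits
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        if self.method not in CLASSIFIER_METHODS:
            raise ValueError(f"unknown classifier method {self.method!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training fold contains a single class")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if self.method == "knn":
            self.X_train_, self.y_train_ = Xs, y
        elif self.method == "lasso":
            self.C_ = self._select_c(Xs, y, groups)
            self.model_ = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=self.C_, max_iter=5000,
                random_state=self.random_state,
            ).fit(Xs, y)
            self.coef_ = self.model_.coef_.ravel()
        else:
            self.model_ = RandomForestClassifier(
                n_estimators=self.n_trees, max_features="sqrt",
                random_state=self.random_state,
            ).fit(Xs, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _select_c(self, Xs, y, groups):
        if groups is None:
            return float(self.c_grid[len(self.c_grid) // 2])
        groups = np.asarray(groups)
        cv = _inner_groups_cv(len(np.unique(groups)), self.inner_splits)
        best_c, best_acc = None, -np.inf
        for c in self.c_grid:
            accs = []
            for tr, te in cv.split(Xs, y, groups):
                if len(np.unique(y[tr])) < 2:
                    continue
                m = LogisticRegression(
                    l1_ratio=1.0, solver="liblinear", C=c, max_iter=5000,
                    random_state=self.random_state,
                ).fit(Xs[tr], y[tr])
                accs.append(np.mean(m.predict(Xs[te]) == y[te]))
            acc = float(np.mean(accs)) if accs else -np.inf
            if acc > best_acc:  # ties keep the smaller (stronger) penalty
                best_acc, best_c = acc, float(c)
        return best_c

    def predict(self, X):
        check_is_fitted(self, "scaler_")
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        if self.method == "knn":
            return _knn_predict(self.X_train_, self.y_train_, Xs, self.k)
        return self.model_.predict(Xs)


class GrowthRegressor(BaseEstimator, RegressorMixin):
    """Growth-rate predictor from flattened morphological profiles.

    ``method="lasso"`` is an L1 linear regression with alpha chosen by an
    inner lot-grouped 3-fold CV; ``method="rf"`` a random forest.
    Predictions are unclipped.
    """

    def __init__(
        self,
        method: str = "lasso",
        n_trees: int = 500,
        alpha_grid: tuple = _DEFAULT_ALPHA_GRID,
        inner_splits: int = 3,
        random_state: int = 0,
    ):
        self.method = method
        self.n_trees = n_trees
        self.alpha_grid = alpha_grid
        self.inner_splits = inner_splits
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        if self.method not in REGRESSOR_METHODS:
            raise ValueError(f"unknown regressor method {self.method!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if self.method == "lasso":
            self.alpha_ = self._select_alpha(Xs, y, groups)
            self.model_ = Lasso(alpha=self.alpha_, max_iter=50_000).fit(Xs, y)
            self.coef_ = self.model_.coef_
        else:
            self.model_ = RandomForestRegressor(
                n_estimators=self.n_trees, max_features="sqrt",
                random_state=self.random_state,
            ).fit(Xs, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _select_alpha(self, Xs, y, groups):
        if groups is None:
            return float(self.alpha_grid[len(self.alpha_grid) // 2])
        groups = np.asarray(groups)
        cv = _inner_groups_cv(len(np.unique(groups)), self.inner_splits)
        best_alpha, best_mse = None, np.inf
        for a in self.alpha_grid[::-1]:  # ties keep the stronger penalty
            mses = []
            for tr, te in cv.split(Xs, y, groups):
                m = Lasso(alpha=a, max_iter=50_000).fit(Xs[tr], y[tr])
                mses.append(np.mean((m.predict(Xs[te]) - y[te]) ** 2))
            mse = float(np.mean(mses))
            if mse < best_mse:
                best_mse, best_alpha = mse, float(a)
        return best_alpha

    def predict(self, X):
        check_is_fitted(self, "scaler_")
        return self.model_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))


def fit_predict_classifier(method, train, test, hyper=None, seed=0):
    """Fit a classifier on ``train = (X, y, groups)`` and predict ``test`` rows."""
    X, y, groups = train
    est = PotencyClassifier(method=method, random_state=seed, **(hyper or {}))
    est.fit(X, y, groups=groups)
    return est.predict(test)


def fit_predict_regressor(method, train, test, hyper=None, seed=0):
    X, y, groups = train
    est = GrowthRegressor(method=method, random_state=seed, **(hyper or {}))
    est.fit(X, y, groups=groups)
    return est.predict(test)


def score_classification(y_true, y_pred) -> dict:
    """Pooled accuracy / precision / specificity with the confusion matrix.

    Positive class = Low-risk (label 1): precision = TP / (TP + FP),
    specificity = TN / (TN + FP).  The confusion matrix is always emitted
    so either positive-class convention can be recomputed.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("no predictions to score")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return {
        "accuracy": (tp + tn) / y_true.size,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "confusion": {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
    }


def _rmse(y_true, y_pred) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def cross_validate_lots(
    dm: DesignMatrix,
    estimator,
    task: str,
    parameter_mode: str = "mean+SD",
    window_end_h: float = np.nan,
) -> CVReport:
    """Run leave-lot-out CV with a prototype estimator; pool held-out predictions."""
    splits = leave_lot_out_splits(dm)
    lots = np.unique(dm.lots)
    Xv = dm.X.values
    y_pred = np.empty(dm.n_samples, dtype=dm.y.dtype if task == "classification" else float)
    fold_coefs = []
    for (train, test), lot in zip(splits, lots):
        est = clone(estimator)
        try:
            est.fit(Xv[train], dm.y[train], groups=dm.lots[train])
        except ValueError as e:
            raise ValueError(f"fold holding out lot {lot}: {e}") from e
        y_pred[test] = est.predict(Xv[test])
        if getattr(est, "method", None) == "lasso":
            fold_coefs.append(np.asarray(est.coef_, dtype=float))
    if task == "classification":
        metrics = score_classification(dm.y, y_pred)
    else:
        metrics = {"rmse": _rmse(dm.y, y_pred)}
    return CVReport(
        task=task,
        method=getattr(estimator, "method", type(estimator).__name__),
        parameter_mode=parameter_mode,
        window_end_h=float(window_end_h),
        fold_lots=list(lots),
        y_true=dm.y.copy(),
        y_pred=y_pred,
        sample_lots=dm.lots.copy(),
        metrics=metrics,
        hyper=estimator.get_params(),
        lasso_fold_coefs=fold_coefs or None,
        feature_names=dm.feature_names,
    )


def sweep(
    profiles: Sequence[MorphProfile],
    targets: Mapping,
    task: str,
    methods: Sequence[str],
    modes: Sequence[str],
    window_ends: Sequence[float],
    seed: int = 0,
) -> list[CVReport]:
    """Full factorial sweep over methods x parameter modes x time windows."""
    reports = []
    for mode in modes:
        for end in window_ends:
            dm = build_design_matrix(profiles, targets, mode=mode, window_end=end)
            for method in methods:
                if task == "classification":
                    est = PotencyClassifier(method=method, random_state=seed)
                else:
                    est = GrowthRegressor(method=method, random_state=seed)
                try:
                    reports.append(
                        cross_validate_lots(
                            dm, est, task, parameter_mode=mode, window_end_h=end
                        )
                    )
                except Exception as e:
                    raise RuntimeError(
                        f"sweep cell (method={method}, mode={mode}, window={end}): {e}"
                    ) from e
    return reports


def lasso_report(report: CVReport, top: int = 15) -> pd.DataFrame:
    """Per-feature LASSO selection counts and mean signed weights across folds.

    Rows are sorted by selection count (descending), ties broken by the
    magnitude of the mean weight; the head of the table is the "top 15"
    view.  Raises for non-LASSO reports.
    """
    if report.method != "lasso" or not report.lasso_fold_coefs:
        raise ValueError("lasso_report requires a fitted LASSO CVReport")
    coefs = np.vstack(report.lasso_fold_coefs)
    counts = (coefs != 0).sum(axis=0)
    mean_w = coefs.mean(axis=0)
    tab = pd.DataFrame(
        {
            "feature": report.feature_names,
            "n_selected": counts,
            "mean_weight": mean_w,
        }
    )
    tab = tab.sort_values(
        by=["n_selected", "mean_weight"],
        key=lambda s: np.abs(s) if s.name == "mean_weight" else s,
        ascending=[False, False],
    ).reset_index(drop=True)
    return tab.head(top) if top else tab
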