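"""The five mortality risk-model families with the study validation protocol.

Families: logistic regression, random forest, XGBoost, class-weighted SVM
(with Platt-style probability calibration), and a single-hidden-layer
neural network.  Hyperparameters are selected by stratified 5-fold
cross-validation on the training window, maximising mean fold CEM (AUC
selectable), and the final model is refit on the full training window with
the chosen parameters.

``RiskModel`` is a scikit-learn compatible estimator (BaseEstimator /
ClassifierMixin, ``fit``/``predict_proba``/``get_params``), so it composes
with sklearn pipelines and model selection; the module-level functions
``cross_validate_select`` / ``fit_final`` / ``predict_risk`` are thin
wrappers over it operating on patient tables.

The published hyperparameter grids of the original study are not available;
the defaults here are deliberately small, documented, desk-scale stand-ins.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import metrics as _metrics

__all__ = ["FAMILIES", "DEFAULT_GRIDS", "ModelSpec", "RiskModel",
           "cross_validate_select", "fit_final", "predict_risk",
           "feature_columns"]

FAMILIES = ("logistic_regression", "random_forest", "xgboost",
            "weighted_svm", "neural_network")

#: Desk-scale default search grids (declared stand-ins, not the study's).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"max_depth": [4, 8, None]},
    "xgboost": {"max_depth": [3, 4, 6], "learning_rate": [0.05, 0.1]},
    "weighted_svm": {"C": [0.1, 1.0, 10.0]},
    "neural_network": {"hidden_layer_sizes": [(16,), (32,)]},
}

#: Fixed (non-searched) settings per family.
DEFAULT_FIXED: dict[str, dict] = {
    "logistic_regression": {"max_iter": 2000, "solver": "lbfgs"},
    "random_forest": {"n_estimators": 500, "min_samples_leaf": 5},
    "xgboost": {"n_estimators": 200, "subsample": 0.9, "tree_method": "hist",
                "eval_metric": "logloss", "n_jobs": 1},
    "weighted_svm": {"kernel": "rbf", "probability": True, "cache_size": 200},
    "neural_network": {"max_iter": 300, "early_stopping": True,
                       "n_iter_no_change": 10},
}

RESERVED_COLUMNS = ("month", "mortality")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


class ModelSpec:
    """Declarative description of one model family to train.

    Parameters
    ----------
    family : one of ``FAMILIES``
    grid : dict of lists, optional — hyperparameter search grid
        (family default used when omitted).
    class_weighting : bool — apply inverse-prevalence class weights
        (always on for ``weighted_svm``).
    seed : int
    fixed_params : dict, optional — extra constructor arguments overriding
        the family defaults (e.g. smaller forests in tests).
    """

    def __init__(self, family: str, grid: dict | None = None,
                 class_weighting: bool | None = None, seed: int = 0,
                 fixed_params: dict | None = None):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        self.family = family
        self.grid = grid if grid is not None else DEFAULT_GRIDS[family]
        for values in self.grid.values():
            if not np.iterable(values):
                raise ValueError("grid values must be finite lists")
        self.class_weighting = (family == "weighted_svm"
                                if class_weighting is None else class_weighting)
        self.seed = seed
        self.fixed_params = dict(DEFAULT_FIXED[family])
        if fixed_params:
            self.fixed_params.update(fixed_params)

    def grid_points(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def _class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-prevalence weights: w_c = 0.5 / P(class c)."""
    pi = float(np.mean(y))
    return {0: 0.5 / (1.0 - pi), 1: 0.5 / pi}


def _build_estimator(spec: ModelSpec, params: dict, y: np.ndarray):
    kw = dict(spec.fixed_params)
    kw.update(params)
    if spec.family == "logistic_regression":
        if spec.class_weighting:
            kw["class_weight"] = _class_weights(y)
        return LogisticRegression(**kw)
    if spec.family == "random_forest":
        if spec.class_weighting:
            kw["class_weight"] = _class_weights(y)
        return RandomForestClassifier(random_state=spec.seed, **kw)
    if spec.family == "xgboost":
        if spec.class_weighting:
            kw["scale_pos_weight"] = float(np.sum(y == 0) / np.sum(y == 1))
        return XGBClassifier(random_state=spec.seed, **kw)
    if spec.family == "weighted_svm":
        kw["class_weight"] = _class_weights(y)
        return SVC(random_state=spec.seed, **kw)
    if spec.family == "neural_network":
        return MLPClassifier(random_state=spec.seed, **kw)
    raise AssertionError(spec.family)


class RiskModel(ClassifierMixin, BaseEstimator):
    """A cardiac-surgery mortality risk model with built-in CV selection.

    ``fit`` runs stratified k-fold cross-validation over the spec's grid,
    selects the point maximising the mean fold score (CEM by default, AUC
    via ``scoring="auc"``), then refits on all training data.

    Fitted attributes
    -----------------
    best_params_ : chosen grid point
    cv_results_ : list of {params, fold_scores, mean_score}
    estimator_ : the fitted underlying sklearn/xgboost estimator
    feature_names_ : column order the model expects
    effective_class_weight_ : class weights actually applied (if any)
    """

    def __init__(self, family: str = "xgboost", grid: dict | None = None,
                 class_weighting: bool | None = None, seed: int = 0,
                 fixed_params: dict | None = None, scoring: str = "cem",
                 cv: int = 5, f1_threshold: float = 0.5, ece_bins: int = 10):
        self.family = family
        self.grid = grid
        self.class_weighting = class_weighting
        self.seed = seed
        self.fixed_params = fixed_params
        self.scoring = scoring
        self.cv = cv
        self.f1_threshold = f1_threshold
        self.ece_bins = ece_bins

    # -- internals ------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(self.family, grid=self.grid,
                         class_weighting=self.class_weighting, seed=self.seed,
                         fixed_params=self.fixed_params)

    def _score(self, prob: np.ndarray, y: np.ndarray) -> float:
        if self.scoring == "auc":
            return _metrics.auc(prob, y)
        if self.scoring == "cem":
            return _metrics.evaluate(prob, y, f1_threshold=self.f1_threshold,
                                     n_bins=self.ece_bins).cem
        raise ValueError(f"unknown scoring {self.scoring!r}")

    @staticmethod
    def _as_xy(X, y=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        if y is None:
            return Xv, None, names
        yv = np.asarray(y).astype(int)
        return Xv, yv, names

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y):
        Xv, yv, names = self._as_xy(X, y)
        if len(np.unique(yv)) < 2:
            raise ValueError("training data must contain both outcome classes")
        spec = self._spec()
        points = spec.grid_points()
        cv_results = []
        if len(points) > 1 or self.cv > 1:
            if self.cv < 2:
                raise ValueError("cv must be >= 2 for grid selection")
            if int(np.sum(yv == 1)) < self.cv or int(np.sum(yv == 0)) < self.cv:
                raise ValueError(
                    "stratification error: fewer minority-class records than folds")
            skf = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.seed)
            splits = list(skf.split(Xv, yv))
            for params in points:
                fold_scores = []
                for tr, te in splits:
                    est = _build_estimator(spec, params, yv[tr])
                    est.fit(Xv[tr], yv[tr])
                    prob = est.predict_proba(Xv[te])[:, 1]
                    fold_scores.append(self._score(prob, yv[te]))
                cv_results.append({"params": params, "fold_scores": fold_scores,
                                   "mean_score": float(np.mean(fold_scores))})
            # a NaN mean score (e.g. CEM with a zero component) never wins
            best = max(cv_results,
                       key=lambda r: (-np.inf if np.isnan(r["mean_score"])
                                      else r["mean_score"]))
        else:
            best = {"params": points[0], "fold_scores": [], "mean_score": float("nan")}
            cv_results.append(best)
        self.cv_results_ = cv_results
        self.best_params_ = dict(best["params"])
        est = _build_estimator(spec, self.best_params_, yv)
        est.fit(Xv, yv)
        self.estimator_ = est
        self.effective_class_weight_ = getattr(est, "class_weight", None)
        if spec.family == "xgboost" and spec.class_weighting:
            self.effective_class_weight_ = {"scale_pos_weight": est.get_params()["scale_pos_weight"]}
        self.feature_names_ = names
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = Xv.shape[1]
        return self

    def predict_proba(self, X):
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names_) - set(X.columns)
            if missing:
                raise ValueError(f"schema error: missing features {sorted(missing)}")
            X = X[self.feature_names_]
        Xv, _, _ = self._as_xy(X)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError("schema error: wrong number of features")
        return self.estimator_.predict_proba(Xv)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def __sklearn_clone__(self):  # keep default cloning semantics explicit
        return clone(self, safe=False)


# ---------------------------------------------------------------------------
# patient-table wrappers
# ---------------------------------------------------------------------------

def cross_validate_select(spec: ModelSpec, train_table: pd.DataFrame,
                          k: int = 5, scoring: str = "cem",
                          f1_threshold: float = 0.5, ece_bins: int = 10):
    """Select hyperparameters by stratified k-fold CV on the training window.

    Returns (best_params, cv_results) where cv_results holds per-grid-point
    fold scores.  Deterministic given the spec seed.
    """
    model = RiskModel(family=spec.family, grid=spec.grid,
                      class_weighting=spec.class_weighting, seed=spec.seed,
                      fixed_params=spec.fixed_params, scoring=scoring, cv=k,
                      f1_threshold=f1_threshold, ece_bins=ece_bins)
    cols = feature_columns(train_table)
    model.fit(train_table[cols], train_table["mortality"])
    return model.best_params_, model.cv_results_


def fit_final(spec: ModelSpec, train_table: pd.DataFrame,
              chosen_params: dict) -> RiskModel:
    """Refit the family on the full training window with chosen parameters."""
    model = RiskModel(family=spec.family, grid={k: [v] for k, v in chosen_params.items()},
                      class_weighting=spec.class_weighting, seed=spec.seed,
                      fixed_params=spec.fixed_params, cv=0)
    cols = feature_columns(train_table)
    model.fit(train_table[cols], train_table["mortality"])
    return model


def predict_risk(model: RiskModel, table: pd.DataFrame) -> pd.DataFrame:
    """Order-preserving prediction set for a (cleaned, standardized) table.

    Returns a DataFrame with ``probability``, ``outcome`` and ``month``
    aligned 1:1 with the input records.
    """
    out = pd.DataFrame(index=table.index)
    if len(table) == 0:
        return pd.DataFrame(columns=["probability", "outcome", "month"])
    out["probability"] = model.predict_proba(table[model.feature_names_])[:, 1]
    out["outcome"] = table["mortality"].to_numpy() if "mortality" in table.columns else np.nan
    out["month"] = table["month"].to_numpy() if "month" in table.columns else None
    return out
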