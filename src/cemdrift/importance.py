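"""Per-month variable-importance series — the drift-detection instrument.

For each holdout month, k-fold nested cross-validation (inner loop selects
hyperparameters, outer folds yield attributions on held-out records) gives
per-fold mean absolute attributions per feature; the geometric mean across
outer folds is the month's importance.  Attribution backends:

* tree ensembles (xgboost): exact per-record tree-path SHAP values via the
  booster's ``pred_contribs`` output;
* any other family: permutation importance (mean |score drop| over
  shuffles), the model-agnostic fallback.

The backend actually used is recorded in the output.  Series are smoothed
with LOESS (default span 0.5) and a residual-bootstrap 95% band; the
changepoint estimate of a series is the month with the largest absolute
first difference of the unsmoothed geometric means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess

from .models import ModelSpec, RiskModel, feature_columns

__all__ = ["monthly_importance", "importance_series", "smooth_series",
           "top_features", "change_month"]


def _fold_attribution(model: RiskModel, X_test: pd.DataFrame, y_test,
                      seed: int) -> tuple[np.ndarray, str]:
    """Mean |per-record attribution| per feature on one held-out fold."""
    if model.family == "xgboost":
        booster = model.estimator_.get_booster()
        import xgboost as xgb
        dm = xgb.DMatrix(X_test.to_numpy(dtype=float),
                         feature_names=list(X_test.columns))
        contribs = booster.predict(dm, pred_contribs=True)
        return np.mean(np.abs(contribs[:, :-1]), axis=0), "tree_shap"
    perm = permutation_importance(model, X_test, np.asarray(y_test),
                                  scoring="roc_auc", n_repeats=5,
                                  random_state=seed)
    return np.abs(perm.importances_mean), "permutation"


def monthly_importance(month_table: pd.DataFrame, spec: ModelSpec,
                       k: int = 5, inner_k: int = 3,
                       seed: int = 0) -> pd.DataFrame:
    """Nested-CV per-feature attributions within one month slice.

    Returns a long DataFrame (feature, fold, value, backend) plus the
    geometric mean across the k outer folds in a ``geomean`` column
    (repeated per feature).  A degenerate slice (missing a class, or fewer
    minority records than folds) raises ``ValueError`` — callers flag the
    month as missing.
    """
    cols = feature_columns(month_table)
    X = month_table[cols]
    y = month_table["mortality"].to_numpy().astype(int)
    if len(np.unique(y)) < 2 or np.sum(y == 1) < k or np.sum(y == 0) < k:
        raise ValueError("degenerate month slice for nested CV")
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        model = RiskModel(family=spec.family, grid=spec.grid,
                          class_weighting=spec.class_weighting,
                          seed=spec.seed + fold, fixed_params=spec.fixed_params,
                          cv=inner_k if len(spec.grid_points()) > 1 else 0)
        model.fit(X.iloc[tr], y[tr])
        values, backend = _fold_attribution(model, X.iloc[te], y[te],
                                            seed=spec.seed + fold)
        for name, v in zip(cols, values):
            records.append({"feature": name, "fold": fold,
                            "value": float(v), "backend": backend})
    df = pd.DataFrame(records)
    # geometric mean across folds; a zero fold makes the geomean zero
    geo = df.groupby("feature")["value"].apply(
        lambda v: float(np.exp(np.mean(np.log(np.maximum(v, 1e-300)))))
        if (v > 0).all() else 0.0)
    df["geomean"] = df["feature"].map(geo)
    return df


def importance_series(table: pd.DataFrame, spec: ModelSpec, k: int = 5,
                      inner_k: int = 3, seed: int = 0) -> pd.DataFrame:
    """Per-month importance for every feature over the holdout months.

    Long format: month, month_index (0 = first month), feature, fold,
    value, geomean, backend.  Degenerate months are skipped and listed in
    the frame's ``attrs["missing_months"]``.
    """
    months = pd.PeriodIndex(table["month"], freq="M")
    start = months.min()
    frames, missing = [], []
    for month in pd.period_range(start, months.max(), freq="M"):
        sel = np.asarray(months == month)
        if not sel.any():
            missing.append(str(month))
            continue
        try:
            df = monthly_importance(table.loc[sel], spec, k=k, inner_k=inner_k,
                                    seed=seed + (month - start).n)
        except ValueError:
            missing.append(str(month))
            continue
        df.insert(0, "month_index", (month - start).n)
        df.insert(0, "month", str(month))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["missing_months"] = missing
    return out


def smooth_series(series: pd.DataFrame, span: float = 0.5, seed: int = 0,
                  n_boot: int = 200) -> pd.DataFrame:
    """LOESS-smooth each feature's geomean trajectory with a 95% band.

    ``span`` is the LOESS fraction in (0, 1].  The band comes from a
    residual bootstrap of the LOESS fit (seeded).  Needs >= 3 months.
    Returns one row per (feature, month): month_index, geomean, smoothed,
    lo, hi.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for feature, grp in series.groupby("feature"):
        g = grp.drop_duplicates("month_index").sort_values("month_index")
        t = g["month_index"].to_numpy(dtype=float)
        y = g["geomean"].to_numpy(dtype=float)
        if t.size < 3:
            raise ValueError("smoothing needs >= 3 months")
        fitted = lowess(y, t, frac=span, return_sorted=False)
        resid = y - fitted
        boots = np.empty((n_boot, t.size))
        for b in range(n_boot):
            yb = fitted + rng.choice(resid, size=resid.size, replace=True)
            boots[b] = lowess(yb, t, frac=span, return_sorted=False)
        lo = np.percentile(boots, 2.5, axis=0)
        hi = np.percentile(boots, 97.5, axis=0)
        for i in range(t.size):
            rows.append({"feature": feature, "month_index": int(t[i]),
                         "geomean": y[i], "smoothed": fitted[i],
                         "lo": lo[i], "hi": hi[i]})
    return pd.DataFrame(rows)


def top_features(series: pd.DataFrame, m: int = 6) -> list[str]:
    """Top-m features by mean (over months) geometric-mean importance."""
    means = (series.drop_duplicates(["month_index", "feature"])
             .groupby("feature")["geomean"].mean()
             .sort_values(ascending=False))
    return list(means.index[:m])


def change_month(series: pd.DataFrame, feature: str,
                 method: str = "segment") -> int:
    """Estimated change month of a feature's unsmoothed importance series.

    ``method="segment"`` (default) fits a two-segment piecewise-constant
    model and returns the split minimising the residual sum of squares —
    the classic least-squares step-change estimator, robust to single-month
    spikes.  ``method="diff"`` returns the month with the largest absolute
    first difference (the naive estimator; a one-month outlier produces two
    large opposite-signed differences and can capture it).  Both report the
    index of the first month *after* the change.
    """
    g = (series.loc[series["feature"] == feature]
         .drop_duplicates("month_index").sort_values("month_index"))
    if len(g) < 2:
        raise ValueError("change-month estimate needs >= 2 months")
    t = g["month_index"].to_numpy()
    y = g["geomean"].to_numpy(dtype=float)
    if method == "diff":
        return int(t[1:][np.argmax(np.abs(np.diff(y)))])
    if method != "segment":
        raise ValueError(f"unknown method {method!r}")
    best_k, best_sse = 1, np.inf
    for k in range(1, len(y)):
        a, b = y[:k], y[k:]
        sse = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
        if sse < best_sse:
            best_k, best_sse = k, sse
    return int(t[best_k])
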