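"""Temporal drift analysis of model performance.

Builds per-month bootstrap metric series for each model, fits a linear
month trend to the per-month point estimates with residual diagnostics
(Shapiro-Wilk normality, Breusch-Pagan homoscedasticity), falling back to
the seasonal Kendall test with Sen slope when the diagnostics fail; runs
the model-comparison test batteries (repeated-measures ANOVA + paired
one-tailed t tests with Bonferroni correction + Dunnett-style many-to-one
comparison for the nontemporal baseline; Kruskal-Wallis + paired Wilcoxon +
Dunn post hoc within and between calendar windows); performs the DeLong
test on correlated ROC areas; and linearly projects a fitted metric trend
to a future month.

Month indexing is 0-based at the first holdout month, so with a January
2017 holdout start, January 2030 is month 156.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.stats import multivariate_t
from statsmodels.stats.diagnostic import het_breuschpagan

from .metrics import METRIC_NAMES, BootstrapSummary, bootstrap_evaluate

__all__ = [
    "MetricTimeSeries",
    "DriftFit",
    "ComparisonResult",
    "monthly_series",
    "fit_drift",
    "seasonal_kendall",
    "compare_models_nontemporal",
    "compare_models_window",
    "compare_windows",
    "delong_auc_test",
    "project_metric",
    "month_seed",
]


def month_seed(seed: int, month_index: int) -> int:
    """Deterministic per-month bootstrap seed shared across models."""
    ss = np.random.SeedSequence(seed, spawn_key=(month_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class MetricTimeSeries:
    """Per-month bootstrap summaries of one metric for one model."""

    metric: str
    months: pd.PeriodIndex            # months with a valid point
    month_index: np.ndarray           # 0 = first holdout month
    points: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    summaries: list[BootstrapSummary]
    missing_months: list[str] = field(default_factory=list)
    B: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months.astype(str),
                             "month_index": self.month_index,
                             "point": self.points, "ci_low": self.ci_low,
                             "ci_high": self.ci_high})


def monthly_series(predictions: pd.DataFrame, metric: str = "cem",
                   B: int = 1000, seed: int = 0, f1_threshold: float = 0.5,
                   n_bins: int = 10, thresholds=None,
                   origin: str | None = None) -> MetricTimeSeries:
    """Bootstrap one metric per holdout month.

    ``predictions`` must carry ``probability``, ``outcome`` and ``month``.
    Bootstrap seeds derive from (seed, month index), so different models
    evaluated with the same seed on the same slices share resample streams
    (the pairing contract).  Months where either outcome class has fewer
    than 2 records are flagged missing, not silently dropped.

    ``origin`` pins month index 0 (default: first month present).
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    months_all = pd.PeriodIndex(predictions["month"], freq="M")
    start = pd.Period(origin, "M") if origin else months_all.min()
    uniq = pd.period_range(months_all.min(), months_all.max(), freq="M")
    months, mindex, points, lo, hi, summaries, missing = [], [], [], [], [], [], []
    for month in uniq:
        sel = months_all == month
        if not sel.any():
            missing.append(str(month))
            continue
        y = predictions.loc[sel, "outcome"].to_numpy().astype(int)
        if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
            missing.append(str(month))
            continue
        m_idx = (month - start).n
        summ = bootstrap_evaluate(
            predictions.loc[sel, "probability"].to_numpy(), y, B=B,
            f1_threshold=f1_threshold, n_bins=n_bins, thresholds=thresholds,
            seed=month_seed(seed, m_idx))
        months.append(month)
        mindex.append(m_idx)
        points.append(summ.point[metric])
        lo.append(summ.ci_low[metric])
        hi.append(summ.ci_high[metric])
        summaries.append(summ)
    return MetricTimeSeries(metric=metric, months=pd.PeriodIndex(months, freq="M"),
                            month_index=np.asarray(mindex),
                            points=np.asarray(points, dtype=float),
                            ci_low=np.asarray(lo, dtype=float),
                            ci_high=np.asarray(hi, dtype=float),
                            summaries=summaries, missing_months=missing, B=B)


@dataclass
class DriftFit:
    """Fitted metric-vs-month trend with diagnostics."""

    method: str                    # "linear_regression" | "seasonal_kendall"
    intercept: float               # metric units at month 0
    slope: float                   # metric units per month
    p_value: float
    slope_se: float = float("nan")
    shapiro_stat: float = float("nan")
    shapiro_p: float = float("nan")
    het_stat: float = float("nan")
    het_p: float = float("nan")
    diagnostics_pass: bool = True
    n: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("method", "intercept", "slope", "p_value", "slope_se",
                 "shapiro_p", "het_p", "diagnostics_pass", "n")}


def _ols_line(t: np.ndarray, y: np.ndarray):
    n = t.size
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * tbar)
    resid = y - (intercept + slope * t)
    if n > 2:
        s2 = float(np.sum(resid ** 2) / (n - 2))
        se = float(np.sqrt(s2 / sxx))
    else:
        se = 0.0
    if se > 0:
        tstat = slope / se
        p = 2.0 * stats.t.sf(abs(tstat), n - 2)
    else:  # noiseless or 2-point fit: exact line
        p = 1.0 if slope == 0.0 else 0.0
    return intercept, slope, se, float(p), resid


def seasonal_kendall(months: pd.PeriodIndex, y: np.ndarray):
    """Seasonal Kendall trend test with Sen slope.

    Seasons are calendar months (12).  Kendall S statistics and their
    null variances are summed over seasons; the Sen slope is the median of
    within-season pairwise slopes.  Returns (slope, intercept, p, z).
    """
    t = np.array([(m - months[0]).n for m in months], dtype=float)
    season = np.array([m.month for m in months])
    S_tot, var_tot = 0.0, 0.0
    pair_slopes = []
    for s in np.unique(season):
        sel = season == s
        ys, ts = y[sel], t[sel]
        n = ys.size
        if n < 2:
            continue
        for i, j in itertools.combinations(range(n), 2):
            diff = ys[j] - ys[i]
            S_tot += np.sign(diff)
            if ts[j] != ts[i]:
                pair_slopes.append(diff / (ts[j] - ts[i]))
        var_tot += n * (n - 1) * (2 * n + 5) / 18.0
    if var_tot == 0 or not pair_slopes:
        raise ValueError("seasonal Kendall needs >=2 points in some season")
    z = (S_tot - np.sign(S_tot)) / np.sqrt(var_tot) if S_tot != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    slope = float(np.median(pair_slopes))
    intercept = float(np.median(y - slope * t))
    return slope, intercept, float(p), float(z)


def fit_drift(series: MetricTimeSeries, alpha: float = 0.05) -> DriftFit:
    """OLS trend of per-month point estimates with assumption checks.

    Residual normality (Shapiro-Wilk) and heteroscedasticity
    (Breusch-Pagan) are tested at ``alpha``; on failure the fit switches to
    the seasonal Kendall test (Sen slope), with the method recorded.
    A (near-)noiseless fit keeps the linear method with diagnostics skipped.
    """
    if len(series) < 3:
        raise ValueError("drift fit needs at least 3 monthly points")
    t = series.month_index.astype(float)
    y = series.points
    if np.any(~np.isfinite(y)):
        raise ValueError(
            "metric series contains undefined points (e.g. CEM with a zero "
            "component); fix the metric settings or drop those months explicitly")
    intercept, slope, se, p, resid = _ols_line(t, y)
    fit = DriftFit(method="linear_regression", intercept=intercept, slope=slope,
                   p_value=p, slope_se=se, n=len(series))
    if float(np.ptp(resid)) < 1e-12:      # exact line: diagnostics void
        return fit
    sh_stat, sh_p = stats.shapiro(resid)
    X = np.column_stack([np.ones_like(t), t])
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, X)
    fit.shapiro_stat, fit.shapiro_p = float(sh_stat), float(sh_p)
    fit.het_stat, fit.het_p = float(bp_stat), float(bp_p)
    fit.diagnostics_pass = bool(sh_p >= alpha and bp_p >= alpha)
    if not fit.diagnostics_pass:
        sk_slope, sk_int, sk_p, _ = seasonal_kendall(series.months, y)
        return DriftFit(method="seasonal_kendall", intercept=sk_int,
                        slope=sk_slope, p_value=sk_p,
                        shapiro_stat=fit.shapiro_stat, shapiro_p=fit.shapiro_p,
                        het_stat=fit.het_stat, het_p=fit.het_p,
                        diagnostics_pass=False, n=len(series))
    return fit


def project_metric(fit: DriftFit, target_month_index: int) -> float:
    """Linear extrapolation intercept + slope * month_index.

    Month 0 is the first holdout month, so a January 2017 origin puts
    January 2030 at month 156.  Defined only for linear fits.
    """
    if fit.method != "linear_regression":
        raise ValueError("projection is defined only for linear fits")
    return float(fit.intercept + fit.slope * target_month_index)


# ---------------------------------------------------------------------------
# model-comparison batteries
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """One statistical test's outcome within a comparison battery."""

    name: str
    statistic: float
    p_value: float
    correction: str = "none"
    details: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"name": self.name, "statistic": self.statistic,
                "p_value": self.p_value, "correction": self.correction,
                "details": _jsonable(self.details)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _check_paired(matrix: pd.DataFrame):
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 models to compare")
    if matrix.isna().any().any():
        raise ValueError("unpaired inputs: NaNs in the paired bootstrap matrix")


def _rm_anova(matrix: pd.DataFrame) -> ComparisonResult:
    """Repeated-measures one-way ANOVA (subjects = bootstrap resamples)."""
    X = matrix.to_numpy(dtype=float)
    n, k = X.shape
    grand = X.mean()
    ss_treat = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_treat - ss_subj
    df_t, df_e = k - 1, (k - 1) * (n - 1)
    if ss_err <= 0:        # identical replicate patterns across models
        F = np.inf if ss_treat > 0 else 0.0
        p = 0.0 if ss_treat > 0 else 1.0
    else:
        F = (ss_treat / df_t) / (ss_err / df_e)
        p = stats.f.sf(F, df_t, df_e)
    return ComparisonResult("repeated_measures_anova", float(F), float(p),
                            details={"df": (df_t, df_e)})


def _dunnett_paired(matrix: pd.DataFrame, control: str,
                    conf: float = 0.95, seed: int = 0) -> ComparisonResult:
    """Many-to-one comparison of paired differences against a control.

    Works on D_i = model_i - control per bootstrap resample; p-values and
    family-wise CIs come from the equicoordinate tail of the multivariate t
    with the estimated correlation of the differences (Bonferroni fallback
    if the correlation matrix is degenerate).
    """
    others = [c for c in matrix.columns if c != control]
    D = matrix[others].to_numpy() - matrix[[control]].to_numpy()
    n, m = D.shape
    mean = D.mean(axis=0)
    se = D.std(axis=0, ddof=1) / np.sqrt(n)
    se = np.where(se == 0, np.finfo(float).tiny, se)
    tstats = mean / se
    df = n - 1
    corr = np.corrcoef(D, rowvar=False) if m > 1 else np.array([[1.0]])
    correction = "dunnett_mvt"
    try:
        if m > 1 and (np.any(~np.isfinite(corr)) or
                      np.linalg.matrix_rank(corr) < m):
            raise np.linalg.LinAlgError("degenerate correlation")
        mvt = multivariate_t(loc=np.zeros(m), shape=corr, df=df, seed=seed)

        def coverage(c):
            return float(mvt.cdf(np.full(m, c), lower_limit=np.full(m, -c)))

        pvals = np.array([min(1.0, 1.0 - coverage(abs(t))) for t in tstats])
        crit = brentq(lambda c: coverage(c) - conf, 1.0, 50.0, xtol=1e-4)
    except Exception:  # pragma: no cover - exercised only on degenerate input
        warnings.warn("multivariate-t reference unavailable; Bonferroni fallback",
                      stacklevel=2)
        correction = "bonferroni_fallback"
        pvals = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(tstats), df) * m)
        crit = stats.t.ppf(1 - (1 - conf) / (2 * m), df)
    details = {"control": control, "comparisons": {}}
    for j, name in enumerate(others):
        details["comparisons"][name] = {
            "difference": float(mean[j]),
            "ci": (float(mean[j] - crit * se[j]), float(mean[j] + crit * se[j])),
            "t": float(tstats[j]), "p": float(pvals[j])}
    return ComparisonResult("dunnett_vs_control", float(np.max(np.abs(tstats))),
                            float(np.min(pvals)), correction=correction,
                            details=details)


def compare_models_nontemporal(cem_matrix: pd.DataFrame, control: str,
                               seed: int = 0) -> dict[str, ComparisonResult]:
    """Parametric baseline battery on the paired bootstrap CEM matrix.

    Columns are models, rows paired bootstrap resamples (shared resample
    indices).  Runs per-model Shapiro-Wilk normality, repeated-measures
    one-way ANOVA, Bonferroni-corrected one-tailed paired t tests (direction:
    the higher-mean model of each pair against the other), and a
    Dunnett-style many-to-one comparison against ``control``.
    """
    _check_paired(cem_matrix)
    if control not in cem_matrix.columns:
        raise ValueError(f"control {control!r} not among models")
    results: dict[str, ComparisonResult] = {}
    sh = {c: stats.shapiro(cem_matrix[c]) for c in cem_matrix.columns}
    results["normality"] = ComparisonResult(
        "shapiro_wilk_per_model", float("nan"), float(min(v.pvalue for v in sh.values())),
        details={c: {"stat": float(v.statistic), "p": float(v.pvalue)}
                 for c, v in sh.items()})
    results["anova"] = _rm_anova(cem_matrix)
    pairs = list(itertools.combinations(cem_matrix.columns, 2))
    m = len(pairs)
    pair_details = {}
    for a, b in pairs:
        hi, lo = (a, b) if cem_matrix[a].mean() >= cem_matrix[b].mean() else (b, a)
        diff = cem_matrix[hi].to_numpy() - cem_matrix[lo].to_numpy()
        if np.allclose(diff, 0):   # identical columns: no evidence of difference
            t_res = type("T", (), {"statistic": 0.0, "pvalue": 1.0})
        else:
            t_res = stats.ttest_rel(cem_matrix[hi], cem_matrix[lo],
                                    alternative="greater")
        p_corr = min(1.0, float(t_res.pvalue) * m)
        pair_details[f"{hi}>{lo}"] = {
            "t": float(t_res.statistic), "p_raw": float(t_res.pvalue),
            "p_bonferroni": p_corr,
            "difference": float(cem_matrix[hi].mean() - cem_matrix[lo].mean())}
    results["paired_t"] = ComparisonResult(
        "paired_t_one_tailed", float("nan"),
        float(min(d["p_bonferroni"] for d in pair_details.values())),
        correction="bonferroni", details=pair_details)
    results["dunnett"] = _dunnett_paired(cem_matrix, control, seed=seed)
    return results


def _kruskal(*groups) -> ComparisonResult:
    try:
        kw = stats.kruskal(*groups)
        stat, p = float(kw.statistic), float(kw.pvalue)
    except ValueError:        # all values identical across groups
        stat, p = 0.0, 1.0
    return ComparisonResult("kruskal_wallis", stat, p)


def _dunn_vs_control(matrix: pd.DataFrame, control: str) -> ComparisonResult:
    """Dunn post hoc z tests against a control from pooled Kruskal ranks."""
    cols = list(matrix.columns)
    values = np.concatenate([matrix[c].to_numpy() for c in cols])
    groups = np.concatenate([[c] * len(matrix) for c in cols])
    ranks = stats.rankdata(values)
    N = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_rank = {c: ranks[groups == c].mean() for c in cols}
    nc = len(matrix)
    others = [c for c in cols if c != control]
    details = {"control": control, "comparisons": {}}
    for c in others:
        z = (mean_rank[c] - mean_rank[control]) / np.sqrt(var_base * (2.0 / nc))
        p = 2.0 * stats.norm.sf(abs(z))
        details["comparisons"][c] = {
            "z": float(z), "p_raw": float(p),
            "p_bonferroni": min(1.0, float(p) * len(others)),
            "difference": float(matrix[c].median() - matrix[control].median())}
    pmin = min(d["p_bonferroni"] for d in details["comparisons"].values())
    return ComparisonResult("dunn_vs_control", float("nan"), float(pmin),
                            correction="bonferroni", details=details)


def compare_models_window(cem_matrix: pd.DataFrame, control: str
                          ) -> dict[str, ComparisonResult]:
    """Nonparametric battery within a calendar window.

    Kruskal-Wallis across models, Bonferroni-corrected paired Wilcoxon
    signed-rank tests for every pair, and the Dunn post hoc test against
    the control model.
    """
    _check_paired(cem_matrix)
    if control not in cem_matrix.columns:
        raise ValueError(f"control {control!r} not among models")
    results: dict[str, ComparisonResult] = {}
    results["kruskal"] = _kruskal(*[cem_matrix[c] for c in cem_matrix.columns])
    pairs = list(itertools.combinations(cem_matrix.columns, 2))
    m = len(pairs)
    pair_details = {}
    for a, b in pairs:
        diff = cem_matrix[a].to_numpy() - cem_matrix[b].to_numpy()
        if np.allclose(diff, 0):
            w_stat, w_p = 0.0, 1.0
        else:
            w = stats.wilcoxon(diff)
            w_stat, w_p = float(w.statistic), float(w.pvalue)
        pair_details[f"{a}|{b}"] = {"w": w_stat, "p_raw": w_p,
                                    "p_bonferroni": min(1.0, w_p * m)}
    results["wilcoxon"] = ComparisonResult(
        "paired_wilcoxon", float("nan"),
        float(min(d["p_bonferroni"] for d in pair_details.values())),
        correction="bonferroni", details=pair_details)
    results["dunn"] = _dunn_vs_control(cem_matrix, control)
    return results


def compare_windows(values_a: np.ndarray, values_b: np.ndarray,
                    paired: bool = True) -> dict[str, ComparisonResult]:
    """Compare one model's CEM values between two calendar windows.

    Paired Wilcoxon signed-rank (pairing via shared bootstrap streams),
    Kolmogorov-Smirnov normality of each window, Kruskal-Wallis across the
    windows, and the Bonferroni-adjusted Dunn magnitude.  The headline
    effect size is the median difference median(a - b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("length mismatch under pairing")
    results: dict[str, ComparisonResult] = {}

    def ks_norm(x):
        z = (x - x.mean()) / (x.std(ddof=1) if x.std(ddof=1) > 0 else 1.0)
        return stats.kstest(z, "norm")

    ks_a, ks_b = ks_norm(a), ks_norm(b)
    results["normality"] = ComparisonResult(
        "kolmogorov_smirnov", float(max(ks_a.statistic, ks_b.statistic)),
        float(min(ks_a.pvalue, ks_b.pvalue)),
        details={"window_a_p": float(ks_a.pvalue), "window_b_p": float(ks_b.pvalue)})
    results["kruskal"] = _kruskal(a, b)
    diff = a - b if paired else None
    if paired:
        if np.allclose(diff, 0):
            w_stat, w_p = 0.0, 1.0
        else:
            w = stats.wilcoxon(diff)
            w_stat, w_p = float(w.statistic), float(w.pvalue)
        median_diff = float(np.median(diff))
    else:
        u = stats.mannwhitneyu(a, b)
        w_stat, w_p = float(u.statistic), float(u.pvalue)
        median_diff = float(np.median(a) - np.median(b))
    results["wilcoxon"] = ComparisonResult(
        "paired_wilcoxon" if paired else "mann_whitney", w_stat, w_p,
        details={"median_difference": median_diff})
    two = pd.DataFrame({"a": a[: min(a.size, b.size)], "b": b[: min(a.size, b.size)]})
    results["dunn"] = _dunn_vs_control(two, control="b")
    results["dunn"].details["median_difference"] = median_diff
    return results


def plot_series(series: MetricTimeSeries, fit: DriftFit | None = None, ax=None,
                label: str | None = None):
    """Metric-vs-month plot with bootstrap CI band and optional trend line.

    Returns the matplotlib axes; import is deferred so headless use of the
    library never touches a display backend.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = series.month_index
    ax.fill_between(t, series.ci_low, series.ci_high, alpha=0.25, linewidth=0)
    ax.plot(t, series.points, "o-", ms=3, label=label or series.metric)
    if fit is not None and fit.method == "linear_regression":
        ax.plot(t, fit.intercept + fit.slope * t, "r--",
                label=f"trend {fit.slope:+.2e}/month (p={fit.p_value:.2g})")
    ax.set_xlabel("month index (0 = first holdout month)")
    ax.set_ylabel(series.metric)
    ax.legend(frameon=False, fontsize=8)
    return ax


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(prob: np.ndarray, y: np.ndarray):
    """Per-model AUC and DeLong structural components (Sun & Xu midranks)."""
    pos = prob[y == 1]
    neg = prob[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc_val = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - r_pos) / n                 # structural components, cases
    v01 = 1.0 - (all_r[m:] - r_neg) / m           # structural components, controls
    return auc_val, v10, v01


def delong_auc_test(prob_a, prob_b, outcome) -> ComparisonResult:
    """DeLong covariance-based z test on two correlated ROC areas.

    Both prediction sets must score the same records.  The z statistic is
    antisymmetric in (A, B).
    """
    pa = np.asarray(prob_a, dtype=float)
    pb = np.asarray(prob_b, dtype=float)
    y = np.asarray(outcome).astype(int)
    if pa.shape != pb.shape or pa.shape != y.shape:
        raise ValueError("prediction sets must score the same records")
    if len(np.unique(y)) < 2:
        raise ValueError("DeLong test undefined with a single outcome class")
    auc_a, v10_a, v01_a = _delong_auc_variance(pa, y)
    auc_b, v10_b, v01_b = _delong_auc_variance(pb, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult("delong", float(z), float(p),
                            details={"auc_a": float(auc_a), "auc_b": float(auc_b),
                                     "difference": float(auc_a - auc_b)})
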