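"""Tests for trend fitting, comparison batteries, DeLong and projection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cemdrift.drift import (
    DriftFit,
    MetricTimeSeries,
    compare_models_nontemporal,
    compare_models_window,
    compare_windows,
    delong_auc_test,
    fit_drift,
    monthly_series,
    project_metric,
    seasonal_kendall,
)


def make_series(values, start="2017-01"):
    months = pd.period_range(start, periods=len(values), freq="M")
    v = np.asarray(values, dtype=float)
    return MetricTimeSeries(metric="cem", months=months,
                            month_index=np.arange(len(v)), points=v,
                            ci_low=v, ci_high=v, summaries=[], B=1)


class TestFitDrift:
    def test_noiseless_line_recovered_exactly(self):
        # the published XGBoost CEM trend constants
        t = np.arange(27)
        series = make_series(0.755 - 0.000720 * t)
        fit = fit_drift(series)
        assert fit.method == "linear_regression"
        assert fit.intercept == pytest.approx(0.755, abs=1e-12)
        assert fit.slope == pytest.approx(-0.000720, abs=1e-12)

    def test_constant_series_flat_with_p_one(self):
        fit = fit_drift(make_series([0.7] * 12))
        assert fit.slope == 0.0
        assert fit.p_value == pytest.approx(1.0)

    def test_needs_three_points(self):
        with pytest.raises(ValueError, match="3"):
            fit_drift(make_series([0.7, 0.71]))

    def test_gaussian_noise_keeps_linear_method(self):
        g = np.random.default_rng(1)
        t = np.arange(36)
        series = make_series(0.75 - 0.001 * t + g.normal(0, 0.005, 36))
        fit = fit_drift(series)
        assert fit.method == "linear_regression"
        assert fit.diagnostics_pass

    def test_sawtooth_switches_to_seasonal_kendall(self):
        # strong periodic sawtooth violates residual normality/homoscedasticity
        t = np.arange(48)
        saw = 0.04 * (t % 12 == 0) - 0.04 * (t % 12 == 6)
        g = np.random.default_rng(2)
        truth_slope = -0.0008
        series = make_series(0.75 + truth_slope * t + saw + g.normal(0, 0.0005, 48))
        fit = fit_drift(series)
        assert fit.method == "seasonal_kendall"
        assert fit.slope == pytest.approx(truth_slope, rel=0.10)

    def test_nan_points_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            fit_drift(make_series([0.7, np.nan, 0.71, 0.72]))


class TestSeasonalKendall:
    def test_matches_plain_kendall_with_single_season(self):
        # all points in one calendar month -> reduces to the Mann-Kendall test
        g = np.random.default_rng(3)
        y = np.cumsum(g.normal(0.5, 1, 10))
        months = pd.PeriodIndex([f"{2000 + i}-03" for i in range(10)], freq="M")
        t = np.array([(m - months[0]).n for m in months], dtype=float)
        slope, intercept, p, z = seasonal_kendall(months, y)
        tau_res = sps.kendalltau(t, y)
        assert (p < 0.05) == (tau_res.pvalue < 0.05)
        # Sen slope equals the median pairwise slope computed directly
        direct = np.median([(y[j] - y[i]) / (t[j] - t[i])
                            for i in range(10) for j in range(i + 1, 10)])
        assert slope == pytest.approx(direct)


class TestProjection:
    def test_published_xgboost_net_benefit_projection(self):
        fit = DriftFit("linear_regression", intercept=0.9051, slope=-5.68e-5,
                       p_value=0.0)
        assert round(project_metric(fit, 156), 4) == 0.8962

    def test_published_nn_net_benefit_projection(self):
        fit = DriftFit("linear_regression", intercept=0.9035, slope=-0.000145,
                       p_value=0.0)
        assert project_metric(fit, 156) == pytest.approx(0.88088, abs=5e-6)

    def test_zero_slope_returns_intercept(self):
        fit = DriftFit("linear_regression", intercept=0.5, slope=0.0, p_value=1.0)
        assert project_metric(fit, 9999) == 0.5

    def test_projection_is_linear_in_horizon(self):
        fit = DriftFit("linear_regression", intercept=0.8, slope=-2e-4, p_value=0.0)
        assert (project_metric(fit, 100) - project_metric(fit, 40)
                ) == pytest.approx(fit.slope * 60)

    def test_nonlinear_method_refused(self):
        fit = DriftFit("seasonal_kendall", intercept=0.8, slope=-2e-4, p_value=0.0)
        with pytest.raises(ValueError, match="linear"):
            project_metric(fit, 156)


def paired_matrix(offsets, n=200, noise=0.002, seed=4):
    g = np.random.default_rng(seed)
    base = 0.7 + g.normal(0, 0.01, n)
    return pd.DataFrame({name: base + off + g.normal(0, noise, n)
                         for name, off in offsets.items()})


class TestNontemporalBattery:
    def test_identical_columns_no_evidence(self):
        m = paired_matrix({"a": 0.0})
        m["b"] = m["a"]
        res = compare_models_nontemporal(m, control="a")
        assert res["paired_t"].p_value == 1.0
        assert abs(res["dunnett"].details["comparisons"]["b"]["difference"]) < 1e-12

    def test_constant_offset_detected(self):
        delta = 0.02
        m = paired_matrix({"a": 0.0, "b": -delta})
        res = compare_models_nontemporal(m, control="a")
        est = res["dunnett"].details["comparisons"]["b"]["difference"]
        assert est == pytest.approx(-delta, abs=0.001)
        assert res["dunnett"].details["comparisons"]["b"]["p"] < 0.001
        assert res["anova"].p_value < 0.001

    def test_control_best_all_differences_nonpositive(self):
        m = paired_matrix({"best": 0.0, "mid": -0.01, "worst": -0.03})
        res = compare_models_nontemporal(m, control="best")
        diffs = [c["difference"] for c in res["dunnett"].details["comparisons"].values()]
        assert all(d <= 0 for d in diffs)

    def test_familywise_ci_covers_estimate(self):
        m = paired_matrix({"a": 0.0, "b": -0.01, "c": -0.02})
        res = compare_models_nontemporal(m, control="a")
        for comp in res["dunnett"].details["comparisons"].values():
            lo, hi = comp["ci"]
            assert lo <= comp["difference"] <= hi

    def test_unpaired_input_rejected(self):
        m = paired_matrix({"a": 0.0, "b": -0.01})
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="unpaired"):
            compare_models_nontemporal(m, control="a")


class TestWindowBattery:
    def test_identical_columns_all_p_near_one(self):
        m = paired_matrix({"a": 0.0})
        m["b"] = m["a"]
        res = compare_models_window(m, control="a")
        assert res["kruskal"].p_value > 0.9
        assert res["wilcoxon"].p_value == 1.0

    def test_single_shifted_column_flagged_by_dunn(self):
        m = paired_matrix({"a": 0.0, "b": 0.0005, "c": -0.05}, noise=0.004, seed=6)
        res = compare_models_window(m, control="a")
        comp = res["dunn"].details["comparisons"]
        assert comp["c"]["p_bonferroni"] < 0.001
        assert comp["b"]["p_bonferroni"] > 0.05

    def test_kruskal_invariant_under_monotone_transform(self):
        m = paired_matrix({"a": 0.0, "b": -0.02, "c": 0.01})
        res1 = compare_models_window(m, control="a")
        res2 = compare_models_window(np.exp(5 * m), control="a")
        assert res1["kruskal"].statistic == pytest.approx(res2["kruskal"].statistic)


class TestBetweenWindows:
    def test_identical_windows_zero_median_difference(self):
        a = paired_matrix({"a": 0.0})["a"].to_numpy()
        res = compare_windows(a, a.copy())
        assert res["wilcoxon"].details["median_difference"] == 0.0
        assert res["wilcoxon"].p_value == 1.0

    def test_constant_shift_recovered(self):
        # the published largest between-window CEM drop for the best model
        a = paired_matrix({"a": 0.0})["a"].to_numpy()
        res = compare_windows(a, a - 0.0288)
        assert res["wilcoxon"].details["median_difference"] == pytest.approx(0.0288)
        assert res["wilcoxon"].p_value < 1e-10

    def test_length_mismatch_under_pairing(self):
        a = np.full(10, 0.7)
        with pytest.raises(ValueError, match="length"):
            compare_windows(a, a[:5])


class TestDeLong:
    def test_equal_predictions_p_one(self):
        g = np.random.default_rng(7)
        p = g.random(200)
        y = (g.random(200) < p).astype(int)
        res = delong_auc_test(p, p, y)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_antisymmetric_in_model_order(self):
        g = np.random.default_rng(8)
        y = g.integers(0, 2, 300)
        pa = np.clip(y * 0.4 + g.random(300) * 0.6, 0, 1)
        pb = g.random(300)
        ab = delong_auc_test(pa, pb, y)
        ba = delong_auc_test(pb, pa, y)
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_perfect_vs_random_strongly_separated(self):
        g = np.random.default_rng(9)
        n = 2000
        y = g.integers(0, 2, n)
        perfect = y.astype(float)
        random_p = g.random(n)
        res = delong_auc_test(perfect, random_p, y)
        assert res.p_value < 1e-6
        assert res.details["auc_a"] == 1.0

    def test_matches_auc_point_estimates(self, random_predictions):
        p, y = random_predictions
        res = delong_auc_test(p, 1 - p, y)
        from cemdrift.metrics import auc
        assert res.details["auc_a"] == pytest.approx(auc(p, y))
        assert res.details["auc_b"] == pytest.approx(auc(1 - p, y))


class TestMonthlySeries:
    def _preds(self, months, n=120, seed=10):
        g = np.random.default_rng(seed)
        rows = []
        for mth in months:
            p = g.beta(1.5, 6, n)
            y = (g.random(n) < p).astype(int)
            rows.append(pd.DataFrame({"probability": p, "outcome": y, "month": mth}))
        return pd.concat(rows, ignore_index=True)

    def test_single_month_series_of_length_one(self):
        preds = self._preds(["2017-01"])
        series = monthly_series(preds, B=20, seed=1, f1_threshold=0.2)
        assert len(series) == 1 and series.month_index[0] == 0

    def test_degenerate_month_flagged_missing(self):
        preds = self._preds(["2017-01", "2017-02"])
        sel = preds["month"] == "2017-02"
        preds.loc[sel, "outcome"] = 0
        preds.loc[preds.index[sel][:1], "outcome"] = 1  # single case: < 2 per class
        series = monthly_series(preds, B=20, seed=1, f1_threshold=0.2)
        assert series.missing_months == ["2017-02"]
        assert len(series) == 1

    def test_pairing_shared_across_models(self):
        preds = self._preds(["2017-01", "2017-02", "2017-03"])
        s1 = monthly_series(preds, B=30, seed=5, f1_threshold=0.2)
        s2 = monthly_series(preds.assign(probability=lambda d: d["probability"] ** 2),
                            B=30, seed=5, f1_threshold=0.2)
        # same per-month seeds, so both models use identical resample indices
        assert [s.seed for s in s1.summaries] == [s.seed for s in s2.summaries]


def test_plot_series_renders_without_display():
    import matplotlib
    matplotlib.use("Agg")
    series = make_series(0.75 - 0.001 * np.arange(12))
    fit = fit_drift(series)
    ax = __import__("cemdrift.drift", fromlist=["plot_series"]).plot_series(
        series, fit)
    assert ax.get_ylabel() == "cem"
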