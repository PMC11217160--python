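"""Unit and property tests for the component metrics and CEM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import brier_score_loss, f1_score, roc_auc_score

from cemdrift import metrics as m

# ---------------------------------------------------------------------------
# brute-force oracles, deliberately naive
# ---------------------------------------------------------------------------


def auc_by_pairs(prob, y):
    """Concordance over all positive-negative pairs, ties counted half."""
    pos = [p for p, t in zip(prob, y) if t == 1]
    neg = [p for p, t in zip(prob, y) if t == 0]
    total = concordant = 0.0
    for a in pos:
        for b in neg:
            total += 1
            concordant += 1.0 if a > b else (0.5 if a == b else 0.0)
    return concordant / total


def nb_by_confusion(prob, y, t):
    n = len(y)
    tp = sum(1 for p, o in zip(prob, y) if p >= t and o == 1)
    fp = sum(1 for p, o in zip(prob, y) if p >= t and o == 0)
    fn = sum(1 for p, o in zip(prob, y) if p < t and o == 1)
    tn = sum(1 for p, o in zip(prob, y) if p < t and o == 0)
    treated = tp / n - (fp / n) * t / (1 - t)
    untreated = tn / n - (fn / n) * (1 - t) / t
    return treated, untreated


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


class TestAuc:
    def test_hand_example_three_concordant_of_four_pairs(self):
        assert m.auc([0.9, 0.8, 0.7, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert m.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_uninformative_constant_predictor(self):
        assert m.auc([0.3] * 6, [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="one outcome class"):
            m.auc([0.1, 0.2], [1, 1])


class TestF1:
    def test_hand_example(self):
        # TP=1, FP=1, FN=1 -> precision 0.5, recall 0.5
        assert m.f1([0.9, 0.8, 0.3], [1, 0, 1], threshold=0.5) == pytest.approx(0.5)

    def test_all_correct(self):
        assert m.f1([0.9, 0.1], [1, 0], threshold=0.5) == 1.0

    def test_no_predicted_positives_gives_zero(self):
        assert m.f1([0.1, 0.2, 0.3], [1, 1, 0], threshold=0.5) == 0.0

    def test_threshold_must_be_interior(self):
        with pytest.raises(ValueError):
            m.f1([0.5], [1], threshold=1.0)


class TestEce:
    def test_single_record(self):
        assert m.expected_calibration_error([0.3], [0]) == pytest.approx(0.3)

    def test_perfectly_calibrated_within_bins(self):
        # bin [0.2,0.3): mean prediction 0.25, observed rate 1/4
        p = [0.25, 0.25, 0.25, 0.25]
        y = [1, 0, 0, 0]
        assert m.expected_calibration_error(p, y) == pytest.approx(0.0)

    def test_constant_predictor_at_prevalence(self):
        y = [1, 0, 0, 0]
        assert m.expected_calibration_error([0.25] * 4, y) == pytest.approx(0.0)

    def test_probability_one_lands_in_top_bin(self):
        assert m.expected_calibration_error([1.0], [1], n_bins=10) == pytest.approx(0.0)


class TestBrier:
    def test_perfect(self):
        assert m.adjusted_brier([1.0, 0.0], [1, 0]) == 1.0

    def test_half_probability_single_record(self):
        assert m.adjusted_brier([0.5], [0]) == pytest.approx(0.75)

    def test_all_wrong_hard_predictions(self):
        assert m.adjusted_brier([0.0, 1.0], [1, 0]) == 0.0


class TestNetBenefit:
    def test_hand_confusion_example(self):
        curve = m.net_benefit_curve([0.9, 0.6, 0.2, 0.1], [1, 0, 0, 0],
                                    thresholds=[0.5])
        assert curve.treated[0] == pytest.approx(0.0)
        assert curve.untreated[0] == pytest.approx(0.5)
        assert curve.total[0] == pytest.approx(0.5)

    def test_perfect_predictor_sums_to_one_everywhere(self):
        y = [1, 0, 0, 0, 1]
        curve = m.net_benefit_curve([1.0, 0.0, 0.0, 0.0, 1.0], y)
        prevalence = np.mean(y)
        assert np.allclose(curve.treated, prevalence)
        assert np.allclose(curve.untreated, 1 - prevalence)
        assert m.overall_net_benefit(curve) == pytest.approx(1.0)

    def test_treat_all_predictor_zero_untreated(self):
        curve = m.net_benefit_curve([1.0, 1.0, 1.0], [1, 0, 1],
                                    thresholds=[0.25, 0.5, 0.75])
        assert np.allclose(curve.untreated, 0.0)

    def test_boundary_thresholds_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            curve = m.net_benefit_curve([0.5], [1], thresholds=[0.0, 0.5, 1.0])
        assert list(curve.thresholds) == [0.5]

    def test_overall_mean_of_curve(self):
        curve = m.NetBenefitCurve(np.array([0.2, 0.4]), np.array([0.1, 0.3]),
                                  np.array([0.1, 0.1]))
        assert m.overall_net_benefit(curve) == pytest.approx(0.3)

    def test_treat_none_closed_form(self):
        # all probabilities 0: TP=FP=0, untreated NB = TN/N - FN/N*(1-t)/t
        y = [1, 0, 0, 0]
        t = np.array([0.25, 0.5, 0.75])
        curve = m.net_benefit_curve([0.0] * 4, y, thresholds=t)
        pi = 0.25
        expected = (1 - pi) - pi * (1 - t) / t
        assert np.allclose(curve.total, expected)


class TestCem:
    @pytest.mark.parametrize("components,expected", [
        ((0.996, 0.834, 0.976, 0.279, 0.904), 0.728),   # XGBoost row
        ((0.996, 0.835, 0.976, 0.277, 0.904), 0.727),   # random forest row
        ((0.997, 0.819, 0.976, 0.264, 0.902), 0.717),   # logistic regression row
        ((0.641, 0.800, 0.814, 0.240, 0.461), 0.541),   # EuroSCORE II row
    ])
    def test_published_holdout_rows(self, components, expected):
        assert round(m.cem(components), 3) == expected

    def test_all_ones(self):
        assert m.cem((1, 1, 1, 1, 1)) == 1.0

    def test_nonpositive_component_flagged_undefined(self):
        with pytest.warns(UserWarning, match="non-positive"):
            assert np.isnan(m.cem((0.9, 0.0, 0.9, 0.9, 0.9)))

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            m.cem((0.5, 0.5))

    @given(st.lists(st.floats(0.05, 1.0), min_size=5, max_size=5))
    @settings(deadline=None, max_examples=50)
    def test_am_gm_inequality(self, comps):
        g = m.cem(comps)
        assert g <= np.mean(comps) + 1e-12

    @given(st.lists(st.floats(0.05, 0.95), min_size=5, max_size=5),
           st.integers(0, 4))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_in_each_component(self, comps, idx):
        g = m.cem(comps)
        bumped = list(comps)
        bumped[idx] = min(1.0, bumped[idx] + 0.04)
        assert m.cem(bumped) > g


# ---------------------------------------------------------------------------
# cross-checks against independent implementations
# ---------------------------------------------------------------------------


def test_metrics_match_sklearn_on_random_data(random_predictions):
    p, y = random_predictions
    assert m.auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)
    assert m.f1(p, y, 0.3) == pytest.approx(f1_score(y, p >= 0.3), abs=1e-12)
    assert m.adjusted_brier(p, y) == pytest.approx(1 - brier_score_loss(y, p),
                                                   abs=1e-12)


def test_auc_matches_pairwise_oracle(random_predictions):
    p, y = random_predictions
    p, y = p[:80], y[:80]
    if y.sum() in (0, len(y)):
        pytest.skip("degenerate draw")
    assert m.auc(p, y) == pytest.approx(auc_by_pairs(p, y), abs=1e-12)


def test_net_benefit_matches_confusion_oracle(random_predictions):
    p, y = random_predictions
    for t in (0.1, 0.25, 0.5, 0.9):
        curve = m.net_benefit_curve(p, y, thresholds=[t])
        treated, untreated = nb_by_confusion(p, y, t)
        assert curve.treated[0] == pytest.approx(treated, abs=1e-12)
        assert curve.untreated[0] == pytest.approx(untreated, abs=1e-12)


def test_metrics_are_permutation_invariant(random_predictions):
    p, y = random_predictions
    g = np.random.default_rng(3)
    perm = g.permutation(len(p))
    a, b = m.evaluate(p, y, f1_threshold=0.2), m.evaluate(p[perm], y[perm],
                                                          f1_threshold=0.2)
    assert a == b


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


class TestBootstrap:
    def test_single_resample_degenerate_ci(self, random_predictions):
        p, y = random_predictions
        s = m.bootstrap_evaluate(p, y, B=1, seed=4, f1_threshold=0.2)
        if s.n_degenerate == 0:
            for name in m.METRIC_NAMES:
                assert s.ci_low[name] == pytest.approx(s.ci_high[name])
                assert s.ci_low[name] == pytest.approx(s.samples[name][0])

    def test_deterministic_given_seed(self, random_predictions):
        p, y = random_predictions
        a = m.bootstrap_evaluate(p, y, B=25, seed=9, f1_threshold=0.2)
        b = m.bootstrap_evaluate(p, y, B=25, seed=9, f1_threshold=0.2)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert a.point == b.point

    def test_ci_brackets_point(self, random_predictions):
        p, y = random_predictions
        s = m.bootstrap_evaluate(p, y, B=60, seed=2, f1_threshold=0.2)
        for name in m.METRIC_NAMES:
            if np.isnan(s.point[name]):
                continue
            assert s.ci_low[name] <= s.point[name] + 1e-12
            assert s.point[name] <= s.ci_high[name] + 1e-12

    def test_pairing_contract_shared_indices(self):
        idx1 = m.resample_indices(100, 20, seed=5)
        idx2 = m.resample_indices(100, 20, seed=5)
        assert np.array_equal(idx1, idx2)
        assert not np.array_equal(idx1, m.resample_indices(100, 20, seed=6))

    def test_degenerate_resamples_counted_not_hidden(self):
        p = np.array([0.9, 0.1, 0.1, 0.1])
        y = np.array([1, 0, 0, 0])
        s = m.bootstrap_evaluate(p, y, B=200, seed=1)
        assert s.n_degenerate > 0
        assert s.samples["auc"].isna().sum() == s.n_degenerate

    def test_stratified_keeps_class_counts(self):
        y = np.array([1] * 5 + [0] * 45)
        idx = m.resample_indices(50, 30, seed=3, outcome=y, stratified=True)
        assert all(y[row].sum() == 5 for row in idx)


def test_matrix_bootstrap_path_matches_per_resample_path(random_predictions):
    """The vectorised all-resample path and a per-resample evaluate() loop
    must agree to machine precision, including degenerate-row handling."""
    p, y = random_predictions
    idx = m.resample_indices(len(p), 40, seed=11)
    t = m.default_thresholds()
    fast, nd_fast = m._bootstrap_matrix(p, y, idx, 0.2, 10, t)
    slow = np.full_like(fast, np.nan)
    nd_slow = 0
    for b in range(40):
        yb = y[idx[b]]
        if yb.min() == yb.max():
            nd_slow += 1
            continue
        mv = m.evaluate(p[idx[b]], yb, f1_threshold=0.2, thresholds=t)
        slow[b] = [mv.auc, mv.f1, mv.one_minus_ece, mv.adjusted_brier,
                   mv.overall_net_benefit, mv.cem]
    assert nd_fast == nd_slow
    np.testing.assert_allclose(fast, slow, atol=1e-12)
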