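"""Performance metrics and the CEM consensus metric.

The clinical effectiveness metric (CEM) is the geometric mean of five
components computed from predicted mortality probabilities p_i and binary
outcomes y_i:

* AUC — Mann-Whitney formulation with midrank tie correction (equals the
  trapezoidal ROC area);
* F1 — harmonic mean of precision and recall on the death class at a
  binarisation threshold (default 0.5);
* 1 - ECE ("adjusted ECE") — expected calibration error over equal-width
  probability bins (default 10), higher is better;
* 1 - Brier ("adjusted Brier") — one minus the mean squared error of the
  probabilities, without the prevalence normalisation term;
* overall net benefit — the decision-curve net benefit, treated plus
  untreated framing, averaged arithmetically over a threshold grid
  (default 0.01..0.99 step 0.01).  The arithmetic average is used here
  because per-threshold net benefit can be negative, which the geometric
  mean cannot absorb.

Uncertainty comes from bootstrap resampling of patients (default B=1000)
with the geometric mean across resamples as the point estimate and
percentile 2.5/97.5 bounds as the 95% CI.  Resample index streams are a
deterministic function of (seed, n, B), so two models evaluated on the same
cohort slice with the same seed share resamples — the pairing contract that
the model-comparison tests rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MetricVector",
    "BootstrapSummary",
    "NetBenefitCurve",
    "auc",
    "f1",
    "expected_calibration_error",
    "adjusted_brier",
    "net_benefit_curve",
    "overall_net_benefit",
    "cem",
    "evaluate",
    "resample_indices",
    "bootstrap_evaluate",
    "default_thresholds",
    "geometric_mean",
]

METRIC_NAMES = ("auc", "f1", "one_minus_ece", "adjusted_brier",
                "overall_net_benefit", "cem")


def default_thresholds() -> np.ndarray:
    """Decision-curve threshold grid 0.01..0.99 step 0.01."""
    return np.round(np.arange(0.01, 1.00, 0.01), 10)


def _validate(prob, outcome) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(prob, dtype=float)
    y = np.asarray(outcome)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("prob and outcome must be aligned 1-d arrays")
    if p.size == 0:
        raise ValueError("empty prediction set")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = y.astype(int)
    if np.any((y != 0) & (y != 1)):
        raise ValueError("outcomes must be binary 0/1")
    return p, y


def auc(prob, outcome) -> float:
    """ROC area via the Mann-Whitney U statistic with midrank ties."""
    p, y = _validate(prob, outcome)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one outcome class present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def f1(prob, outcome, threshold: float = 0.5) -> float:
    """F1 on the positive (death) class at a binarisation threshold.

    Returns 0 when precision + recall is 0 (no predicted and/or no true
    positives overlap).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p, y = _validate(prob, outcome)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2.0 * tp / denom


def expected_calibration_error(prob, outcome, n_bins: int = 10) -> float:
    """ECE over equal-width probability bins; empty bins contribute 0."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p, y = _validate(prob, outcome)
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    n = p.size
    ece = 0.0
    counts = np.bincount(idx, minlength=n_bins)
    sum_p = np.bincount(idx, weights=p, minlength=n_bins)
    sum_y = np.bincount(idx, weights=y.astype(float), minlength=n_bins)
    occupied = counts > 0
    gaps = np.abs(sum_p[occupied] / counts[occupied] - sum_y[occupied] / counts[occupied])
    ece = float(np.sum(counts[occupied] / n * gaps))
    return ece


def adjusted_brier(prob, outcome) -> float:
    """1 - mean squared error of probabilities against outcomes."""
    p, y = _validate(prob, outcome)
    return float(1.0 - np.mean((p - y) ** 2))


@dataclass
class NetBenefitCurve:
    """Per-threshold decision-curve net benefit (treated, untreated, sum)."""

    thresholds: np.ndarray
    treated: np.ndarray
    untreated: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.treated + self.untreated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "treated": self.treated,
                             "untreated": self.untreated, "total": self.total})


def net_benefit_curve(prob, outcome, thresholds=None) -> NetBenefitCurve:
    """Decision-curve net benefit at each threshold p_t.

    With confusion counts at cutoff p_t (predicted positive when
    prob >= p_t):

        treated NB   = TP/N - (FP/N) * p_t / (1 - p_t)
        untreated NB = TN/N - (FN/N) * (1 - p_t) / p_t

    Thresholds at exactly 0 or 1 are excluded with a warning.
    """
    p, y = _validate(prob, outcome)
    t = default_thresholds() if thresholds is None else np.asarray(thresholds, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        warnings.warn("thresholds at 0 or 1 excluded from net-benefit grid", stacklevel=2)
        t = t[(t > 0) & (t < 1)]
    if t.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    n = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ys = y[order]
    pos_cum = np.concatenate([[0], np.cumsum(ys)])          # positives among first i sorted
    total_pos = pos_cum[-1]
    # index of first prediction >= threshold in the sorted array
    first_ge = np.searchsorted(ps, t, side="left")
    tp = total_pos - pos_cum[first_ge]
    fp = (n - first_ge) - tp
    fn = pos_cum[first_ge]
    tn = first_ge - fn
    treated = tp / n - (fp / n) * t / (1.0 - t)
    untreated = tn / n - (fn / n) * (1.0 - t) / t
    return NetBenefitCurve(t, treated, untreated)


def overall_net_benefit(curve_or_prob, outcome=None, thresholds=None) -> float:
    """Arithmetic mean over the threshold grid of treated + untreated NB."""
    if isinstance(curve_or_prob, NetBenefitCurve):
        curve = curve_or_prob
    else:
        curve = net_benefit_curve(curve_or_prob, outcome, thresholds)
    return float(np.mean(curve.total))


def cem(components) -> float:
    """Geometric mean of the five component metrics.

    ``components`` is an iterable of the five values (AUC, F1, 1-ECE,
    1-Brier, overall net benefit; order immaterial).  If any component is
    <= 0 the geometric mean is undefined: NaN is returned and a diagnostic
    warning names the offending components rather than hiding them.
    """
    c = np.asarray(list(components), dtype=float)
    if c.size != 5:
        raise ValueError(f"CEM takes exactly 5 components, got {c.size}")
    if np.any(np.isnan(c)):
        return float("nan")
    if np.any(c <= 0):
        warnings.warn(
            f"CEM undefined: non-positive components {c[c <= 0].tolist()}",
            stacklevel=2)
        return float("nan")
    return float(np.exp(np.mean(np.log(c))))


@dataclass
class MetricVector:
    """The five component metrics plus CEM for one evaluation."""

    auc: float
    f1: float
    one_minus_ece: float
    adjusted_brier: float
    overall_net_benefit: float
    cem: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def evaluate(prob, outcome, f1_threshold: float = 0.5, n_bins: int = 10,
             thresholds=None) -> MetricVector:
    """Compute the full metric vector for one prediction set."""
    a = auc(prob, outcome)
    f = f1(prob, outcome, threshold=f1_threshold)
    e = 1.0 - expected_calibration_error(prob, outcome, n_bins=n_bins)
    b = adjusted_brier(prob, outcome)
    nb = overall_net_benefit(prob, outcome, thresholds=thresholds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = cem((a, f, e, b, nb))
    return MetricVector(a, f, e, b, nb, g)


def geometric_mean(values: np.ndarray) -> float:
    """Geometric mean; NaN-propagating, requires strictly positive input."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(v))))


def resample_indices(n: int, B: int, seed: int, outcome=None,
                     stratified: bool = False) -> np.ndarray:
    """Deterministic (B, n) bootstrap index matrix.

    A pure function of (seed, n, B) — the contract that lets two models
    evaluated on the same cohort slice share resamples.  With
    ``stratified=True`` cases and non-cases are resampled separately so
    every resample keeps the observed class counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(n, B)))
    if not stratified:
        return rng.integers(0, n, size=(B, n))
    y = np.asarray(outcome).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    cols = [pos[rng.integers(0, pos.size, size=(B, pos.size))],
            neg[rng.integers(0, neg.size, size=(B, neg.size))]]
    return np.concatenate(cols, axis=1)


def _bootstrap_matrix(p: np.ndarray, y: np.ndarray, indices: np.ndarray,
                      f1_threshold: float, n_bins: int,
                      t: np.ndarray) -> tuple[np.ndarray, int]:
    """All-resample metric matrix computed with row-wise array operations.

    Numerically identical to evaluating each resample with ``evaluate``;
    degenerate (single-class) rows stay NaN and are counted.
    """
    if np.any((t <= 0) | (t >= 1)):
        warnings.warn("thresholds at 0 or 1 excluded from net-benefit grid",
                      stacklevel=3)
        t = t[(t > 0) & (t < 1)]
    B, n = indices.shape
    P = p[indices]
    Y = y[indices]
    n1 = Y.sum(axis=1)
    valid = (n1 > 0) & (n1 < n)
    n0 = n - n1
    rows = np.full((B, len(METRIC_NAMES)), np.nan)

    # AUC via midranks per row
    ranks = rankdata(P, axis=1)
    pos_rank_sum = np.sum(ranks * Y, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        auc_v = (pos_rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # F1 at the binarisation threshold
    pred = P >= f1_threshold
    tp = np.sum(pred & (Y == 1), axis=1)
    fp = np.sum(pred & (Y == 0), axis=1)
    fn = np.sum(~pred & (Y == 1), axis=1)
    denom = 2 * tp + fp + fn
    f1_v = np.where(denom == 0, 0.0, 2.0 * tp / np.maximum(denom, 1))

    # ECE over equal-width bins, row-wise bincounts via flattened offsets
    bin_idx = np.minimum((P * n_bins).astype(int), n_bins - 1)
    flat = bin_idx + np.arange(B)[:, None] * n_bins
    counts = np.bincount(flat.ravel(), minlength=B * n_bins).reshape(B, n_bins)
    sum_p = np.bincount(flat.ravel(), weights=P.ravel(),
                        minlength=B * n_bins).reshape(B, n_bins)
    sum_y = np.bincount(flat.ravel(), weights=Y.ravel().astype(float),
                        minlength=B * n_bins).reshape(B, n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gaps = np.abs(sum_p / counts - sum_y / counts)
    gaps[counts == 0] = 0.0
    ece_v = np.sum(counts / n * gaps, axis=1)

    brier_v = 1.0 - np.mean((P - Y) ** 2, axis=1)

    # net benefit: confusion counts at every threshold via row-wise sorting
    order = np.argsort(P, axis=1, kind="stable")
    Ps = np.take_along_axis(P, order, axis=1)
    Ys = np.take_along_axis(Y, order, axis=1)
    pos_cum = np.concatenate([np.zeros((B, 1)), np.cumsum(Ys, axis=1)], axis=1)
    first_ge = np.stack([np.searchsorted(Ps[b], t, side="left")
                         for b in range(B)])
    tp_t = n1[:, None] - np.take_along_axis(pos_cum, first_ge, axis=1)
    fp_t = (n - first_ge) - tp_t
    fn_t = np.take_along_axis(pos_cum, first_ge, axis=1)
    tn_t = first_ge - fn_t
    treated = tp_t / n - (fp_t / n) * (t / (1.0 - t))[None, :]
    untreated = tn_t / n - (fn_t / n) * ((1.0 - t) / t)[None, :]
    nb_v = np.mean(treated + untreated, axis=1)

    comp = np.column_stack([auc_v, f1_v, 1.0 - ece_v, brier_v, nb_v])
    with np.errstate(invalid="ignore", divide="ignore"):
        cem_v = np.where(np.all(comp > 0, axis=1),
                         np.exp(np.mean(np.log(np.maximum(comp, 1e-300)),
                                        axis=1)),
                         np.nan)
    rows[valid, 0] = auc_v[valid]
    rows[valid, 1] = f1_v[valid]
    rows[valid, 2] = 1.0 - ece_v[valid]
    rows[valid, 3] = brier_v[valid]
    rows[valid, 4] = nb_v[valid]
    rows[valid, 5] = cem_v[valid]
    return rows, int(np.sum(~valid))


@dataclass
class BootstrapSummary:
    """Distribution of metric vectors over B bootstrap resamples."""

    samples: pd.DataFrame          # B rows x 6 metric columns (NaN where degenerate)
    point: dict[str, float]        # geometric mean across valid resamples
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    B: int
    n: int
    seed: int
    n_degenerate: int = 0
    arithmetic_fallback: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {"point": self.point, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "B": self.B, "n": self.n, "seed": self.seed,
                "n_degenerate": self.n_degenerate,
                "arithmetic_fallback": list(self.arithmetic_fallback)}


def bootstrap_evaluate(prob, outcome, B: int = 1000, f1_threshold: float = 0.5,
                       n_bins: int = 10, thresholds=None, seed: int = 0,
                       stratified: bool = False,
                       indices: np.ndarray | None = None) -> BootstrapSummary:
    """Bootstrap the full metric vector.

    Resamples patients with replacement B times; degenerate resamples
    (a single outcome class) get NaN metrics and are counted, not hidden.
    Point estimates are geometric means across valid resamples per metric;
    when a metric has non-positive resample values (possible for net
    benefit) the arithmetic mean is used instead and the metric is listed
    in ``arithmetic_fallback``.  95% CIs are percentile (2.5/97.5).
    """
    p, y = _validate(prob, outcome)
    if B < 1:
        raise ValueError("B must be >= 1")
    if indices is None:
        indices = resample_indices(p.size, B, seed, outcome=y, stratified=stratified)
    t = default_thresholds() if thresholds is None else np.asarray(thresholds, dtype=float)
    # small problems take the matrix path (identical results, far fewer
    # Python-level calls); large ones loop to bound memory
    if B * p.size <= 2_000_000:
        rows, n_degenerate = _bootstrap_matrix(p, y, indices, f1_threshold, n_bins, t)
    else:
        rows = np.full((B, len(METRIC_NAMES)), np.nan)
        n_degenerate = 0
        for b in range(B):
            idx = indices[b]
            yb = y[idx]
            if yb.min() == yb.max():
                n_degenerate += 1
                continue
            mv = evaluate(p[idx], yb, f1_threshold=f1_threshold, n_bins=n_bins,
                          thresholds=t)
            rows[b] = [mv.auc, mv.f1, mv.one_minus_ece, mv.adjusted_brier,
                       mv.overall_net_benefit, mv.cem]
    samples = pd.DataFrame(rows, columns=METRIC_NAMES)
    point, lo, hi = {}, {}, {}
    fallback = []
    for name in METRIC_NAMES:
        v = samples[name].dropna().to_numpy()
        if v.size == 0:
            point[name] = lo[name] = hi[name] = float("nan")
            continue
        if np.all(v > 0):
            point[name] = geometric_mean(v)
        else:
            point[name] = float(np.mean(v))
            fallback.append(name)
        lo[name] = float(np.percentile(v, 2.5))
        hi[name] = float(np.percentile(v, 97.5))
    return BootstrapSummary(samples=samples, point=point, ci_low=lo, ci_high=hi,
                            B=B, n=int(p.size), seed=seed, n_degenerate=n_degenerate,
                            arithmetic_fallback=tuple(fallback))
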